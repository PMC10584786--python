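"""Tabular feature container shared across the pipeline stages.

A :class:`FeatureTable` is a thin, validated wrapper around an ``n x p``
float matrix with unique column names and binary labels in ``{-1, +1}``
(``-1`` metastasis-like, ``+1`` glioma-like).  It round-trips through CSV
with the label as the final column, and optionally carries the names of
columns with planted ground-truth relevance (written as a JSON sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    values: np.ndarray
    names: list[str]
    labels: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)
    relevant: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.names = list(self.names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of rows")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no missing values)")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, +1}}, got extra {bad}")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, indices) -> "FeatureTable":
        """New table restricted to the given column indices (order kept)."""
        indices = list(indices)
        names = [self.names[i] for i in indices]
        relevant = None
        if self.relevant is not None:
            relevant = [n for n in self.relevant if n in names]
        return FeatureTable(
            self.values[:, indices],
            names,
            self.labels.copy(),
            {n: self.provenance.get(n, "") for n in names},
            relevant,
        )

    def subset_rows(self, idx) -> "FeatureTable":
        return FeatureTable(
            self.values[idx], list(self.names), self.labels[idx],
            dict(self.provenance), self.relevant,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        """Write the table; final column is ``label`` in {-1, +1}.

        If ground-truth relevance is known it is written next to the CSV as
        ``<stem>.relevance.json``.
        """
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if self.relevant is not None:
            sidecar = path.with_suffix("").with_suffix(".relevance.json")
            sidecar.write_text(json.dumps({"relevant": self.relevant}, indent=2))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("CSV must contain a final 'label' column")
        labels = df.pop("label").to_numpy()
        relevant = None
        sidecar = path.with_suffix("").with_suffix(".relevance.json")
        if sidecar.exists():
            relevant = json.loads(sidecar.read_text())["relevant"]
        return cls(df.to_numpy(float), list(df.columns), labels, {}, relevant)
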