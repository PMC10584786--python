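"""Synthetic lesion volumes and feature tables with planted structure.

The volume generator emulates contrast-enhancing brain lesions of two
classes that differ in the two directions the downstream interpretation
highlights: metastasis-like lesions (label -1) are near-spherical with a
heterogeneous (rough) internal texture, glioma-like lesions (label +1) are
irregular with a smoother internal texture.  The lesion boundary is an
ellipsoid whose radius is perturbed by a smoothed noise field scaled by
``shape_irregularity``; the interior intensity is a faint short-range
component plus a correlated Gaussian field whose variance is controlled by
``texture_heterogeneity`` (a stronger correlated field spreads the
gray-level run-length distribution and raises run entropy).  A peritumoral ring of configurable physical
radius (default 5 mm) surrounds each lesion.

The table generator plants the statistical structure the selection stages
must recognise: class-shifted informative features, near-duplicate
redundant copies (|Spearman rho| > 0.8, so correlation pruning must remove
them), XOR-style interacting pairs that are marginally independent of the
label but jointly predictive (the case motivating the conditional-MI
terms of the selector), and pure noise — under a 129:72-like class
imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .tables import FeatureTable

__all__ = [
    "VolumeSample",
    "SyntheticTableSpec",
    "gen_volume",
    "make_ring",
    "gen_feature_table",
    "save_volume",
    "load_volume",
]

RING_RADIUS_MM = 5.0
MIN_DIAMETER_MM = 20.0  # inclusion rule: lesions larger than 2 cm

# label-dependent generator defaults (planted class structure)
_DEFAULT_IRREGULARITY = {-1: 0.05, 1: 0.35}
_DEFAULT_HETEROGENEITY = {-1: 1.0, 1: 0.35}
_SEMI_AXIS_RATIOS = {-1: (1.0, 0.95, 0.9), 1: (1.2, 0.9, 0.7)}
_BASE_ROUGH_AMPLITUDE = 0.1  # fixed short-range interior component
_CORR_GAIN = 0.3  # correlated-field amplitude per unit heterogeneity


@dataclass
class VolumeSample:
    """One synthetic lesion: image, tumor and ring masks, geometry, label."""

    image: np.ndarray
    tumor_mask: np.ndarray
    ring_mask: np.ndarray
    spacing: tuple[float, float, float]
    label: int
    seed: int

    def __post_init__(self):
        if self.label not in (-1, 1):
            raise ValueError("label must be -1 or +1")
        if not self.tumor_mask.any() or not self.ring_mask.any():
            raise ValueError("tumor and ring masks must be non-empty")
        if (self.tumor_mask & self.ring_mask).any():
            raise ValueError("tumor and ring masks must be disjoint")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image must be finite everywhere")


def make_ring(tumor_mask, radius: float = RING_RADIUS_MM,
              spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Peritumoral ring: voxels within ``radius`` mm of the tumor surface.

    Equivalent to dilating the mask with a spherical structuring element of
    the given physical radius and subtracting the tumor; anisotropic voxel
    sizes are handled through the physical distance transform.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    if radius <= 0:
        raise ValueError("radius must be positive")
    dist = distance_transform_edt(~tumor_mask, sampling=spacing)
    return (dist <= radius + 1e-9) & ~tumor_mask


def _unit_field(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return f / f.std()


def gen_volume(label: int, size: int = 64, spacing=(1.0, 1.0, 1.0),
               shape_irregularity: float | None = None,
               texture_heterogeneity: float | None = None,
               seed: int = 0) -> VolumeSample:
    """Generate one lesion volume with label-dependent shape and texture.

    ``shape_irregularity`` scales a smoothed radial perturbation of the
    ellipsoidal boundary (0 gives a digital ellipsoid);
    ``texture_heterogeneity`` scales the correlated interior field (exactly
    0 gives a constant interior).  ``None`` picks the class default:
    metastasis-like (-1) low irregularity / high heterogeneity,
    glioma-like (+1) the reverse.
    """
    if label not in (-1, 1):
        raise ValueError("label must be -1 or +1")
    if size < 32:
        raise ValueError("size must be at least 32 voxels per axis")
    spacing = tuple(float(s) for s in spacing)
    irregularity = (_DEFAULT_IRREGULARITY[label]
                    if shape_irregularity is None else float(shape_irregularity))
    heterogeneity = (_DEFAULT_HETEROGENEITY[label]
                     if texture_heterogeneity is None
                     else float(texture_heterogeneity))
    if irregularity < 0 or heterogeneity < 0:
        raise ValueError("irregularity and heterogeneity must be >= 0")

    rng = np.random.default_rng(seed)
    shape = (size, size, size)
    r0 = MIN_DIAMETER_MM / 2.0 + 1.0  # base semi-axis, mm
    axes = r0 * np.asarray(_SEMI_AXIS_RATIOS[label])
    # sizing: lesion + perturbation + ring must fit inside the volume
    extent = axes.max() * (1.0 + 2.0 * irregularity) + RING_RADIUS_MM
    half = min(size * s for s in spacing) / 2.0
    if extent >= half - max(spacing):
        raise ValueError(
            f"volume of {size} voxels cannot contain a lesion of extent "
            f"{extent:.1f} mm plus the {RING_RADIUS_MM} mm ring")

    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    rho = np.sqrt(sum(
        ((g - c) * s / a) ** 2
        for g, c, s, a in zip(grids, center, spacing, axes)
    ))
    eta = _unit_field(rng, shape, sigma=4.0)
    tumor = rho <= 1.0 + irregularity * eta
    ring = make_ring(tumor, RING_RADIUS_MM, spacing)

    rough = _unit_field(rng, shape, sigma=1.2)
    corr = _unit_field(rng, shape, sigma=3.0)
    image = 0.1 + 0.05 * rough  # faint textured background
    if heterogeneity == 0.0:
        interior = np.ones(shape)
    else:
        interior = 1.0 + _BASE_ROUGH_AMPLITUDE * rough + \
            _CORR_GAIN * heterogeneity * corr
    image = np.where(tumor, interior, image)
    image = np.where(ring, 0.7 + 0.1 * rough, image)  # enhancing rim
    return VolumeSample(image=image, tumor_mask=tumor, ring_mask=ring,
                        spacing=spacing, label=label, seed=seed)


# ---------------------------------------------------------------------------
# feature tables


@dataclass
class SyntheticTableSpec:
    """Recipe for a planted-structure feature table.

    Defaults give 5 informative features (class-shifted means), one
    XOR-style interacting pair and 10 noise features at n = 4000 with the
    cohort-like class imbalance (36% minority, glioma-like +1).
    """

    n_samples: int = 4000
    class_ratio: float = 72.0 / 201.0  # minority (+1) fraction
    n_informative: int = 5
    n_redundant: int = 0
    n_interacting_pairs: int = 1
    n_noise: int = 10
    effect_sizes: float | tuple = 1.0
    correlation: float = 0.9  # target |Spearman rho| for redundant copies
    xor_purity: float = 0.95  # P(sign(a) * sign(b) == y)
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_informative, self.n_redundant,
                  self.n_interacting_pairs, self.n_noise)
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if sum(counts) < 1:
            raise ValueError("at least one feature is required")
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must be in (0, 1)")
        if self.n_redundant > 0 and not 0.8 < self.correlation < 1.0:
            raise ValueError("correlation for redundant copies must be in "
                             "(0.8, 1) so pruning at 0.8 removes them")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant copies require informative parents")


def gen_feature_table(spec: SyntheticTableSpec) -> FeatureTable:
    """Generate the planted table described by ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_min = int(round(spec.class_ratio * n))
    if min(n_min, n - n_min) < 2:
        raise ValueError("class_ratio leaves a class with fewer than 2 rows")
    y = np.full(n, -1)
    y[rng.choice(n, size=n_min, replace=False)] = 1

    if np.isscalar(spec.effect_sizes):
        effects = np.full(spec.n_informative, float(spec.effect_sizes))
    else:
        effects = np.asarray(spec.effect_sizes, dtype=float)
        if effects.size != spec.n_informative:
            raise ValueError("effect_sizes must match n_informative")

    cols, names, prov, relevant = [], [], {}, []

    for i in range(spec.n_informative):
        x = effects[i] / 2.0 * y + rng.standard_normal(n)
        name = f"inf_{i}"
        cols.append(x)
        names.append(name)
        prov[name] = f"informative, effect size {effects[i]:g}"
        relevant.append(name)

    # Pearson r reproducing the target Spearman rho under bivariate normality
    r = 2.0 * np.sin(np.pi * spec.correlation / 6.0)
    for i in range(spec.n_redundant):
        parent_idx = i % spec.n_informative
        parent = cols[parent_idx]
        v = parent.var()
        sigma = np.sqrt(v * (1.0 - r**2) / r**2)
        x = parent + sigma * rng.standard_normal(n)
        name = f"red_{i}_of_inf_{parent_idx}"
        cols.append(x)
        names.append(name)
        prov[name] = f"redundant copy of inf_{parent_idx}, target rho " \
                     f"{spec.correlation:g}"
        relevant.append(name)

    for i in range(spec.n_interacting_pairs):
        mag_a = np.abs(rng.standard_normal(n))
        mag_b = np.abs(rng.standard_normal(n))
        s_a = rng.choice([-1.0, 1.0], size=n)
        flip = np.where(rng.random(n) < spec.xor_purity, 1.0, -1.0)
        s_b = s_a * y * flip
        for suffix, x in (("a", mag_a * s_a), ("b", mag_b * s_b)):
            name = f"xor_{i}_{suffix}"
            cols.append(x)
            names.append(name)
            prov[name] = "interacting pair member (XOR of signs predicts " \
                         "the label; marginally independent of it)"
            relevant.append(name)

    for i in range(spec.n_noise):
        name = f"noise_{i}"
        cols.append(rng.standard_normal(n))
        names.append(name)
        prov[name] = "label-independent noise"

    return FeatureTable(np.column_stack(cols), names, y, prov, relevant)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(sample: VolumeSample, out_dir, stem: str = "sample") -> dict:
    """Write image + tumor/ring masks as NIfTI (.nii.gz) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*sample.spacing, 1.0])
    paths = {}
    for key, arr in (("image", sample.image.astype(np.float32)),
                     ("tumor_mask", sample.tumor_mask.astype(np.uint8)),
                     ("ring_mask", sample.ring_mask.astype(np.uint8))):
        p = out_dir / f"{stem}_{key}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), p)
        paths[key] = str(p)
    meta = out_dir / f"{stem}_meta.json"
    meta.write_text(json.dumps(
        {"label": sample.label, "seed": sample.seed,
         "spacing": list(sample.spacing)}, indent=2))
    paths["meta"] = str(meta)
    return paths


def load_volume(out_dir, stem: str = "sample") -> VolumeSample:
    out_dir = Path(out_dir)
    img = nib.load(out_dir / f"{stem}_image.nii.gz")
    tumor = nib.load(out_dir / f"{stem}_tumor_mask.nii.gz")
    ring = nib.load(out_dir / f"{stem}_ring_mask.nii.gz")
    meta = json.loads((out_dir / f"{stem}_meta.json").read_text())
    return VolumeSample(
        image=np.asarray(img.dataobj, dtype=float),
        tumor_mask=np.asarray(tumor.dataobj).astype(bool),
        ring_mask=np.asarray(ring.dataobj).astype(bool),
        spacing=tuple(meta["spacing"]),
        label=int(meta["label"]),
        seed=int(meta["seed"]),
    )
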