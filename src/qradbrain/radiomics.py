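"""Minimal IBSI-style radiomic feature extraction.

Covers the preprocessing chain (z-score normalisation, Laplacian-of-
Gaussian and single-level Haar wavelet filtering, fixed-bin-number
discretization with 32 bins), the shape and texture statistics the
downstream interpretation relies on (sphericity, GLCM contrast and cluster
prominence, GLRLM run entropy, GLSZM zone entropy, first-order mean /
variance / entropy), and the complete feature-name manifest of 913 tumor +
900 ring descriptors (7 feature classes x 10 image types; shape features
only for the tumor region on the original image).

Conventions: GLCM at distance 1 aggregated over the 13 unique 3-D
directions (symmetric, matrices summed before normalisation); GLRLM
likewise; GLSZM zones use 26-connectivity; entropies are base 2 with
0 log 0 = 0; the wavelet is an undecimated (stationary) single-level Haar
transform with periodic boundary, so sub-bands keep the input size; surface
area comes from a marching-cubes mesh of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

__all__ = [
    "FeatureDescriptor",
    "FEATURE_CLASSES",
    "IMAGE_TYPES",
    "zscore_normalize",
    "discretize_fbn",
    "log_filter",
    "wavelet_subbands",
    "sphericity",
    "texture_stats",
    "first_order_stats",
    "feature_manifest",
    "extract_features",
    "UnsupportedFeatureError",
]

# 13 unique direction offsets in 3-D (distance 1, up to sign)
OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

IMAGE_TYPES = [
    "original", "log-sigma-1",
    "wavelet-LLH", "wavelet-LHL", "wavelet-LHH", "wavelet-HLL",
    "wavelet-HLH", "wavelet-HHL", "wavelet-HHH", "wavelet-LLL",
]

# IBSI/common feature names trimmed to the configured class cardinalities
FEATURE_CLASSES: dict[str, list[str]] = {
    "shape": [
        "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
        "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
        "MinorAxisLength", "LeastAxisLength", "Elongation",
    ],
    "firstorder": [
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance",
    ],
    "glcm": [
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn",
        "Idn", "Imc1", "Imc2", "InverseVariance", "JointAverage",
        "JointEnergy", "JointEntropy", "MaximumProbability", "SumEntropy",
        "SumSquares",
    ],
    "glrlm": [
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ],
    "glszm": [
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ],
    "gldm": [
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance",
        "HighGrayLevelEmphasis", "LargeDependenceEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ],
    "ngtdm": ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"],
}

_EXPECTED_CARDINALITIES = {
    "shape": 13, "firstorder": 17, "glcm": 22, "glrlm": 16,
    "glszm": 16, "gldm": 14, "ngtdm": 5,
}

# the computable subset (everything else is manifest-only)
_SUPPORTED = {
    "shape": {"Sphericity"},
    "firstorder": {"Mean", "Variance", "Entropy"},
    "glcm": {"Contrast", "ClusterProminence"},
    "glrlm": {"RunEntropy"},
    "glszm": {"ZoneEntropy"},
    "gldm": set(),
    "ngtdm": set(),
}


class UnsupportedFeatureError(ValueError):
    """Raised when a manifest-only descriptor is requested for computation."""


@dataclass(frozen=True)
class FeatureDescriptor:
    region: str  # tumor | ring
    image_type: str
    feature_class: str
    name: str

    def __post_init__(self):
        if self.region not in ("tumor", "ring"):
            raise ValueError("region must be 'tumor' or 'ring'")
        if self.image_type not in IMAGE_TYPES:
            raise ValueError(f"unknown image type {self.image_type!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.feature_class == "shape" and (
                self.region != "tumor" or self.image_type != "original"):
            raise ValueError("shape features exist only for the tumor region "
                             "on the original image")

    @property
    def key(self) -> str:
        return f"{self.region}_{self.image_type}_{self.feature_class}_{self.name}"


def feature_manifest(config: dict[str, list[str]] | None = None
                     ) -> list[FeatureDescriptor]:
    """Full descriptor manifest: 913 tumor + 900 ring entries.

    Shape features are computed once (tumor, original image); every other
    class is enumerated for each of the 10 image types and both regions.
    A ``config`` overriding the name lists must keep the configured class
    cardinalities (13/17/22/16/16/14/5).
    """
    classes = FEATURE_CLASSES if config is None else config
    for cls, expected in _EXPECTED_CARDINALITIES.items():
        got = len(classes.get(cls, ()))
        if got != expected:
            raise ValueError(
                f"feature class {cls!r} must list {expected} names, got {got}")
    out: list[FeatureDescriptor] = []
    for region in ("tumor", "ring"):
        if region == "tumor":
            out += [FeatureDescriptor(region, "original", "shape", n)
                    for n in classes["shape"]]
        for image_type in IMAGE_TYPES:
            for cls in ("firstorder", "glcm", "glrlm", "glszm", "gldm",
                        "ngtdm"):
                out += [FeatureDescriptor(region, image_type, cls, n)
                        for n in classes[cls]]
    keys = [d.key for d in out]
    assert len(set(keys)) == len(keys)
    return out


# ---------------------------------------------------------------------------
# preprocessing

def zscore_normalize(image, mask):
    """Affine-map the image so masked voxels have mean 0 and variance 1."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image[mask]
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        raise ValueError("zero intensity variance inside mask")
    return (image - mu) / sd


def discretize_fbn(image, mask, n_bins: int = 32):
    """Fixed-bin-number discretization into labels 1..n_bins.

    Equal-width bins span the masked intensity range; the maximum maps to
    bin ``n_bins``.  A constant image maps every voxel to bin 1 (documented
    convention).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    lo, hi = image[mask].min(), image[mask].max()
    if hi == lo:
        return np.ones_like(image, dtype=np.int32)
    labels = np.floor((image - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    return np.clip(labels, 1, n_bins)


def log_filter(image, sigma: float = 1.0, spacing=(1.0, 1.0, 1.0)):
    """Laplacian-of-Gaussian response at physical scale ``sigma`` (mm)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    voxel_sigma = [sigma / s for s in spacing]
    # wide truncation keeps the discrete kernel's zero-sum property tight
    return ndimage.gaussian_laplace(image, sigma=voxel_sigma, truncate=6.0)


def wavelet_subbands(image) -> dict[str, np.ndarray]:
    """Single-level undecimated 3-D Haar decomposition, periodic boundary.

    Returns the 8 same-size sub-bands keyed ``LLL``..``HHH`` (per-axis
    low/high sequence).  The normalised stationary transform preserves
    energy, so the sub-band energies of an impulse sum to its energy.  Odd
    axes are wrap-padded to even length and cropped back.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or min(image.shape) < 2:
        raise ValueError("image must be 3-D with every axis >= 2")
    pad = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pad, mode="wrap")
    coeffs = pywt.swtn(padded, "haar", level=1, norm=True,
                       trim_approx=False)[0]
    out = {}
    crop = tuple(slice(0, s) for s in image.shape)
    for key, arr in coeffs.items():
        # pywt keys use 'a'/'d' per axis; map to L/H
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[crop]
    return out


# ---------------------------------------------------------------------------
# shape

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum(
        "ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))


def sphericity(mask, spacing=(1.0, 1.0, 1.0), smooth_sigma: float = 0.7,
               volume_tol: float = 0.03) -> float:
    """Shape roundness ``(36 pi V^2)^(1/3) / A`` (1 for a perfect sphere).

    Convention: the mask is lightly Gaussian-smoothed (``smooth_sigma``
    voxels) before marching cubes so large compact lesions are not
    penalised by voxel stair-stepping; the smoothed mesh is accepted only
    when its enclosed volume agrees with the voxel-count volume to
    ``volume_tol`` (then V is the voxel-count volume).  Otherwise the raw
    binary mask is meshed and both V and A come from that mesh, which keeps
    the value isoperimetrically bounded for thin or scattered masks.
    Invariant to isotropic rescaling of the spacing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = tuple(float(s) for s in spacing)
    vox_volume = mask.sum() * float(np.prod(spacing))

    field = ndimage.gaussian_filter(np.pad(mask, 2).astype(float),
                                    smooth_sigma)
    volume = None
    if field.min() < 0.5 < field.max():
        verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=spacing)
        mv = _mesh_volume(verts, faces)
        if abs(mv - vox_volume) <= volume_tol * vox_volume:
            volume = vox_volume
    if volume is None:
        verts, faces, _, _ = marching_cubes(np.pad(mask, 1).astype(float),
                                            level=0.5, spacing=spacing)
        volume = _mesh_volume(verts, faces)
    area = mesh_surface_area(verts, faces)
    return float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area)


# ---------------------------------------------------------------------------
# texture matrices

def _shifted_views(arr, off):
    """Pair of views of ``arr`` displaced by ``off`` (a, a+off)."""
    sl_a, sl_b = [], []
    for o in off:
        if o >= 0:
            sl_a.append(slice(0, arr.shape[len(sl_a)] - o))
            sl_b.append(slice(o, arr.shape[len(sl_b)]))
        else:
            sl_a.append(slice(-o, arr.shape[len(sl_a)]))
            sl_b.append(slice(0, arr.shape[len(sl_b)] + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrix(labels, mask, n_levels: int) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix, distance 1, 13 directions
    summed before normalisation."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    P = np.zeros((n_levels, n_levels))
    for off in OFFSETS_13:
        la, lb = _shifted_views(labels, off)
        ma, mb = _shifted_views(mask, off)
        valid = ma & mb
        a = la[valid] - 1
        b = lb[valid] - 1
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total > 0:
        P /= total
    return P


def glrlm_matrix(labels, mask, n_levels: int) -> np.ndarray:
    """Gray-level x run-length counts aggregated over the 13 directions."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in labels.shape)))) + 1
    R = np.zeros((n_levels, max_len))
    shape = np.asarray(labels.shape)
    for off in OFFSETS_13:
        off_a = np.asarray(off)
        # run starts: masked voxels whose predecessor along -off is not a
        # same-label masked voxel
        la, lb = _shifted_views(labels, off)
        ma, mb = _shifted_views(mask, off)
        same_next = np.zeros_like(mask)
        va, _ = _shifted_views(same_next, off)
        va[...] = ma & mb & (la == lb)  # voxel continues into its successor
        prev_same = np.zeros_like(mask)
        _, vb = _shifted_views(prev_same, off)
        vb[...] = ma & mb & (la == lb)  # voxel continues from its predecessor
        starts = mask & ~prev_same
        pos = np.argwhere(starts)
        lev = labels[starts] - 1
        length = np.ones(len(pos), dtype=int)
        active = np.ones(len(pos), dtype=bool)
        cur = pos.copy()
        while active.any():
            nxt = cur[active] + off_a
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            ok = np.zeros(len(nxt), dtype=bool)
            if inb.any():
                coords = tuple(nxt[inb].T)
                ok[inb] = mask[coords] & (labels[coords] ==
                                          lev[active][inb] + 1)
            idx = np.flatnonzero(active)
            cont = idx[ok]
            length[cont] += 1
            cur[cont] += off_a
            active[idx[~ok]] = False
        np.add.at(R, (lev, length - 1), 1.0)
    return R


def glszm_matrix(labels, mask, n_levels: int) -> np.ndarray:
    """Gray-level x zone-size counts (26-connected zones)."""
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int(mask.sum())
    Z = np.zeros((n_levels, max_size))
    for g in range(1, n_levels + 1):
        region = mask & (labels == g)
        if not region.any():
            continue
        lab, n_zones = ndimage.label(region, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[g - 1, s - 1] += 1.0
    return Z


def _entropy(P: np.ndarray) -> float:
    p = P[P > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def texture_stats(labels, mask, n_levels: int) -> dict[str, float]:
    """The four texture statistics the interpretation stage names.

    GLCM contrast and cluster prominence, GLRLM run entropy and GLSZM zone
    entropy (all base-2, matrix-level direction aggregation).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    inside = labels[mask]
    if inside.min() < 1 or inside.max() > n_levels:
        raise ValueError("labels inside mask must lie in [1, n_levels]")

    P = glcm_matrix(labels, mask, n_levels)
    i = np.arange(1, n_levels + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = (ii * P).sum()
    mu_j = (jj * P).sum()
    contrast = ((ii - jj) ** 2 * P).sum()
    prominence = ((ii + jj - mu_i - mu_j) ** 4 * P).sum()

    R = glrlm_matrix(labels, mask, n_levels)
    Zm = glszm_matrix(labels, mask, n_levels)
    return {
        "glcm_contrast": float(contrast),
        "glcm_cluster_prominence": float(prominence),
        "glrlm_run_entropy": _entropy(R),
        "glszm_zone_entropy": _entropy(Zm),
    }


def first_order_stats(image, mask, n_bins: int = 32) -> dict[str, float]:
    """Mean, population variance and discretized intensity entropy."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    labels = discretize_fbn(image, mask, n_bins)
    counts = np.bincount(labels[mask], minlength=n_bins + 1)[1:]
    return {
        "Mean": float(vals.mean()),
        "Variance": float(vals.var()),
        "Entropy": _entropy(counts.astype(float)),
    }


# ---------------------------------------------------------------------------
# extraction

def _filtered_image(image, image_type: str, spacing) -> np.ndarray:
    if image_type == "original":
        return image
    if image_type == "log-sigma-1":
        return log_filter(image, sigma=1.0, spacing=spacing)
    if image_type.startswith("wavelet-"):
        return wavelet_subbands(image)[image_type.split("-")[1]]
    raise ValueError(f"unknown image type {image_type!r}")


def extract_features(sample, which, n_bins: int = 32) -> dict[str, float]:
    """Compute the requested descriptors for one volume sample.

    ``which`` is a list of :class:`FeatureDescriptor` (or manifest keys).
    Preprocessing per image type: z-score normalise over the region mask,
    filter, discretize, then texture; descriptors outside the implemented
    subset raise :class:`UnsupportedFeatureError`.
    """
    manifest = {d.key: d for d in feature_manifest()}
    descs = []
    for d in which:
        if isinstance(d, str):
            if d not in manifest:
                raise UnsupportedFeatureError(f"unknown descriptor {d!r}")
            d = manifest[d]
        descs.append(d)
    for d in descs:
        if d.name not in _SUPPORTED[d.feature_class]:
            raise UnsupportedFeatureError(
                f"descriptor {d.key!r} is manifest-only (not computable)")

    masks = {"tumor": sample.tumor_mask, "ring": sample.ring_mask}
    cache: dict[tuple, dict] = {}
    out: dict[str, float] = {}
    for d in descs:
        if d.feature_class == "shape":
            out[d.key] = sphericity(sample.tumor_mask, sample.spacing)
            continue
        mask = masks[d.region]
        ckey = (d.region, d.image_type)
        if ckey not in cache:
            try:
                norm = zscore_normalize(sample.image, mask)
            except ValueError:
                norm = sample.image - sample.image[mask].mean()
            filt = _filtered_image(norm, d.image_type, sample.spacing)
            labels = discretize_fbn(filt, mask, n_bins)
            cache[ckey] = {
                "firstorder": first_order_stats(filt, mask, n_bins),
                "texture": texture_stats(labels, mask, n_bins),
            }
        stats = cache[ckey]
        if d.feature_class == "firstorder":
            out[d.key] = stats["firstorder"][d.name]
        elif d.feature_class == "glcm":
            key = {"Contrast": "glcm_contrast",
                   "ClusterProminence": "glcm_cluster_prominence"}[d.name]
            out[d.key] = stats["texture"][key]
        elif d.feature_class == "glrlm":
            out[d.key] = stats["texture"]["glrlm_run_entropy"]
        elif d.feature_class == "glszm":
            out[d.key] = stats["texture"]["glszm_zone_entropy"]
    return out
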