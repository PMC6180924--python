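"""Radiomic feature formulas and the per-subject extraction entry point.

First-order statistics and the SUV/SUL peak operate on raw uptake values;
all texture features operate on the 64-bin min-max quantized VOI, so they are
invariant under positive affine rescaling of the image.

Feature definitions
-------------------
Let p(i, j) be the aggregated run-length counts (level i, run length j),
N_r = sum p(i, j), N the VOI voxel count and D the number of directions:

* run percentage      RP    = N_r / (D * N)
* low-intensity long-run emphasis
                      LILRE = (1/N_r) * sum_{i,j} p(i,j) * j^2 / i^2

With z(i, s) the size-zone counts and N_z = sum z(i, s):

* low-intensity large-zone emphasis
                      LILZE = (1/N_z) * sum_{i,s} z(i,s) * s^2 / i^2

With the normalized co-occurrence matrix P(i, j):

* homogeneity = sum P(i,j) / (1 + |i - j|)
* contrast    = sum P(i,j) * (i - j)^2

With NGTDM probabilities p_i and difference sums s_i:

* coarseness = 1 / (eps + sum_i p_i * s_i),  eps = 1e-6

Code similarity is the probability that two distinct VOI voxels drawn at
random carry an identical ternary texture-unit code (the Simpson index of
the code distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .matrices import (GLRLM, NGTDM, glcm_build, glrlm_build, glszm_build,
                       ngtdm_build, texture_codes)
from .quantization import quantize
from .segmentation import compute_volume_ml
from .volume import ImageVolume, VOIMask

__all__ = [
    "FeatureConfig",
    "FEATURE_NAMES",
    "first_order_features",
    "suv_peak",
    "sul_peak",
    "lean_body_mass_james",
    "run_percentage",
    "lilre",
    "lilze",
    "ngtdm_coarseness",
    "glcm_features",
    "code_similarity",
    "extract_all",
]

#: Stable column order of the extracted feature vector.
FEATURE_NAMES = (
    "SUVmean", "SUVmax", "skewness", "kurtosis", "SUV_peak", "SUL_peak",
    "GLCM_homogeneity", "GLCM_contrast", "run_percentage", "LILRE",
    "coarseness", "code_similarity", "LILZE", "volume_ml",
)

COARSENESS_EPS = 1e-6

# radius of a 1 cm^3 sphere: (3/(4 pi))^(1/3) cm, in mm
PEAK_SPHERE_RADIUS_MM = 10.0 * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class FeatureConfig:
    """Extraction settings, serialized alongside outputs for provenance."""

    n_bins: int = 64
    glrlm_aggregate: bool = True  # sum matrices over directions (False: average per-direction features)
    connectivity: int = 26
    coarseness_eps: float = COARSENESS_EPS

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# first order / intensity


def first_order_features(vol: ImageVolume, mask: VOIMask) -> dict[str, float]:
    """Histogram statistics of raw SUV over the VOI.

    Skewness is m3 / m2^(3/2) and kurtosis m4 / m2^2 (Pearson convention,
    not excess), with central moments over mask voxels.  Both are reported
    as NaN on a zero-variance VOI.
    """
    values = vol.data[mask.mask]
    if values.size == 0:
        raise ValueError("empty mask")
    out = {"SUVmean": float(values.mean()), "SUVmax": float(values.max())}
    if values.size < 2:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
        return out
    centered = values - values.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        warnings.warn("zero-variance VOI: skewness/kurtosis undefined", stacklevel=2)
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    else:
        out["skewness"] = float(np.mean(centered**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(centered**4) / m2**2)
    return out


def _sphere_kernel(spacing_mm: tuple[float, float, float],
                   radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> np.ndarray:
    """Boolean kernel of voxel offsets whose centres lie within radius_mm."""
    half = [int(np.floor(radius_mm / s)) for s in spacing_mm]
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing_mm))
    return dist2 <= radius_mm**2


def suv_peak(vol: ImageVolume, mask: VOIMask) -> float:
    """Maximal mean uptake in a 1 cm^3 sphere centred at a VOI voxel.

    The sphere is the set of voxel offsets whose centres fall within
    (3/(4 pi))^(1/3) cm of the candidate centre; parts of the sphere outside
    the grid are dropped from the mean.  At coarse spacing the sphere may
    contain a single voxel, in which case the peak equals SUVmax.
    """
    kernel = _sphere_kernel(vol.spacing_mm).astype(float)
    sums = ndimage.convolve(vol.data, kernel, mode="constant", cval=0.0)
    cnts = ndimage.convolve(np.ones_like(vol.data), kernel, mode="constant", cval=0.0)
    means = sums / cnts
    return float(means[mask.mask].max())


def lean_body_mass_james(weight_kg: float, height_cm: float, sex: str) -> float:
    """James-formula lean body mass (kg); ``sex`` is 'M' or 'F'."""
    w, h = float(weight_kg), float(height_cm)
    if sex.upper().startswith("M"):
        return 1.10 * w - 128.0 * (w / h) ** 2
    return 1.07 * w - 148.0 * (w / h) ** 2


def sul_peak(vol: ImageVolume, mask: VOIMask, weight_kg: float | None,
             height_cm: float | None, sex: str | None) -> float:
    """SUV peak rescaled from body weight to lean body mass.

    SUV is dose-per-body-weight normalized, so SUL = SUV * LBM / weight.
    Returns NaN (with a warning) when anthropometrics are missing.
    """
    peak = suv_peak(vol, mask)
    if weight_kg is None or height_cm is None or sex is None or \
            not np.isfinite([weight_kg, height_cm]).all():
        warnings.warn("missing anthropometrics: SUL peak unavailable", stacklevel=2)
        return np.nan
    lbm = lean_body_mass_james(weight_kg, height_cm, sex)
    return peak * lbm / float(weight_kg)


# ---------------------------------------------------------------------------
# GLRLM features


def run_percentage(m: GLRLM, n_voxels: int | None = None,
                   n_directions: int | None = None) -> float:
    """Number of runs over the maximal possible number of runs, in (0, 1]."""
    n = m.n_voxels if n_voxels is None else n_voxels
    d = m.n_directions if n_directions is None else n_directions
    return m.n_runs / (d * n)


def lilre(m: GLRLM) -> float:
    """Low-intensity long-run emphasis: (1/N_r) sum p(i,j) j^2 / i^2."""
    if m.n_runs == 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, m.counts.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, m.counts.shape[1] + 1)[None, :].astype(float)
    return float((m.counts * j**2 / i**2).sum() / m.n_runs)


# ---------------------------------------------------------------------------
# GLSZM / NGTDM / GLCM / codes


def lilze(z: np.ndarray) -> float:
    """Low-intensity large-zone emphasis: (1/N_z) sum z(i,s) s^2 / i^2."""
    n_zones = z.sum()
    if n_zones == 0:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, z.shape[0] + 1)[:, None].astype(float)
    s = np.arange(1, z.shape[1] + 1)[None, :].astype(float)
    return float((z * s**2 / i**2).sum() / n_zones)


def ngtdm_coarseness(m: NGTDM, eps: float = COARSENESS_EPS) -> float:
    """1 / (eps + sum_i p_i s_i); the eps floor caps a perfectly uniform VOI."""
    return float(1.0 / (eps + float(np.dot(m.p, m.s))))


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Homogeneity and contrast of a normalized co-occurrence matrix."""
    B = P.shape[0]
    i = np.arange(1, B + 1)[:, None].astype(float)
    j = np.arange(1, B + 1)[None, :].astype(float)
    if P.sum() == 0:
        return {"GLCM_homogeneity": np.nan, "GLCM_contrast": np.nan}
    return {
        "GLCM_homogeneity": float((P / (1.0 + np.abs(i - j))).sum()),
        "GLCM_contrast": float((P * (i - j) ** 2).sum()),
    }


def code_similarity(codes: np.ndarray) -> float:
    """Probability two distinct voxels share an identical texture-unit code.

    Simpson index of the code distribution: sum_c n_c (n_c - 1) / (N (N - 1)).
    """
    n = codes.size
    if n < 2:
        raise ValueError("code similarity needs at least 2 coded voxels")
    _, counts = np.unique(codes, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# full extraction


def extract_all(vol: ImageVolume, mask: VOIMask,
                config: FeatureConfig | None = None,
                weight_kg: float | None = None,
                height_cm: float | None = None,
                sex: str | None = None) -> dict[str, float]:
    """Compute the full feature vector for one VOI.

    First-order and peak features use raw SUV; everything else the quantized
    levels.  A degenerate VOI (single level) yields NaN for the per-feature
    undefined entries but never raises.
    """
    cfg = config or FeatureConfig()
    out: dict[str, float] = dict.fromkeys(FEATURE_NAMES, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.update(first_order_features(vol, mask))
        out["SUV_peak"] = suv_peak(vol, mask)
        out["SUL_peak"] = sul_peak(vol, mask, weight_kg, height_cm, sex)
    q = quantize(vol, mask, n_bins=cfg.n_bins)

    if cfg.glrlm_aggregate:
        m = glrlm_build(q, aggregate=True)
        out["run_percentage"] = run_percentage(m)
        out["LILRE"] = lilre(m)
    else:
        per_dir = glrlm_build(q, aggregate=False)
        out["run_percentage"] = float(np.mean([run_percentage(m) for m in per_dir]))
        out["LILRE"] = float(np.mean([lilre(m) for m in per_dir]))

    out.update(glcm_features(glcm_build(q)))
    out["coarseness"] = ngtdm_coarseness(ngtdm_build(q), eps=cfg.coarseness_eps)
    out["LILZE"] = lilze(glszm_build(q))
    codes = texture_codes(q)
    out["code_similarity"] = code_similarity(codes) if codes.size >= 2 else np.nan
    out["volume_ml"] = compute_volume_ml(mask)
    return out
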