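"""Texture matrix builders on quantized VOIs.

All builders consume a :class:`~petradiomics.quantization.QuantizedVOI` whose
``levels`` array is 0 outside the mask, and enumerate spatial structure over
the 13 unique 3D directions (one per antipodal pair of the 26-neighbourhood):

* GLRLM — grey-level run-length matrix: maximal collinear runs of equal level,
  broken at the mask boundary, summed (or kept separate) over directions.
* GLCM — grey-level co-occurrence at distance 1, symmetric, normalized.
* NGTDM — neighbourhood grey-tone difference: per-level occurrence probability
  and the summed absolute deviation from the mean of in-mask 26-neighbours.
* GLSZM — grey-level size-zone matrix: 26-connected zones of constant level.
* Texture-unit codes — ternary comparison of each voxel against its 26
  neighbours (the texture-spectrum encoding).

Each builder is deliberately written as array sweeps over explicit direction
vectors so its output can be checked voxel-by-voxel against brute-force
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .quantization import QuantizedVOI

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glrlm_build",
    "glcm_build",
    "ngtdm_build",
    "glszm_build",
    "texture_codes",
    "GLRLM",
    "NGTDM",
]

#: The 13 unique direction vectors of the 3D 26-neighbourhood (one per
#: antipodal pair), lexicographically the first of each pair negated so the
#: leading nonzero component is positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: All 26 neighbour offsets, in fixed lexicographic order (code digit order).
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """Return ``out[v] = arr[v + offset]`` with out-of-grid positions = fill."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, d in zip(arr.shape, offset):
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


@dataclass
class GLRLM:
    """Run-length counts ``p[i-1, j-1]`` = number of runs of level i, length j."""

    counts: np.ndarray  # (n_bins, max_run_length), int
    n_directions: int
    n_voxels: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _runs_one_direction(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Counts matrix (B implied by caller, here max level) for a single direction.

    A voxel starts a run if its predecessor along ``-d`` is outside the mask or
    has a different level; the run extends while successors along ``d`` keep
    the level.  Returns (level, length) pairs as a dense counts matrix sized
    to the data.
    """
    neg = tuple(-c for c in d)
    prev = _shift(levels, neg, fill=0)
    starts = (levels > 0) & (prev != levels)
    coords = np.argwhere(starts)
    if coords.size == 0:
        return np.zeros((1, 1), dtype=np.int64)
    start_levels = levels[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    cur = coords.copy()
    alive = np.arange(len(coords))
    dvec = np.asarray(d)
    shape = np.asarray(levels.shape)
    while alive.size:
        cur_a = cur[alive] + dvec
        inside = np.all((cur_a >= 0) & (cur_a < shape), axis=1)
        same = np.zeros(len(alive), dtype=bool)
        if inside.any():
            idx = cur_a[inside]
            same[inside] = levels[idx[:, 0], idx[:, 1], idx[:, 2]] == start_levels[alive[inside]]
        keep = alive[same]
        lengths[keep] += 1
        cur[keep] += dvec
        alive = keep
    max_len = int(lengths.max())
    max_lvl = int(start_levels.max())
    counts = np.zeros((max_lvl, max_len), dtype=np.int64)
    np.add.at(counts, (start_levels - 1, lengths - 1), 1)
    return counts


def glrlm_build(q: QuantizedVOI,
                directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
                aggregate: bool = True) -> GLRLM | list[GLRLM]:
    """Build the run-length matrix over the given directions.

    With ``aggregate=True`` (default) the per-direction matrices are summed;
    the partition identity sum_{i,j} p(i,j)*j = n_directions * n_voxels then
    holds.  With ``aggregate=False`` a list of single-direction matrices is
    returned (for the per-direction-feature-average convention).
    """
    n = q.n_voxels
    per_dir = []
    for d in directions:
        c = _runs_one_direction(q.levels, d)
        per_dir.append(GLRLM(counts=c, n_directions=1, n_voxels=n))
    if not aggregate:
        return per_dir
    max_lvl = max(m.counts.shape[0] for m in per_dir)
    max_len = max(m.counts.shape[1] for m in per_dir)
    total = np.zeros((max_lvl, max_len), dtype=np.int64)
    for m in per_dir:
        total[: m.counts.shape[0], : m.counts.shape[1]] += m.counts
    return GLRLM(counts=total, n_directions=len(directions), n_voxels=n)


def glcm_build(q: QuantizedVOI,
               directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix at distance 1.

    Both orderings of every in-mask voxel pair at offset d (for each of the
    given directions) are counted, then the matrix is normalized to sum to 1.
    Returns a (B, B) float array; all-zero if no voxel pair exists.
    """
    B = q.n_bins
    counts = np.zeros((B, B), dtype=np.int64)
    lv = q.levels
    for d in directions:
        nb = _shift(lv, d, fill=0)
        valid = (lv > 0) & (nb > 0)
        a = lv[valid] - 1
        b = nb[valid] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        return counts.astype(float)
    return counts / total


@dataclass
class NGTDM:
    """Per-level occurrence probabilities and neighbour-difference sums."""

    p: np.ndarray  # (n_bins,) probabilities, sums to 1 over occurring levels
    s: np.ndarray  # (n_bins,) absolute difference sums
    n_valid: int   # voxels with at least one in-mask neighbour


def ngtdm_build(q: QuantizedVOI) -> NGTDM:
    """Neighbourhood grey-tone difference matrix.

    For each voxel with at least one in-mask 26-neighbour, the absolute
    difference between its level and the mean level of those neighbours is
    accumulated per grey level.  Voxels without in-mask neighbours are
    skipped (they contribute to neither p nor s).
    """
    lv = q.levels.astype(float)
    m = q.mask.astype(float)
    kernel = _STRUCT_26.astype(float).copy()
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(lv * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nb_cnt > 0.5)
    n_valid = int(valid.sum())
    B = q.n_bins
    p = np.zeros(B)
    s = np.zeros(B)
    if n_valid == 0:
        return NGTDM(p=p, s=s, n_valid=0)
    levels_v = q.levels[valid]
    diffs = np.abs(q.levels[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(p, levels_v - 1, 1.0)
    np.add.at(s, levels_v - 1, diffs)
    p /= n_valid
    return NGTDM(p=p, s=s, n_valid=n_valid)


def glszm_build(q: QuantizedVOI) -> np.ndarray:
    """Size-zone matrix ``z[i-1, s-1]`` = number of 26-connected zones of level i, size s."""
    n = q.n_voxels
    zones: list[tuple[int, int]] = []
    for lvl in np.unique(q.voxel_levels):
        labeled, n_zones = ndimage.label(q.levels == lvl, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((int(lvl), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    max_lvl = max(l for l, _ in zones)
    z = np.zeros((max_lvl, max_size), dtype=np.int64)
    for lvl, size in zones:
        z[lvl - 1, size - 1] += 1
    assert int((z * np.arange(1, max_size + 1)).sum()) == n
    return z


def texture_codes(q: QuantizedVOI) -> np.ndarray:
    """Ternary texture-unit code per mask voxel.

    Each of the 26 neighbours contributes a digit: 0 if the neighbour's level
    is strictly lower, 1 if equal, 2 if strictly higher.  Neighbours outside
    the mask (or the grid) are coded as "equal".  Digits are packed base-3 in
    the fixed :data:`OFFSETS_26` order into an int64 per voxel.
    """
    lv = q.levels
    m = q.mask
    codes = np.zeros(lv.shape, dtype=np.int64)
    for k, off in enumerate(OFFSETS_26):
        nb = _shift(lv, off, fill=0)
        digit = np.ones(lv.shape, dtype=np.int64)  # missing neighbour => equal
        in_mask_nb = nb > 0
        digit[in_mask_nb & (nb < lv)] = 0
        digit[in_mask_nb & (nb > lv)] = 2
        codes += digit * 3**k
    return codes[m]
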