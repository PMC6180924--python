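"""Shared fixtures and brute-force texture oracles.

The oracles enumerate runs, co-occurrences, zones, neighbourhood differences
and texture codes voxel by voxel with plain Python loops; they share no code
with the array-sweep builders they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from petradiomics.matrices import DIRECTIONS_13, OFFSETS_26
from petradiomics.quantization import QuantizedVOI
from petradiomics.volume import ImageVolume, VOIMask


# ---------------------------------------------------------------------------
# small helpers


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(data=np.asarray(data, dtype=float), spacing_mm=spacing)


def make_mask(mask, spacing=(1.0, 1.0, 1.0)) -> VOIMask:
    return VOIMask(mask=np.asarray(mask, dtype=bool), spacing_mm=spacing)


def line_voi(levels_1d, n_bins=None) -> QuantizedVOI:
    """A 1D mask along the x-axis with prescribed integer levels."""
    lv = np.asarray(levels_1d, dtype=np.int64).reshape(-1, 1, 1)
    mask = lv > 0
    return QuantizedVOI(levels=lv, mask=mask, n_bins=n_bins or int(lv.max()),
                        vmin=1.0, vmax=float(lv.max()))


@pytest.fixture
def random_quantized_vois():
    """100 seeded random 4x4x4 masked level grids (the oracle-equivalence set)."""
    vois = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        mask = rng.random((4, 4, 4)) < 0.7
        if mask.sum() < 2:
            mask[0, 0, 0] = mask[1, 1, 1] = True
        levels = np.zeros((4, 4, 4), dtype=np.int64)
        levels[mask] = rng.integers(1, 5, size=int(mask.sum()))
        vois.append(QuantizedVOI(levels=levels, mask=mask, n_bins=4,
                                 vmin=1.0, vmax=4.0))
    return vois


# ---------------------------------------------------------------------------
# brute-force oracles


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def oracle_runs(levels: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Enumerate maximal runs along one direction by walking every start voxel."""
    shape = levels.shape
    counts: dict[tuple[int, int], int] = {}
    d = tuple(direction)
    for idx in np.ndindex(shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        prev = tuple(c - dc for c, dc in zip(idx, d))
        if _inside(shape, prev) and levels[prev] == lvl:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(c + dc for c, dc in zip(cur, d))
            if _inside(shape, nxt) and levels[nxt] == lvl:
                length += 1
                cur = nxt
            else:
                break
        counts[(int(lvl), length)] = counts.get((int(lvl), length), 0) + 1
    return counts


def oracle_glrlm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    total: dict[tuple[int, int], int] = {}
    for d in DIRECTIONS_13:
        for k, v in oracle_runs(levels, d).items():
            total[k] = total.get(k, 0) + v
    return total


def oracle_glcm(levels: np.ndarray) -> np.ndarray:
    """Symmetric co-occurrence counts over the 13 directions, unnormalized."""
    B = int(levels.max())
    counts = np.zeros((B, B), dtype=int)
    for d in DIRECTIONS_13:
        for idx in np.ndindex(levels.shape):
            a = levels[idx]
            if a == 0:
                continue
            nxt = tuple(c + dc for c, dc in zip(idx, d))
            if _inside(levels.shape, nxt) and levels[nxt] > 0:
                b = levels[nxt]
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def oracle_ngtdm(levels: np.ndarray):
    """(p_i, s_i, n_valid) by explicit neighbourhood enumeration."""
    B = int(levels.max())
    p = np.zeros(B)
    s = np.zeros(B)
    n_valid = 0
    for idx in np.ndindex(levels.shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        nbs = []
        for off in OFFSETS_26:
            v = tuple(c + dc for c, dc in zip(idx, off))
            if _inside(levels.shape, v) and levels[v] > 0:
                nbs.append(levels[v])
        if not nbs:
            continue
        n_valid += 1
        p[lvl - 1] += 1
        s[lvl - 1] += abs(lvl - float(np.mean(nbs)))
    if n_valid:
        p /= n_valid
    return p, s, n_valid


def oracle_zones(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """26-connected constant-level zones by flood fill."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(levels.shape):
        if levels[idx] == 0 or visited[idx]:
            continue
        lvl = int(levels[idx])
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                v = tuple(c + dc for c, dc in zip(cur, off))
                if _inside(levels.shape, v) and not visited[v] and levels[v] == lvl:
                    visited[v] = True
                    stack.append(v)
        zones[(lvl, size)] = zones.get((lvl, size), 0) + 1
    return zones


def oracle_codes(levels: np.ndarray) -> list[tuple[int, ...]]:
    """Ternary texture-unit code per mask voxel, as digit tuples."""
    out = []
    for idx in np.ndindex(levels.shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        digits = []
        for off in OFFSETS_26:
            v = tuple(c + dc for c, dc in zip(idx, off))
            if _inside(levels.shape, v) and levels[v] > 0:
                nb = levels[v]
                digits.append(0 if nb < lvl else (1 if nb == lvl else 2))
            else:
                digits.append(1)
        out.append(tuple(digits))
    return out
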