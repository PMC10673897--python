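"""Dynamic time warping distance between daily percent-change series.

DTW aligns two series by warping their time axes so that similar shapes match
even when they unfold at different speeds — here, an individual who loses
weight quickly and plateaus should sit close to one who reaches the same
plateau more slowly. The distance is the classic dynamic program

    D(i, j) = cost(a_i, b_j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

with D(0, 0) = 0, returning D(n, m). The local cost is squared difference
(with a final square root, the convention of the common DTW libraries) or
absolute difference. An optional Sakoe-Chiba band bounds how far the warp
may stray from the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

try:  # JIT-compiled inner loop; pure-python fallback keeps the package importable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


__all__ = ["DtwConfig", "dtw_distance", "dtw_distance_matrix"]


@dataclass(frozen=True)
class DtwConfig:
    """DTW parameterization.

    local_cost : {"squared", "absolute"}
        Per-step alignment cost.
    window : int or None
        Sakoe-Chiba band half-width in days; None = unconstrained. For
        unequal-length series the band is widened to at least the length
        difference so a path always exists.
    final_sqrt : bool
        Take the square root of the accumulated cost; applied only with
        squared local cost.
    """

    local_cost: str = "squared"
    window: int | None = None
    final_sqrt: bool = True

    def __post_init__(self) -> None:
        if self.local_cost not in ("squared", "absolute"):
            raise ValueError(f"unknown local_cost {self.local_cost!r}")
        if self.window is not None and self.window < 1:
            raise ValueError("window, if set, must be >= 1")


@njit(cache=True)
def _dtw_core(a, b, squared, window):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    w = window
    if w < 0:
        w = n + m
    if w < abs(n - m):
        w = abs(n - m)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = i - w
        if j_lo < 1:
            j_lo = 1
        j_hi = i + w
        if j_hi > m:
            j_hi = m
        for j in range(j_lo, j_hi + 1):
            d = a[i - 1] - b[j - 1]
            c = d * d if squared else abs(d)
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[n, m]


def _as_vector(x) -> np.ndarray:
    v = np.asarray(getattr(x, "values", x), dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("DTW requires nonempty 1-d series")
    if not np.isfinite(v).all():
        raise ValueError("DTW requires finite series")
    return v


def dtw_distance(a, b, cfg: DtwConfig | None = None) -> float:
    """DTW distance between two series (vectors or DailySeries)."""
    cfg = cfg or DtwConfig()
    va, vb = _as_vector(a), _as_vector(b)
    squared = cfg.local_cost == "squared"
    window = -1 if cfg.window is None else int(cfg.window)
    d = float(_dtw_core(va, vb, squared, window))
    if squared and cfg.final_sqrt:
        d = float(np.sqrt(d))
    return d


def dtw_distance_matrix(series, cfg: DtwConfig | None = None) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix with a zero diagonal."""
    cfg = cfg or DtwConfig()
    vecs = [_as_vector(s) for s in series]
    n = len(vecs)
    if n == 0:
        raise ValueError("need at least one series")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dtw_distance(vecs[i], vecs[j], cfg)
    return out


if not _HAVE_NUMBA:  # pragma: no cover
    warnings.warn("numba unavailable: DTW falls back to pure python and will be slow")
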