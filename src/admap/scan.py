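"""Density-difference scanning of an ADM and compact-region prediction.

At every residue index i the upper-triangular map is divided into a
triangular part and a trapezoidal part and the plot-density difference
delta_rho_i = rho_i (triangle) - rho~_i (trapezoid) is recorded.  Two scan
directions are kept:

* horizontal scan: the triangle holds pairs with both residues >= i, so a
  compact block [m, n] produces a positive peak at its start m;
* vertical scan: the triangle holds pairs with both residues <= i, peaking
  at the block end n.

A candidate compact region pairs a horizontal peak m with a vertical peak n
(n - m >= min_span) and is scored by the compactness measure

    eta = delta_rho^h_m + delta_rho^v_n.

Overlapping candidates are resolved greedily in descending eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adm import ADM
from .errors import ValidationError

DEFAULT_MIN_HEIGHT = 0.01
DEFAULT_MIN_SPAN = 20


@dataclass
class ScanProfile:
    """Per-index density-difference traces of one map.

    Arrays are length N with entry t-1 describing the division at residue t
    (1-based).  Divisions where either part has zero cells are NaN-flagged,
    never zero-filled.
    """

    N: int
    delta_h: np.ndarray
    delta_v: np.ndarray
    rho_tri_h: np.ndarray
    rho_trap_h: np.ndarray
    rho_tri_v: np.ndarray
    rho_trap_v: np.ndarray


def scan(adm: ADM) -> ScanProfile:
    """Compute both density-difference scanning profiles of a map."""
    return scan_plots(adm.plots, adm.N)


def scan_plots(plots: np.ndarray, N: int) -> ScanProfile:
    """Scan a bare (n, 2) array of 1-based plotted pairs on a length-N map."""
    if N < 3:
        raise ValidationError(f"scanning needs N >= 3, got {N}")
    plots = np.asarray(plots, dtype=np.int64).reshape(-1, 2)
    total = len(plots)
    total_cells = N * (N - 1) // 2
    t = np.arange(1, N + 1)

    # vertical division at t: triangle = pairs with both indices <= t
    in_tri_v = np.cumsum(np.bincount(plots[:, 1], minlength=N + 1))[t]
    cells_tri_v = t * (t - 1) // 2
    # horizontal division at t: triangle = pairs with both indices >= t
    below_i = np.cumsum(np.bincount(plots[:, 0], minlength=N + 1))[t - 1]
    in_tri_h = total - below_i
    cells_tri_h = (N - t + 1) * (N - t) // 2

    def _delta(in_tri, cells_tri):
        cells_trap = total_cells - cells_tri
        ok = (cells_tri >= 1) & (cells_trap >= 1)
        rho_tri = np.full(N, np.nan)
        rho_trap = np.full(N, np.nan)
        rho_tri[ok] = in_tri[ok] / cells_tri[ok]
        rho_trap[ok] = (total - in_tri[ok]) / cells_trap[ok]
        return rho_tri - rho_trap, rho_tri, rho_trap

    delta_v, rho_tri_v, rho_trap_v = _delta(in_tri_v, cells_tri_v)
    delta_h, rho_tri_h, rho_trap_h = _delta(in_tri_h, cells_tri_h)
    return ScanProfile(
        N=N,
        delta_h=delta_h,
        delta_v=delta_v,
        rho_tri_h=rho_tri_h,
        rho_trap_h=rho_trap_h,
        rho_tri_v=rho_tri_v,
        rho_trap_v=rho_trap_v,
    )


def _peaks_1d(x: np.ndarray, min_height: float) -> tuple[list[int], list[int]]:
    """Interior local maxima above min_height / minima below -min_height.

    Plateaus resolve to their leftmost index; NaN entries split the trace
    into independent segments; segment endpoints are never extrema (a
    monotone trace yields nothing).  Returned indices are 1-based.
    """
    peaks: list[int] = []
    valleys: list[int] = []
    finite = np.isfinite(x)
    n = len(x)
    seg_start = None
    for pos in range(n + 1):
        if pos < n and finite[pos]:
            if seg_start is None:
                seg_start = pos
            continue
        if seg_start is None:
            continue
        seg = x[seg_start:pos]
        run_start = 0
        for q in range(1, len(seg) + 1):
            if q < len(seg) and seg[q] == seg[run_start]:
                continue
            # run [run_start, q-1] of equal values
            if run_start > 0 and q < len(seg):
                v = seg[run_start]
                left, right = seg[run_start - 1], seg[q]
                if left < v > right and v > min_height:
                    peaks.append(seg_start + run_start + 1)
                elif left > v < right and v < -min_height:
                    valleys.append(seg_start + run_start + 1)
            run_start = q
        seg_start = None
    return peaks, valleys


@dataclass(frozen=True)
class PeakSet:
    """1-based peak/valley indices for both scan directions."""

    h_peaks: list[int]
    h_valleys: list[int]
    v_peaks: list[int]
    v_valleys: list[int]


def find_peaks(profile: ScanProfile, min_height: float = DEFAULT_MIN_HEIGHT) -> PeakSet:
    """Locate the peaks and valleys marking sudden density changes."""
    hp, hv = _peaks_1d(profile.delta_h, min_height)
    vp, vv = _peaks_1d(profile.delta_v, min_height)
    return PeakSet(h_peaks=hp, h_valleys=hv, v_peaks=vp, v_valleys=vv)


@dataclass(frozen=True)
class CompactRegion:
    """A predicted compact (ordered) region [start, end], scored by eta."""

    start: int
    end: int
    eta: float
    peak_h: float
    peak_v: float

    def __post_init__(self) -> None:
        if not 1 <= self.start < self.end:
            raise ValidationError(
                f"compact region must satisfy 1 <= start < end, got "
                f"({self.start}, {self.end})"
            )


def predict_regions(
    profile: ScanProfile,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[CompactRegion]:
    """Rank candidate compact regions by the compactness score eta.

    Candidates pair every horizontal peak m (region start) with every
    vertical peak n (region end) at least min_span residues downstream;
    overlapping candidates are resolved greedily in descending eta and the
    survivors are returned eta-descending.
    """
    pk = find_peaks(profile, min_height)
    candidates = []
    for m in pk.h_peaks:
        for n in pk.v_peaks:
            if n - m >= min_span:
                ph = float(profile.delta_h[m - 1])
                pv = float(profile.delta_v[n - 1])
                candidates.append(
                    CompactRegion(start=m, end=n, eta=ph + pv, peak_h=ph, peak_v=pv)
                )
    candidates.sort(key=lambda r: (-r.eta, r.start, r.end))
    chosen: list[CompactRegion] = []
    for cand in candidates:
        if all(cand.end < r.start or cand.start > r.end for r in chosen):
            chosen.append(cand)
    return chosen
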