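"""Average distance map construction from sequence and distance statistics.

An average distance map (ADM) is the sequence-only analogue of a contact
map.  For each separation range M a distance threshold is chosen and every
residue pair whose table mean distance falls below it is plotted.  The
thresholds are not free: the whole-map plot density is calibrated to
rho_av = C / N, the empirical density law of real distance maps at a 15-Å
cutoff (C defaults to 36.12).  Per range, the number of plotted pairs obeys

    P(M)_C = (D / M) * P(M)

where P(M) counts the sequence's residue pairs in range M with statistically
significant table entries and D is a single global scalar adjusting the total
plot count to the density target.  Within each range, the P(M)_C pairs with
the smallest table mean distances are plotted; the recorded per-range
threshold is the midpoint between the largest plotted mean and the next
larger candidate, so "mean < threshold" reproduces the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidIntervalError, NoStatisticsError, ValidationError
from .stats import (
    DEFAULT_C,
    AvgDistanceTable,
    _range_index_array,
    encode_sequence,
)


def round_half_away(x: float) -> int:
    """Round half away from zero (deterministic, unlike banker's rounding)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def target_plot_count(N: int, C: float = DEFAULT_C) -> int:
    """Total plot count implied by the density law rho_av = C / N.

    rho_av applies to the N(N-1)/2 upper-triangle cells, so the target is
    round(C * (N - 1) / 2).
    """
    if N < 2:
        raise ValidationError(f"sequence length must be >= 2, got {N}")
    if C < 0:
        raise ValidationError(f"calibration constant must be >= 0, got {C}")
    return round_half_away(C * (N - 1) / 2)


@dataclass(frozen=True)
class _Candidates:
    """Flat arrays describing every plottable pair of one sequence."""

    i: np.ndarray  # 1-based smaller index
    j: np.ndarray  # 1-based larger index
    k: np.ndarray  # separation j - i
    M: np.ndarray  # separation range
    dist: np.ndarray  # table mean distance (NaN if unobserved)
    significant: np.ndarray  # table count >= min_count


def _candidates(seq_idx: np.ndarray, table: AvgDistanceTable) -> _Candidates:
    N = len(seq_idx)
    i0, j0 = np.triu_indices(N, k=1)
    k = j0 - i0
    M = _range_index_array(k)
    keep = M <= table.max_M
    i0, j0, k, M = i0[keep], j0[keep], k[keep], M[keep]
    a, b = seq_idx[i0], seq_idx[j0]
    standard = (a >= 0) & (b >= 0)
    a_safe = np.where(standard, a, 0)
    b_safe = np.where(standard, b, 0)
    dist = table.mean[a_safe, b_safe, M - 1]
    count = table.count[a_safe, b_safe, M - 1]
    sig = standard & (count >= table.min_count) & np.isfinite(dist)
    dist = np.where(sig, dist, np.nan)
    return _Candidates(i=i0 + 1, j=j0 + 1, k=k, M=M, dist=dist, significant=sig)


def _solve_density_parameter(P: dict[int, int], target: int) -> float:
    """Solve sum_M min((D/M) * P(M), P(M)) = target for the global scalar D.

    The left side is a piecewise-linear non-decreasing function of D whose
    only kinks sit at the saturation points D = M (where range M has used all
    of its P(M) significant pairs).  If even full saturation cannot reach the
    target, the smallest fully-saturating D is returned and every range is
    plotted completely.
    """
    active = sorted(M for M, p in P.items() if p > 0)
    if not active:
        raise NoStatisticsError("no significant pairs in any separation range")
    if target <= 0:
        return 0.0
    capacity = sum(P[M] for M in active)
    if capacity <= target:
        return float(active[-1])
    filled = 0.0  # contribution of saturated ranges
    slope = sum(P[M] / M for M in active)
    D_prev = 0.0
    for M in active:  # saturation points in ascending order
        f_at_M = filled + slope * M
        if f_at_M >= target:
            return D_prev + (target - (filled + slope * D_prev)) / slope
        filled += P[M]
        slope -= P[M] / M
        D_prev = float(M)
    return float(active[-1])  # unreachable given the capacity check


@dataclass(frozen=True)
class DensityFit:
    """Result of calibrating the per-range plot counts to rho_av = C / N."""

    D: float
    target: int
    significant_pairs: dict[int, int]  # P(M)
    plot_counts: dict[int, int]  # P(M)_C, capped at P(M)


def fit_D(sequence: str, table: AvgDistanceTable, C: float = DEFAULT_C) -> DensityFit:
    """Fit the density-adjustment scalar D and per-range plot counts."""
    seq_idx = encode_sequence(sequence, allow_x=True)
    cand = _candidates(seq_idx, table)
    return _fit_from_candidates(cand, len(sequence), C)


def _fit_from_candidates(cand: _Candidates, N: int, C: float) -> DensityFit:
    P: dict[int, int] = {}
    for M in np.unique(cand.M):
        P[int(M)] = int(np.count_nonzero(cand.significant[cand.M == M]))
    target = target_plot_count(N, C)
    if all(p == 0 for p in P.values()):
        raise NoStatisticsError(
            "no residue pair of this sequence has a significant table entry"
        )
    D = _solve_density_parameter(P, target)
    counts = {
        M: min(round_half_away((D / M) * p), p) if p > 0 else 0
        for M, p in P.items()
    }
    return DensityFit(D=D, target=target, significant_pairs=P, plot_counts=counts)


@dataclass
class ADM:
    """An average distance map: plotted pairs plus the calibration that made it.

    ``plots`` is an (n, 2) array of 1-based (i, j) pairs with i < j, sorted
    lexicographically.  ``plot_M`` and ``plot_dist`` run parallel to it.
    """

    sequence: str
    plots: np.ndarray
    plot_M: np.ndarray
    plot_dist: np.ndarray
    thresholds: dict[int, float]
    D: float
    C: float
    significant_pairs: dict[int, int] = field(default_factory=dict)
    plot_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.plots = np.asarray(self.plots, dtype=np.int64).reshape(-1, 2)
        self.plot_M = np.asarray(self.plot_M, dtype=np.int64)
        self.plot_dist = np.asarray(self.plot_dist, dtype=float)
        if self.plots.size and np.any(self.plots[:, 0] >= self.plots[:, 1]):
            raise ValidationError("every plotted pair must satisfy i < j")

    @classmethod
    def from_plots(cls, N: int, plots: np.ndarray, C: float = DEFAULT_C) -> "ADM":
        """Wrap a bare plot set (e.g. a synthetic map) as an ADM of length N."""
        plots = np.asarray(plots, dtype=np.int64).reshape(-1, 2)
        order = np.lexsort((plots[:, 1], plots[:, 0])) if len(plots) else []
        plots = plots[order] if len(plots) else plots
        return cls(
            sequence="X" * N,
            plots=plots,
            plot_M=_range_index_array(plots[:, 1] - plots[:, 0])
            if len(plots)
            else np.empty(0, dtype=np.int64),
            plot_dist=np.full(len(plots), np.nan),
            thresholds={},
            D=float("nan"),
            C=C,
        )

    @property
    def N(self) -> int:
        return len(self.sequence)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def separations(self) -> np.ndarray:
        return self.plots[:, 1] - self.plots[:, 0]

    @property
    def density(self) -> float:
        return self.n_plots / (self.N * (self.N - 1) / 2)


def build_adm(sequence: str, table: AvgDistanceTable, C: float = DEFAULT_C) -> ADM:
    """Construct the ADM of a sequence against a statistics table.

    Within each separation range the P(M)_C significant pairs with the
    smallest table mean distances are plotted; ties at equal distance are
    broken by ascending (i, j), making the construction deterministic.
    """
    seq_idx = encode_sequence(sequence, allow_x=True)
    cand = _candidates(seq_idx, table)
    fit = _fit_from_candidates(cand, len(sequence), C)
    rows_i, rows_j, rows_M, rows_d = [], [], [], []
    thresholds: dict[int, float] = {}
    for M, n_take in sorted(fit.plot_counts.items()):
        mask = (cand.M == M) & cand.significant
        if not np.any(mask):
            continue
        ii, jj, dd = cand.i[mask], cand.j[mask], cand.dist[mask]
        order = np.lexsort((jj, ii, dd))
        ii, jj, dd = ii[order], jj[order], dd[order]
        thresholds[M] = _selection_threshold(dd, n_take)
        if n_take > 0:
            rows_i.append(ii[:n_take])
            rows_j.append(jj[:n_take])
            rows_M.append(np.full(n_take, M, dtype=np.int64))
            rows_d.append(dd[:n_take])
    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(rows_j)
        Marr = np.concatenate(rows_M)
        d = np.concatenate(rows_d)
        order = np.lexsort((j, i))
        plots = np.column_stack([i[order], j[order]])
        Marr, d = Marr[order], d[order]
    else:
        plots = np.empty((0, 2), dtype=np.int64)
        Marr = np.empty(0, dtype=np.int64)
        d = np.empty(0, dtype=float)
    return ADM(
        sequence=sequence,
        plots=plots,
        plot_M=Marr,
        plot_dist=d,
        thresholds=thresholds,
        D=fit.D,
        C=C,
        significant_pairs=fit.significant_pairs,
        plot_counts=fit.plot_counts,
    )


def _selection_threshold(sorted_dist: np.ndarray, n_take: int) -> float:
    """Threshold reproducing "the n_take smallest distances are plotted".

    Midpoint between the largest plotted distance and the next strictly
    larger candidate; if every candidate is plotted the last distance plus
    0.5 Å is used, and an empty selection records threshold 0.
    """
    if n_take <= 0:
        return 0.0
    last = float(sorted_dist[n_take - 1])
    rest = sorted_dist[n_take:]
    larger = rest[rest > last]
    if larger.size == 0:
        return last + 0.5
    return (last + float(larger[0])) / 2.0


@dataclass(frozen=True)
class PlotRatioReport:
    """Plots-per-residue ratios, split at the 8-residue separation boundary.

    short_range counts plotted pairs separated by fewer than 9 residues,
    long_range those separated by more than 8; the denominator is the number
    of residues considered (the full sequence or a restriction interval).
    """

    short_range_ratio: float
    long_range_ratio: float
    n_residues: int
    n_plots: int
    interval: tuple[int, int] | None = None

    @property
    def total_ratio(self) -> float:
        return self.n_plots / self.n_residues


def plot_ratios(adm: ADM, interval: tuple[int, int] | None = None) -> PlotRatioReport:
    """Short-/long-range ADM-plot ratios, optionally over a residue interval.

    With an interval only plots with both endpoints inside it are counted and
    the denominator becomes the interval length.
    """
    if interval is None:
        keep = np.ones(adm.n_plots, dtype=bool)
        n_res = adm.N
    else:
        lo, hi = interval
        if not (1 <= lo <= hi <= adm.N):
            raise InvalidIntervalError(
                f"interval {interval} is empty, reversed, or outside 1..{adm.N}"
            )
        keep = (
            (adm.plots[:, 0] >= lo)
            & (adm.plots[:, 1] <= hi)
            if adm.n_plots
            else np.ones(0, dtype=bool)
        )
        n_res = hi - lo + 1
    k = adm.separations[keep] if adm.n_plots else np.empty(0, dtype=np.int64)
    short = int(np.count_nonzero(k < 9))
    long_ = int(np.count_nonzero(k > 8))
    return PlotRatioReport(
        short_range_ratio=short / n_res,
        long_range_ratio=long_ / n_res,
        n_residues=n_res,
        n_plots=int(len(k)),
        interval=interval,
    )
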