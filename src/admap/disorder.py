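"""Intrinsic-disorder prediction from ADM plot counts.

Pipeline: for each residue, count the ADM plots incident to it within a
separation band (default 9 <= k <= 29 — long-range pairs restricted to
separations below 30, where the ordered/disordered contrast is strongest);
smooth the counts with an 11-residue truncated window (five residues either
side); map the smoothed count to a disorder probability through a calibrated
curve; and label residues disordered wherever the probability reaches the
threshold theta.

Calibration pools annotated proteins whose disordered and ordered fractions
both reach 10% of the chain, bins residues by integer-rounded smoothed
count, records the disordered fraction per bin, and fits an
occupancy-weighted cubic polynomial to the binned fractions (clamped to
[0, 1] and held constant outside the observed count range).

Two threshold presets are kept: ``accw`` (0.62), which maximises balanced
accuracy, and ``accp`` (0.53), which maximises plain accuracy.

Tandem mode predicts on the sequence concatenated with itself, probing
order that only appears through self-association: pair statistics that span
the junction create plots no monomer position can receive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adm import ADM, build_adm, round_half_away
from .errors import CalibrationError, ValidationError
from .evaluate import IntervalAnnotation
from .stats import DEFAULT_C, AvgDistanceTable

DEFAULT_BAND = (9, 29)
DEFAULT_HALF_WIDTH = 5
DEFAULT_FIT_DEGREE = 3
DEFAULT_MIN_COVERAGE = 0.10

#: Named threshold presets: accw maximises balanced accuracy, accp plain accuracy.
THRESHOLD_PRESETS = {"accw": 0.62, "accp": 0.53}
DEFAULT_THETA = THRESHOLD_PRESETS["accw"]


@dataclass(frozen=True)
class ResiduePlotCounts:
    """Raw and window-smoothed per-residue ADM plot counts."""

    raw: np.ndarray  # int, length N
    smoothed: np.ndarray  # float, length N
    band: tuple[int, int]


def residue_plot_counts(
    adm: ADM,
    k_lo: int = DEFAULT_BAND[0],
    k_hi: int = DEFAULT_BAND[1],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> ResiduePlotCounts:
    """Count plots incident to each residue within a separation band."""
    if not 1 <= k_lo < k_hi:
        raise ValidationError(f"counting band must satisfy 1 <= k_lo < k_hi, got ({k_lo}, {k_hi})")
    raw = np.zeros(adm.N, dtype=np.int64)
    if adm.n_plots:
        k = adm.separations
        keep = (k >= k_lo) & (k <= k_hi)
        raw += np.bincount(adm.plots[keep, 0] - 1, minlength=adm.N)
        raw += np.bincount(adm.plots[keep, 1] - 1, minlength=adm.N)
    return ResiduePlotCounts(raw=raw, smoothed=smooth(raw, half_width), band=(k_lo, k_hi))


def smooth(values, half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Mean over the truncated window [i - half_width, i + half_width]."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValidationError("smoothing expects a non-empty 1-D series")
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


@dataclass
class DisorderCurve:
    """Binned calibration statistics plus the fitted probability curve.

    Calling the curve evaluates the fitted polynomial at the given smoothed
    count, clipped to [0, 1].  Evaluation is clamped to the observed count
    domain (flat extension instead of extrapolation) and additionally to the
    interval between the polynomial's outermost interior stationary points:
    the disorder probability is monotone non-increasing in the plot count,
    and holding the fit flat past its own turning points keeps the sparse
    tails from oscillating back up.
    """

    bin_counts: np.ndarray  # integer-rounded smoothed counts with data
    bin_n: np.ndarray  # residues per bin
    bin_fraction: np.ndarray  # disordered fraction per bin
    coefficients: np.ndarray  # highest degree first (numpy polyval order)
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(self.bin_fraction < 0) or np.any(self.bin_fraction > 1):
            raise ValidationError("binned disorder fractions must lie in [0, 1]")
        self._eval_domain = self._monotone_domain()

    def _monotone_domain(self) -> tuple[float, float]:
        """Shrink the evaluation window to the fit's central monotone branch."""
        lo, hi = self.domain
        deriv = np.polyder(np.asarray(self.coefficients, dtype=float))
        roots = np.roots(deriv) if len(deriv) else np.empty(0)
        crit = sorted(
            float(r.real) for r in np.atleast_1d(roots)
            if abs(r.imag) < 1e-9 and lo < r.real < hi
        )
        if not crit:
            return (lo, hi)
        # between consecutive stationary points the fit is monotone; keep the
        # branch with the largest total change (the transition branch)
        bounds = [lo, *crit, hi]
        poly = np.asarray(self.coefficients, dtype=float)
        spans = [
            (abs(np.polyval(poly, b) - np.polyval(poly, a)), (a, b))
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        return max(spans)[1]

    def __call__(self, counts) -> np.ndarray:
        x = np.clip(np.asarray(counts, dtype=float), *self._eval_domain)
        return np.clip(np.polyval(self.coefficients, x), 0.0, 1.0)


def _coverage_admissible(ann: IntervalAnnotation, min_coverage: float) -> bool:
    """Training-exclusion rule: both classes must cover >= min_coverage of N."""
    return (
        ann.n_disordered / ann.length >= min_coverage
        and ann.n_ordered / ann.length >= min_coverage
    )


def calibrate(
    training,
    table: AvgDistanceTable,
    C: float = DEFAULT_C,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    band: tuple[int, int] = DEFAULT_BAND,
    half_width: int = DEFAULT_HALF_WIDTH,
    fit_degree: int = DEFAULT_FIT_DEGREE,
) -> DisorderCurve:
    """Fit the disorder-probability curve from annotated training proteins.

    ``training`` is an iterable of (sequence, IntervalAnnotation); sequences
    may be plain strings or objects with a ``residues`` attribute.  Proteins
    with less than ``min_coverage`` of either class are excluded.  Residues
    of admissible proteins are pooled, binned by integer-rounded smoothed
    plot count, and the per-bin disordered fractions are fitted by
    occupancy-weighted least squares.
    """
    tallies: dict[int, list[int]] = {}
    n_admissible = 0
    for seq, ann in training:
        seq = getattr(seq, "residues", seq)
        if len(seq) != ann.length:
            raise ValidationError(
                f"{ann.protein_id}: sequence length {len(seq)} != annotation "
                f"length {ann.length}"
            )
        if not _coverage_admissible(ann, min_coverage):
            continue
        n_admissible += 1
        adm = build_adm(seq, table, C)
        counts = residue_plot_counts(adm, *band, half_width=half_width)
        labels = ann.label_array()
        for smoothed, lab in zip(counts.smoothed, labels):
            if lab < 0:
                continue
            b = round_half_away(float(smoothed))
            cell = tallies.setdefault(b, [0, 0])
            cell[0] += 1
            cell[1] += int(lab)
    if n_admissible == 0 or not tallies:
        raise CalibrationError(
            "no admissible training protein (both classes must cover >= "
            f"{min_coverage:.0%} of the chain)"
        )
    bins = np.array(sorted(tallies), dtype=float)
    n = np.array([tallies[int(b)][0] for b in bins], dtype=float)
    frac = np.array([tallies[int(b)][1] / tallies[int(b)][0] for b in bins])
    degree = min(fit_degree, len(bins) - 1)
    if degree == 0:
        coef = np.array([float(np.average(frac, weights=n))])
    else:
        # weights multiply residuals, so sqrt(n) weights squared error by occupancy
        coef = np.polyfit(bins, frac, degree, w=np.sqrt(n))
    return DisorderCurve(
        bin_counts=bins.astype(np.int64),
        bin_n=n.astype(np.int64),
        bin_fraction=frac,
        coefficients=coef,
        domain=(float(bins[0]), float(bins[-1])),
    )


@dataclass
class DisorderPrediction:
    """Per-residue disorder probabilities, labels and disordered segments."""

    sequence: str
    raw_counts: np.ndarray
    smoothed_counts: np.ndarray
    probability: np.ndarray
    labels: np.ndarray  # bool, True = disordered
    segments: tuple[tuple[int, int], ...]  # maximal disordered runs, 1-based
    theta: float
    adm: ADM | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return len(self.sequence)


def segments_from_labels(labels) -> tuple[tuple[int, int], ...]:
    """Maximal runs of True as 1-based inclusive intervals."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        return ()
    edges = np.flatnonzero(np.diff(np.concatenate(([False], labels, [False]))))
    starts, ends = edges[::2] + 1, edges[1::2]
    return tuple((int(s), int(e)) for s, e in zip(starts, ends))


def labels_from_segments(segments, N: int) -> np.ndarray:
    """Inverse of :func:`segments_from_labels`."""
    labels = np.zeros(N, dtype=bool)
    for s, e in segments:
        if not 1 <= s <= e <= N:
            raise ValidationError(f"segment ({s}, {e}) outside 1..{N}")
        labels[s - 1 : e] = True
    return labels


def predict(
    sequence: str,
    table: AvgDistanceTable,
    curve: DisorderCurve,
    C: float = DEFAULT_C,
    theta: float = DEFAULT_THETA,
    band: tuple[int, int] = DEFAULT_BAND,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> DisorderPrediction:
    """Predict per-residue disorder for one sequence.

    A residue is labelled disordered when its probability reaches theta
    (probability >= theta), so theta = 0 labels everything and theta = 1
    keeps only residues at probability exactly 1.
    """
    sequence = getattr(sequence, "residues", sequence)
    if not 0.0 <= theta <= 1.0:
        raise ValidationError(f"theta must lie in [0, 1], got {theta}")
    adm = build_adm(sequence, table, C)
    counts = residue_plot_counts(adm, *band, half_width=half_width)
    prob = curve(counts.smoothed)
    labels = prob >= theta
    return DisorderPrediction(
        sequence=sequence,
        raw_counts=counts.raw,
        smoothed_counts=counts.smoothed,
        probability=prob,
        labels=labels,
        segments=segments_from_labels(labels),
        theta=theta,
        adm=adm,
    )


@dataclass
class TandemPrediction:
    """Monomer vs tandem-duplication (dimer-like) predictions.

    ``tandem`` covers the 2N-residue concatenation; ``copies`` re-reports it
    per copy so each position of the original sequence can be compared with
    its monomer prediction.
    """

    monomer: DisorderPrediction
    tandem: DisorderPrediction
    copies: tuple[DisorderPrediction, DisorderPrediction]


def _slice_prediction(pred: DisorderPrediction, start: int, stop: int) -> DisorderPrediction:
    labels = pred.labels[start:stop]
    return DisorderPrediction(
        sequence=pred.sequence[start:stop],
        raw_counts=pred.raw_counts[start:stop],
        smoothed_counts=pred.smoothed_counts[start:stop],
        probability=pred.probability[start:stop],
        labels=labels,
        segments=segments_from_labels(labels),
        theta=pred.theta,
    )


def tandem_predict(
    sequence: str,
    table: AvgDistanceTable,
    curve: DisorderCurve,
    C: float = DEFAULT_C,
    theta: float = DEFAULT_THETA,
    band: tuple[int, int] = DEFAULT_BAND,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> TandemPrediction:
    """Predict on the monomer and on the sequence concatenated with itself."""
    sequence = getattr(sequence, "residues", sequence)
    kwargs = dict(C=C, theta=theta, band=band, half_width=half_width)
    monomer = predict(sequence, table, curve, **kwargs)
    tandem = predict(sequence + sequence, table, curve, **kwargs)
    N = len(sequence)
    copies = (_slice_prediction(tandem, 0, N), _slice_prediction(tandem, N, 2 * N))
    return TandemPrediction(monomer=monomer, tandem=tandem, copies=copies)
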