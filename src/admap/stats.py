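"""Inter-residue average distance statistics from Cα coordinates.

The statistics table records, for every unordered pair of amino-acid types
and every sequence-separation range M, the mean Cα–Cα distance observed in a
set of 3D structures and the number of observations behind that mean.  Ranges
pool separations k = |i - j|: M = 1 covers 1 <= k <= 8, M = 2 covers
9 <= k <= 20, and M >= 3 covers the decades 10M - 9 <= k <= 10M.  An entry is
"statistically significant" when its observation count reaches ``min_count``.

The table is the only structural knowledge the predictive side of the package
consumes: average distance maps are built from it and the query sequence
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateTraceError,
    EmptyInputError,
    InvalidSeparationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical ordering of the 20 standard amino acids (one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Default calibration constant matching the 15-Å real-distance-map density.
DEFAULT_C = 36.12
DEFAULT_MIN_COUNT = 10
DEFAULT_MAX_M = 9
DEFAULT_RDM_CUTOFF = 15.0


def encode_sequence(sequence: str, allow_x: bool = False) -> np.ndarray:
    """Map a one-letter sequence to integer indices into :data:`AA_ORDER`.

    With ``allow_x`` the placeholder X is encoded as -1 (an unplottable
    residue that never carries table statistics); any other non-standard
    letter raises :class:`SequenceError`.
    """
    from .errors import SequenceError

    idx = np.empty(len(sequence), dtype=np.int64)
    for pos, letter in enumerate(sequence.upper()):
        if letter in AA_INDEX:
            idx[pos] = AA_INDEX[letter]
        elif letter == "X" and allow_x:
            idx[pos] = -1
        else:
            raise SequenceError(
                f"non-standard residue letter {letter!r} at position {pos + 1}"
            )
    return idx


def range_bounds(M: int) -> tuple[int, int]:
    """Inclusive separation bounds (k_min, k_max) of range M."""
    if M < 1:
        raise InvalidSeparationError(f"range index must be >= 1, got {M}")
    if M == 1:
        return 1, 8
    if M == 2:
        return 9, 20
    return 10 * M - 9, 10 * M


def range_index(k: int, max_M: int = DEFAULT_MAX_M) -> int | None:
    """Range index M containing separation k, or None beyond ``max_M``.

    Raises :class:`InvalidSeparationError` for k < 1: a residue paired with
    itself has no separation range.
    """
    if k < 1:
        raise InvalidSeparationError(f"sequence separation must be >= 1, got {k}")
    M = 1 if k <= 8 else 2 if k <= 20 else (k + 9) // 10
    return None if M > max_M else M


def _range_index_array(k: np.ndarray) -> np.ndarray:
    """Vectorised :func:`range_index` without the max_M cut (k >= 1 assumed)."""
    return np.where(k <= 8, 1, np.where(k <= 20, 2, (k + 9) // 10))


@dataclass(frozen=True)
class CaTrace:
    """An ordered Cα trace: one-letter codes plus coordinates in Å.

    Only the 20 standard amino acids are admitted; parsers drop anything else
    before constructing the trace.
    """

    id: str
    codes: str
    coords: np.ndarray  # shape (N, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.codes) < 2:
            raise DegenerateTraceError(
                f"trace {self.id!r} has {len(self.codes)} residues; need >= 2"
            )
        if coords.shape != (len(self.codes), 3):
            raise ValidationError(
                f"trace {self.id!r}: coords shape {coords.shape} does not match "
                f"{len(self.codes)} residues"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"trace {self.id!r} has non-finite coordinates")
        bad = sorted({c for c in self.codes if c not in AA_INDEX})
        if bad:
            raise ValidationError(
                f"trace {self.id!r} contains non-standard codes {bad!r}"
            )

    @property
    def length(self) -> int:
        return len(self.codes)


@dataclass
class AvgDistanceTable:
    """Mean Cα–Cα distance and observation count per (pair, range).

    Storage is dense and symmetric: ``mean[a, b, M-1]`` equals
    ``mean[b, a, M-1]`` for amino-acid indices a, b and range M.  Cells never
    observed hold count 0 and mean NaN.
    """

    mean: np.ndarray  # (20, 20, max_M) float, NaN where count == 0
    count: np.ndarray  # (20, 20, max_M) int
    min_count: int = DEFAULT_MIN_COUNT

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.mean.shape != self.count.shape or self.mean.shape[:2] != (20, 20):
            raise ValidationError("table arrays must both have shape (20, 20, max_M)")
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")
        if np.any(self.count < 0):
            raise ValidationError("observation counts must be non-negative")
        observed = self.count > 0
        if np.any(self.mean[observed] <= 0):
            raise ValidationError("observed mean distances must be positive")

    @property
    def max_M(self) -> int:
        return self.mean.shape[2]

    @property
    def significant(self) -> np.ndarray:
        """Boolean mask of entries with count >= min_count."""
        return self.count >= self.min_count

    def lookup(self, a: str, b: str, M: int) -> tuple[float, int]:
        """(mean distance, count) for an unordered pair of one-letter codes."""
        ia, ib = AA_INDEX[a.upper()], AA_INDEX[b.upper()]
        if not 1 <= M <= self.max_M:
            raise InvalidSeparationError(f"range {M} outside 1..{self.max_M}")
        return float(self.mean[ia, ib, M - 1]), int(self.count[ia, ib, M - 1])

    def is_significant(self, a: str, b: str, M: int) -> bool:
        return self.lookup(a, b, M)[1] >= self.min_count


def build_table(
    traces,
    min_count: int = DEFAULT_MIN_COUNT,
    max_M: int = DEFAULT_MAX_M,
) -> AvgDistanceTable:
    """Pool Cα–Cα distances from a structure set into an average table.

    For every residue pair (i, j) of every trace with separation k = j - i
    inside some range M <= max_M, the Euclidean Cα distance contributes to the
    (type pair, M) cell.  Pairs are pooled without order, so the result is
    symmetric in the two amino-acid types, and pooling is over raw distances
    (each pair weighted once), not over per-k sub-means.
    """
    traces = list(traces)
    if not traces:
        raise EmptyInputError("cannot build a distance table from zero traces")
    dist_sum = np.zeros((20, 20, max_M), dtype=float)
    n_obs = np.zeros((20, 20, max_M), dtype=np.int64)
    for trace in traces:
        idx = encode_sequence(trace.codes)
        i, j = np.triu_indices(trace.length, k=1)
        k = j - i
        M = _range_index_array(k)
        keep = M <= max_M
        i, j, M = i[keep], j[keep], M[keep]
        d = np.linalg.norm(trace.coords[i] - trace.coords[j], axis=1)
        lo = np.minimum(idx[i], idx[j])
        hi = np.maximum(idx[i], idx[j])
        np.add.at(dist_sum, (lo, hi, M - 1), d)
        np.add.at(n_obs, (lo, hi, M - 1), 1)
    # Accumulation used canonical (lo <= hi) cells; mirror to full symmetry.
    dist_sum = dist_sum + dist_sum.transpose(1, 0, 2)
    n_obs = n_obs + n_obs.transpose(1, 0, 2)
    diag = np.arange(20)
    dist_sum[diag, diag, :] /= 2.0
    n_obs[diag, diag, :] //= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_obs > 0, dist_sum / n_obs, np.nan)
    return AvgDistanceTable(mean=mean, count=n_obs, min_count=min_count)


def merge_tables(first: AvgDistanceTable, second: AvgDistanceTable) -> AvgDistanceTable:
    """Count-weighted merge of two tables built from disjoint structure sets."""
    if first.max_M != second.max_M:
        raise ValidationError("cannot merge tables with different max_M")
    count = first.count + second.count
    total = np.where(first.count > 0, first.mean * first.count, 0.0) + np.where(
        second.count > 0, second.mean * second.count, 0.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    return AvgDistanceTable(mean=mean, count=count, min_count=first.min_count)


def rdm_density(trace: CaTrace, cutoff: float = DEFAULT_RDM_CUTOFF) -> float:
    """Whole-map plot density of the real distance map at a cutoff.

    The RDM marks every residue pair (k >= 1) whose Cα distance is strictly
    below the cutoff; the density divides by the N(N-1)/2 upper-triangle
    cells.  With the default 15 Å cutoff this is the quantity the ADM
    calibration constant C reproduces on average.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    N = trace.length
    if N < 2:
        raise DegenerateTraceError("RDM density needs at least two residues")
    i, j = np.triu_indices(N, k=1)
    d = np.linalg.norm(trace.coords[i] - trace.coords[j], axis=1)
    return float(np.count_nonzero(d < cutoff) / (N * (N - 1) / 2))
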