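"""Synthetic fixtures: toy Cα traces, statistics tables, annotated sequences.

Everything here is seeded and pure: identical arguments always return
identical objects.  The generators reproduce only the statistical contrasts
the method consumes —

* toy chains (straight / helical / collapsed) with realistic local geometry
  for the distance-statistics oracle tests;
* hand-set statistics tables: a ``uniform`` table where every pair is
  significant (exact density-calibration oracles) and a ``two-class`` table
  where pairs of "order-prone" residues carry short average distances, so
  sequences rich in those letters accumulate ADM plots the way ordered,
  hydrophobic-rich regions do in real statistics;
* annotated sequence sets whose disordered labels are Bernoulli draws from
  a known monotone disorder-probability law applied to the realized smoothed
  plot counts, giving calibration a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adm import build_adm
from .disorder import DEFAULT_BAND, DEFAULT_HALF_WIDTH, residue_plot_counts, segments_from_labels
from .errors import ValidationError
from .evaluate import IntervalAnnotation
from .stats import AA_INDEX, AA_ORDER, DEFAULT_C, AvgDistanceTable, CaTrace

#: Hydrophobic, plot-prone letters used by the two-class table.
ORDER_PRONE = "ACFILMVWY"
DISORDER_PRONE = "".join(a for a in AA_ORDER if a not in ORDER_PRONE)

CHAIN_KINDS = ("straight", "helix", "collapsed")


def make_chain(kind: str, N: int, seed: int = 0, codes: str | None = None) -> CaTrace:
    """Generate a toy Cα trace.

    straight: colinear residues at 3.8 Å spacing (closed-form distances);
    helix: ideal alpha-helix (rise 1.5 Å, 100 degree twist, radius 2.3 Å);
    collapsed: a seeded 3.8-Å random walk rescaled into a sphere of radius
    3.0 * N^(1/3) Å, mimicking globular compactness.
    """
    if N < 2:
        raise ValidationError(f"chain length must be >= 2, got {N}")
    rng = np.random.default_rng(seed)
    if kind == "straight":
        coords = np.zeros((N, 3))
        coords[:, 0] = 3.8 * np.arange(N)
    elif kind == "helix":
        theta = np.deg2rad(100.0) * np.arange(N)
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(N)]
        )
    elif kind == "collapsed":
        steps = rng.normal(size=(N - 1, 3))
        steps *= 3.8 / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        coords -= coords.mean(axis=0)
        radius = np.linalg.norm(coords, axis=1).max()
        coords *= 3.0 * N ** (1 / 3) / max(radius, 1e-9)
    else:
        raise ValidationError(f"unknown chain kind {kind!r}; use one of {CHAIN_KINDS}")
    if codes is None:
        codes = "".join(rng.choice(list(AA_ORDER), size=N))
    if len(codes) != N:
        raise ValidationError("codes length must equal N")
    return CaTrace(id=f"synthetic-{kind}-{N}-{seed}", codes=codes, coords=coords)


def make_table(
    profile: str = "uniform",
    seed: int = 0,
    min_count: int = 10,
    max_M: int = 9,
) -> AvgDistanceTable:
    """Hand-set statistics tables for oracle tests and synthetic calibration.

    uniform: every (pair, range) cell is significant with a deterministic
    seeded spread of mean distances (all plots available everywhere, so the
    density calibration is exercised in isolation).  two-class: pairs where
    both residues are order-prone receive short mean distances, all other
    pairs long ones; per-range quantile selection then concentrates plots on
    order-prone segments.
    """
    rng = np.random.default_rng(seed)
    base = 5.0 + 1.5 * np.arange(1, max_M + 1)  # longer ranges, longer distances
    jitter = rng.uniform(0.0, 1.0, size=(20, 20, max_M))
    jitter = (jitter + jitter.transpose(1, 0, 2)) / 2.0
    if profile == "uniform":
        mean = base[None, None, :] + jitter
    elif profile == "two-class":
        prone = np.array([a in ORDER_PRONE for a in AA_ORDER])
        both_prone = prone[:, None] & prone[None, :]
        short = 6.0 + 2.0 * jitter
        long_ = 18.0 + 4.0 * jitter
        mean = np.where(both_prone[:, :, None], short, long_) + 0.5 * base[None, None, :]
    else:
        raise ValidationError(f"unknown table profile {profile!r}")
    count = np.full((20, 20, max_M), min_count, dtype=np.int64)
    return AvgDistanceTable(mean=mean, count=count, min_count=min_count)


def make_plot_map(
    N: int,
    density: float,
    seed: int = 0,
    blocks: list[tuple[int, int]] | None = None,
    block_density: float = 0.0,
) -> np.ndarray:
    """Random upper-triangle plot set: Bernoulli background plus dense blocks.

    Cells with both endpoints inside a block [a, b] (1-based inclusive) are
    plotted with ``block_density`` instead of the background ``density``.
    Returns an (n, 2) array of 1-based pairs.
    """
    rng = np.random.default_rng(seed)
    i, j = np.triu_indices(N, k=1)
    i, j = i + 1, j + 1
    p = np.full(i.shape, density)
    for a, b in blocks or []:
        inside = (i >= a) & (j <= b)
        p[inside] = block_density
    keep = rng.random(i.shape) < p
    return np.column_stack([i[keep], j[keep]])


@dataclass(frozen=True)
class SyntheticLaw:
    """A known monotone non-increasing disorder-probability law.

    The law maps a smoothed plot count c to the probability that the residue
    is disordered: a logistic decay ceiling / (1 + exp((c - midpoint) /
    steepness)), or a hard step when ``steepness`` is 0.  Generated labels
    are Bernoulli draws from the law applied to realized counts.
    """

    midpoint: float = 12.0
    steepness: float = 2.0
    ceiling: float = 1.0
    floor: float = 0.0
    seed: int = 0

    def __call__(self, counts) -> np.ndarray:
        c = np.asarray(counts, dtype=float)
        if self.steepness == 0:
            p = np.where(c < self.midpoint, self.ceiling, self.floor)
        else:
            p = self.floor + (self.ceiling - self.floor) / (
                1.0 + np.exp((c - self.midpoint) / self.steepness)
            )
        return np.clip(p, 0.0, 1.0)

    @classmethod
    def step(cls, midpoint: float, seed: int = 0) -> "SyntheticLaw":
        return cls(midpoint=midpoint, steepness=0.0, seed=seed)


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (uppercase one-letter codes, X allowed)."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        bad = sorted({c for c in self.residues if c not in AA_INDEX and c != "X"})
        if bad:
            raise ValidationError(f"record {self.id!r} contains letters {bad!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _compose_sequence(rng: np.random.Generator, N: int) -> str:
    """Alternating order-prone / disorder-prone segments of seeded lengths."""
    letters: list[str] = []
    prone = bool(rng.integers(2))
    while len(letters) < N:
        seg_len = int(rng.integers(30, 61))
        pool_main = ORDER_PRONE if prone else DISORDER_PRONE
        pool_alt = DISORDER_PRONE if prone else ORDER_PRONE
        for _ in range(min(seg_len, N - len(letters))):
            pool = pool_main if rng.random() < 0.95 else pool_alt
            letters.append(pool[rng.integers(len(pool))])
        prone = not prone
    return "".join(letters)


def make_annotated_set(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 199),
    law: SyntheticLaw | None = None,
    seed: int = 0,
    table: AvgDistanceTable | None = None,
    C: float = DEFAULT_C,
    band: tuple[int, int] = DEFAULT_BAND,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[tuple[SequenceRecord, IntervalAnnotation]]:
    """Annotated sequences whose labels follow a known probability law.

    Each sequence alternates order-prone and disorder-prone compositional
    segments (so its smoothed ADM plot counts spread over a wide range);
    per-residue disordered labels are Bernoulli draws from ``law`` applied
    to the realized smoothed counts, and annotations record the maximal
    label runs as disordered/ordered intervals tiling the chain.
    """
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    law = law or SyntheticLaw()
    table = table if table is not None else make_table("two-class", seed=seed)
    rng = np.random.default_rng(seed)
    out: list[tuple[SequenceRecord, IntervalAnnotation]] = []
    for p in range(n_proteins):
        N = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _compose_sequence(rng, N)
        adm = build_adm(seq, table, C)
        counts = residue_plot_counts(adm, *band, half_width=half_width)
        pi = law(counts.smoothed)
        labels = rng.random(N) < pi
        disordered = segments_from_labels(labels)
        ordered = segments_from_labels(~labels)
        record = SequenceRecord(id=f"synth{p:03d}", description="synthetic", residues=seq)
        ann = IntervalAnnotation(
            protein_id=record.id, length=N, disordered=disordered, ordered=ordered
        )
        out.append((record, ann))
    return out
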