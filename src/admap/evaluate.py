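"""Residue-level evaluation of disorder predictions against annotations.

Annotations are 1-based inclusive intervals labelled disordered or ordered
(DisProt/IDEAL style).  Residues covered by neither label are unannotated
and excluded from scoring rather than assumed ordered.  Two accuracies are
reported, with disordered as the positive class:

    ACCp = (TP + TN) / (TP + TN + FP + FN)
    ACCw = 1/2 * (TP / (TP + FN) + TN / (TN + FP))

ACCp is the plain per-residue accuracy; ACCw balances sensitivity on the
disordered class against specificity on the ordered class, which matters
when a protein is mostly one or the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class IntervalAnnotation:
    """Ordered/disordered interval labels over one protein sequence."""

    protein_id: str
    length: int
    disordered: tuple[tuple[int, int], ...] = ()
    ordered: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "disordered", tuple((int(s), int(e)) for s, e in self.disordered)
        )
        object.__setattr__(
            self, "ordered", tuple((int(s), int(e)) for s, e in self.ordered)
        )
        if self.length < 1:
            raise ValidationError("annotation length must be >= 1")
        covered = np.zeros(self.length, dtype=bool)
        for label, ivals in (("disordered", self.disordered), ("ordered", self.ordered)):
            for s, e in ivals:
                if not (1 <= s <= e <= self.length):
                    raise ValidationError(
                        f"{self.protein_id}: {label} interval ({s}, {e}) outside "
                        f"1..{self.length}"
                    )
                if covered[s - 1 : e].any():
                    raise ValidationError(
                        f"{self.protein_id}: overlapping annotation at ({s}, {e})"
                    )
                covered[s - 1 : e] = True

    def label_array(self) -> np.ndarray:
        """Per-residue labels: 1 disordered, 0 ordered, -1 unannotated."""
        lab = np.full(self.length, -1, dtype=np.int8)
        for s, e in self.ordered:
            lab[s - 1 : e] = 0
        for s, e in self.disordered:
            lab[s - 1 : e] = 1
        return lab

    @property
    def n_disordered(self) -> int:
        return sum(e - s + 1 for s, e in self.disordered)

    @property
    def n_ordered(self) -> int:
        return sum(e - s + 1 for s, e in self.ordered)


@dataclass(frozen=True)
class ConfusionCounts:
    """Residue-level confusion counts; disordered is the positive class."""

    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            TP=self.TP + other.TP,
            FN=self.FN + other.FN,
            TN=self.TN + other.TN,
            FP=self.FP + other.FP,
        )

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def confusion(predicted_disordered, annotation: IntervalAnnotation) -> ConfusionCounts:
    """Count TP/FN/TN/FP over the annotated residues of one protein.

    ``predicted_disordered`` is a length-N boolean array (or a
    DisorderPrediction, whose labels are used).
    """
    labels = getattr(predicted_disordered, "labels", predicted_disordered)
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != annotation.length:
        raise ValidationError(
            f"{annotation.protein_id}: prediction length {len(labels)} != "
            f"annotation length {annotation.length}"
        )
    truth = annotation.label_array()
    scored = truth >= 0
    pos = truth == 1
    return ConfusionCounts(
        TP=int(np.count_nonzero(labels & pos & scored)),
        FN=int(np.count_nonzero(~labels & pos & scored)),
        TN=int(np.count_nonzero(~labels & (truth == 0))),
        FP=int(np.count_nonzero(labels & (truth == 0))),
    )


def acc_p(c: ConfusionCounts) -> float:
    """Plain accuracy (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("ACCp is undefined on zero scored residues")
    return (c.TP + c.TN) / c.total


def acc_w(c: ConfusionCounts) -> float:
    """Balanced accuracy: mean of sensitivity and specificity."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise UndefinedMetricError(
            "ACCw needs at least one residue of each annotated class"
        )
    return 0.5 * (c.TP / (c.TP + c.FN) + c.TN / (c.TN + c.FP))


@dataclass(frozen=True)
class SweepResult:
    """Pooled ACCp/ACCw over a threshold grid, with the argmax thresholds."""

    thetas: np.ndarray
    acc_p: np.ndarray
    acc_w: np.ndarray
    counts: list[ConfusionCounts] = field(repr=False, default_factory=list)

    @property
    def best_theta_accp(self) -> float:
        return float(self.thetas[int(np.argmax(self.acc_p))])

    @property
    def best_theta_accw(self) -> float:
        return float(self.thetas[int(np.argmax(self.acc_w))])


def threshold_sweep(entries, thetas) -> SweepResult:
    """Micro-averaged ACCp/ACCw across proteins over a threshold grid.

    ``entries`` is an iterable of (per-residue probability array,
    IntervalAnnotation); at each theta, residues with probability >= theta
    are predicted disordered, confusion counts are pooled over all proteins,
    and both accuracies are computed from the pooled counts.
    """
    entries = [(np.asarray(p, dtype=float), ann) for p, ann in entries]
    if not entries:
        raise ValidationError("threshold sweep needs at least one protein")
    thetas = np.asarray(thetas, dtype=float)
    accp = np.empty(len(thetas))
    accw = np.empty(len(thetas))
    pooled_counts = []
    for t_idx, theta in enumerate(thetas):
        pooled = ConfusionCounts()
        for prob, ann in entries:
            pooled = pooled + confusion(prob >= theta, ann)
        pooled_counts.append(pooled)
        accp[t_idx] = acc_p(pooled)
        accw[t_idx] = acc_w(pooled)
    return SweepResult(thetas=thetas, acc_p=accp, acc_w=accw, counts=pooled_counts)
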