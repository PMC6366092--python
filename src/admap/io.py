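"""Readers and writers for every external format the package touches.

Sequences come in as FASTA, structures as PDB (Cα records only), and all
tabular artifacts — the statistics table, ADM plot lists, scanning profiles,
compact regions, disorder predictions, interval annotations, calibration
curves and evaluation reports — travel as TSV with strict headers.  Files
whose payload needs companion metadata (the ADM, the calibration curve)
carry it in leading ``#``-comment lines holding a JSON object, so each file
stays a single self-describing text artifact.  Every writer/reader pair
round-trips exactly on valid data.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .adm import ADM
from .disorder import DisorderCurve, DisorderPrediction
from .errors import EmptyInputError, ParseError, ValidationError
from .evaluate import ConfusionCounts, IntervalAnnotation
from .scan import CompactRegion, ScanProfile
from .stats import AA_INDEX, AvgDistanceTable, CaTrace
from .synthetic import SequenceRecord

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


# ---------------------------------------------------------------- sequences
def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    for line_no, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}:{line_no}: expected a '>' header line")
            break
    records = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id, description=rec.description, residues=str(rec.seq).upper()
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# --------------------------------------------------------------- structures
def read_pdb_ca(path, chain: str | None = None) -> CaTrace:
    """Extract the Cα trace of one chain from a PDB file.

    Only the first model is read; the first chain is used unless ``chain``
    names another.  Residues lacking a Cα, with insertion codes, or with
    non-standard names are skipped with a logged warning.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyInputError(f"{path}: no models in file") from None
    chains = {c.id: c for c in model}
    if chain is None:
        selected = next(iter(chains.values()), None)
    else:
        selected = chains.get(chain)
    if selected is None:
        raise ValidationError(
            f"{path}: chain {chain!r} not found (available: {sorted(chains)})"
        )
    codes: list[str] = []
    coords: list[np.ndarray] = []
    for res in selected:
        hetflag, _, icode = res.id
        if hetflag != " ":
            continue
        if icode != " ":
            logger.warning("%s: skipping residue %s with insertion code", path, res.id)
            continue
        one = _THREE_TO_ONE.get(res.get_resname().upper())
        if one is None:
            logger.warning(
                "%s: skipping non-standard residue %s", path, res.get_resname()
            )
            continue
        if "CA" not in res:
            logger.warning("%s: residue %s has no Calpha atom", path, res.id)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            # keep the ' '/'A' alternate location only
            children = {a.get_altloc(): a for a in atom.disordered_get_list()}
            atom = children.get("A") or children.get(" ")
            if atom is None:
                logger.warning("%s: residue %s has no A/blank altloc", path, res.id)
                continue
        codes.append(one)
        coords.append(atom.get_coord())
    if not codes:
        raise EmptyInputError(f"{path}: selected chain contains no usable Calpha atoms")
    return CaTrace(
        id=f"{path.stem}:{selected.id}", codes="".join(codes), coords=np.array(coords)
    )


# ---------------------------------------------------------------- TSV plumbing
def _read_tsv(path, required: list[str], meta_key: str | None = None):
    """Read a TSV with optional leading '# <meta_key>: {json}' lines."""
    path = Path(path)
    meta = None
    lines = path.read_text().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        if meta_key and line.startswith(f"# {meta_key}:"):
            meta = json.loads(line.split(":", 1)[1])
    body = "\n".join(lines[body_start:])
    if not body.strip():
        df = pd.DataFrame(columns=required)
    else:
        df = pd.read_csv(_stdio.StringIO(body), sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if meta_key and meta is None:
        raise ParseError(f"{path}: missing '# {meta_key}:' metadata block")
    return (df, meta) if meta_key else df


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None, meta_key: str = "meta"):
    path = Path(path)
    with path.open("w") as fh:
        if meta is not None:
            fh.write(f"# {meta_key}: {json.dumps(meta, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------- statistics table
def write_table(table: AvgDistanceTable, path) -> None:
    """One row per unordered residue pair per range: aa1 <= aa2."""
    rows = []
    from .stats import AA_ORDER

    for ia, a in enumerate(AA_ORDER):
        for ib in range(ia, 20):
            b = AA_ORDER[ib]
            for m in range(table.max_M):
                c = int(table.count[ia, ib, m])
                if c > 0:
                    rows.append((a, b, m + 1, float(table.mean[ia, ib, m]), c))
    df = pd.DataFrame(rows, columns=["aa1", "aa2", "M", "mean_distance", "count"])
    meta = {"format": "admap-table-v1", "min_count": table.min_count, "max_M": table.max_M}
    _write_tsv(df, path, meta)


def read_table(path) -> AvgDistanceTable:
    df, meta = _read_tsv(path, ["aa1", "aa2", "M", "mean_distance", "count"], "meta")
    max_M = int(meta["max_M"])
    mean = np.full((20, 20, max_M), np.nan)
    count = np.zeros((20, 20, max_M), dtype=np.int64)
    for row in df.itertuples(index=False):
        ia, ib = AA_INDEX[row.aa1], AA_INDEX[row.aa2]
        m = int(row.M) - 1
        mean[ia, ib, m] = mean[ib, ia, m] = float(row.mean_distance)
        count[ia, ib, m] = count[ib, ia, m] = int(row.count)
    return AvgDistanceTable(mean=mean, count=count, min_count=int(meta["min_count"]))


# ---------------------------------------------------------------- ADM
def write_adm(adm: ADM, path) -> None:
    df = pd.DataFrame(
        {
            "i": adm.plots[:, 0],
            "j": adm.plots[:, 1],
            "M": adm.plot_M,
            "mean_distance": adm.plot_dist,
        }
    )
    meta = {
        "format": "admap-adm-v1",
        "sequence": adm.sequence,
        "C": adm.C,
        "D": adm.D,
        "thresholds": {str(k): v for k, v in adm.thresholds.items()},
        "significant_pairs": {str(k): v for k, v in adm.significant_pairs.items()},
        "plot_counts": {str(k): v for k, v in adm.plot_counts.items()},
    }
    _write_tsv(df, path, meta)


def read_adm(path) -> ADM:
    df, meta = _read_tsv(path, ["i", "j", "M", "mean_distance"], "meta")
    return ADM(
        sequence=meta["sequence"],
        plots=np.column_stack([df["i"].to_numpy(np.int64), df["j"].to_numpy(np.int64)])
        if len(df)
        else np.empty((0, 2), dtype=np.int64),
        plot_M=df["M"].to_numpy(np.int64),
        plot_dist=df["mean_distance"].to_numpy(float),
        thresholds={int(k): float(v) for k, v in meta["thresholds"].items()},
        D=float(meta["D"]),
        C=float(meta["C"]),
        significant_pairs={int(k): int(v) for k, v in meta["significant_pairs"].items()},
        plot_counts={int(k): int(v) for k, v in meta["plot_counts"].items()},
    )


# ---------------------------------------------------------------- scan outputs
def write_profile(profile: ScanProfile, path) -> None:
    df = pd.DataFrame(
        {
            "i": np.arange(1, profile.N + 1),
            "delta_h": profile.delta_h,
            "delta_v": profile.delta_v,
        }
    )
    _write_tsv(df, path, {"format": "admap-profile-v1", "N": profile.N})


def write_regions(regions: list[CompactRegion], path) -> None:
    df = pd.DataFrame(
        [(r.start, r.end, r.eta) for r in regions], columns=["start", "end", "eta"]
    )
    _write_tsv(df, path, {"format": "admap-regions-v1"})


def read_regions(path) -> list[CompactRegion]:
    df, _ = _read_tsv(path, ["start", "end", "eta"], "meta")
    return [
        CompactRegion(
            start=int(r.start), end=int(r.end), eta=float(r.eta),
            peak_h=float("nan"), peak_v=float("nan"),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- predictions
def write_prediction(pred: DisorderPrediction, path, protein_id: str = "") -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(1, pred.N + 1),
            "residue": list(pred.sequence),
            "raw_count": pred.raw_counts,
            "smoothed_count": pred.smoothed_counts,
            "probability": pred.probability,
            "label": np.where(pred.labels, "disordered", "ordered"),
        }
    )
    meta = {
        "format": "admap-prediction-v1",
        "protein_id": protein_id,
        "theta": pred.theta,
    }
    _write_tsv(df, path, meta)


def read_prediction(path) -> tuple[DisorderPrediction, str]:
    df, meta = _read_tsv(
        path,
        ["index", "residue", "raw_count", "smoothed_count", "probability", "label"],
        "meta",
    )
    labels = (df["label"] == "disordered").to_numpy()
    from .disorder import segments_from_labels

    pred = DisorderPrediction(
        sequence="".join(df["residue"]),
        raw_counts=df["raw_count"].to_numpy(np.int64),
        smoothed_counts=df["smoothed_count"].to_numpy(float),
        probability=df["probability"].to_numpy(float),
        labels=labels,
        segments=segments_from_labels(labels),
        theta=float(meta["theta"]),
    )
    return pred, meta["protein_id"]


def write_intervals(items, path) -> None:
    """DisProt-like interval list: (protein_id, start, end, label) rows."""
    df = pd.DataFrame(items, columns=["protein_id", "start", "end", "label"])
    _write_tsv(df, path, {"format": "admap-intervals-v1"})


def prediction_intervals(pred: DisorderPrediction, protein_id: str):
    return [(protein_id, s, e, "disordered") for s, e in pred.segments]


# ---------------------------------------------------------------- annotations
def write_annotations(annotations, path) -> None:
    rows = []
    for ann in annotations:
        for s, e in ann.disordered:
            rows.append((ann.protein_id, s, e, "disordered", ann.length))
        for s, e in ann.ordered:
            rows.append((ann.protein_id, s, e, "ordered", ann.length))
    df = pd.DataFrame(rows, columns=["protein_id", "start", "end", "label", "length"])
    _write_tsv(df, path, {"format": "admap-annotations-v1"})


def read_annotations(path) -> list[IntervalAnnotation]:
    df, _ = _read_tsv(path, ["protein_id", "start", "end", "label", "length"], "meta")
    out = []
    for pid, group in df.groupby("protein_id", sort=False):
        lengths = set(group["length"].astype(int))
        if len(lengths) != 1:
            raise ValidationError(f"{path}: inconsistent lengths for {pid!r}")
        bad = set(group["label"]) - {"disordered", "ordered"}
        if bad:
            raise ValidationError(f"{path}: unknown labels {sorted(bad)} for {pid!r}")
        out.append(
            IntervalAnnotation(
                protein_id=str(pid),
                length=lengths.pop(),
                disordered=tuple(
                    (int(r.start), int(r.end))
                    for r in group.itertuples(index=False)
                    if r.label == "disordered"
                ),
                ordered=tuple(
                    (int(r.start), int(r.end))
                    for r in group.itertuples(index=False)
                    if r.label == "ordered"
                ),
            )
        )
    return out


# ---------------------------------------------------------------- calibration curve
def write_curve(curve: DisorderCurve, path) -> None:
    df = pd.DataFrame(
        {
            "count": curve.bin_counts,
            "n_residues": curve.bin_n,
            "fraction_disordered": curve.bin_fraction,
        }
    )
    meta = {
        "format": "admap-curve-v1",
        "coefficients": list(map(float, curve.coefficients)),
        "domain": list(curve.domain),
    }
    _write_tsv(df, path, meta)


def read_curve(path) -> DisorderCurve:
    df, meta = _read_tsv(path, ["count", "n_residues", "fraction_disordered"], "meta")
    if meta.get("format") != "admap-curve-v1":
        raise ParseError(f"{path}: unsupported curve format {meta.get('format')!r}")
    return DisorderCurve(
        bin_counts=df["count"].to_numpy(np.int64),
        bin_n=df["n_residues"].to_numpy(np.int64),
        bin_fraction=df["fraction_disordered"].to_numpy(float),
        coefficients=np.array(meta["coefficients"], dtype=float),
        domain=tuple(meta["domain"]),
    )


# ---------------------------------------------------------------- evaluation report
def write_report(per_protein: dict[str, ConfusionCounts], path) -> None:
    """Per-protein confusion rows plus a micro-averaged pooled summary row."""
    from .evaluate import acc_p, acc_w

    def _metrics(c: ConfusionCounts):
        try:
            p = acc_p(c)
        except Exception:
            p = float("nan")
        try:
            w = acc_w(c)
        except Exception:
            w = float("nan")
        return p, w

    rows = []
    pooled = ConfusionCounts()
    for pid, c in per_protein.items():
        pooled = pooled + c
        p, w = _metrics(c)
        rows.append((pid, c.TP, c.FN, c.TN, c.FP, p, w))
    p, w = _metrics(pooled)
    rows.append(("POOLED", pooled.TP, pooled.FN, pooled.TN, pooled.FP, p, w))
    df = pd.DataFrame(
        rows, columns=["protein_id", "TP", "FN", "TN", "FP", "acc_p", "acc_w"]
    )
    _write_tsv(df, path, {"format": "admap-report-v1"})
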