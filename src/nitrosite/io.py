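"""Sequence and annotation I/O: FASTA reading, window extraction, labelling,
flank deduplication and prediction-table output.

A *site window* is a fixed odd-length peptide centered on a candidate
modified residue (Y, W or C); flanks that run past the protein termini are
padded with the gap symbol ``-``.  Positions are 1-based everywhere
user-facing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from Bio import SeqIO

from .alphabet import GAP, MODIFIABLE, MODIFICATION_RESIDUE, sanitize_sequence

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence (uppercased, nonstandard residues gapped)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")


@dataclass(frozen=True)
class SiteWindow:
    """A fixed-length peptide centered on a candidate modified residue."""

    protein_id: str
    center_position: int  # 1-based index into the protein
    center_residue: str  # one of Y, W, C
    peptide: str  # length L over the 21-symbol alphabet
    label: str = "unknown"

    def __post_init__(self):
        L = len(self.peptide)
        if L % 2 != 1:
            raise ValueError(f"window length must be odd, got {L}")
        if self.center_residue not in MODIFIABLE:
            raise ValueError(f"center residue must be Y, W or C, got {self.center_residue!r}")
        if self.peptide[L // 2] != self.center_residue:
            raise ValueError(
                f"center symbol {self.peptide[L // 2]!r} does not match "
                f"center residue {self.center_residue!r}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.peptide)

    def core(self) -> str:
        """The peptide with terminal gap runs stripped."""
        return self.peptide.strip(GAP)


@dataclass
class LabeledDataset:
    """An ordered collection of same-length windows for one modification type."""

    windows: list[SiteWindow]
    modification_type: str
    window_length: int

    def __post_init__(self):
        residue = MODIFICATION_RESIDUE.get(self.modification_type)
        if residue is None:
            raise ValueError(
                f"unknown modification type {self.modification_type!r}; "
                f"expected one of {sorted(MODIFICATION_RESIDUE)}"
            )
        for w in self.windows:
            if w.length != self.window_length:
                raise ValueError(
                    f"window at {w.protein_id}:{w.center_position} has length "
                    f"{w.length}, expected {self.window_length}"
                )
            if w.center_residue != residue:
                raise ValueError(
                    f"window at {w.protein_id}:{w.center_position} centers on "
                    f"{w.center_residue}, expected {residue}"
                )

    @property
    def peptides(self) -> list[str]:
        return [w.peptide for w in self.windows]

    @property
    def labels(self) -> list[int]:
        """Binary labels: 1 positive, 0 otherwise."""
        return [1 if w.label == "positive" else 0 for w in self.windows]

    def n_positive(self) -> int:
        return sum(1 for w in self.windows if w.label == "positive")

    def n_negative(self) -> int:
        return sum(1 for w in self.windows if w.label == "negative")

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            [self.windows[i] for i in indices],
            self.modification_type,
            self.window_length,
        )


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased and nonstandard residues mapped to the gap
    symbol with a warning.  Record order is preserved; duplicate ids are an
    error.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def extract_windows(protein: ProteinRecord, residue: str, L: int) -> list[SiteWindow]:
    """Extract one L-length window per occurrence of ``residue`` in the protein.

    Flanks of (L-1)/2 on each side; positions beyond the termini are filled
    with the gap symbol.  Labels are set to ``unknown``.
    """
    if L % 2 != 1 or not (3 <= L <= 101):
        raise ValueError(f"window length must be odd and in [3, 101], got {L}")
    if residue not in MODIFIABLE:
        raise ValueError(f"residue must be one of Y, W, C, got {residue!r}")
    flank = (L - 1) // 2
    seq = protein.sequence
    padded = GAP * flank + seq + GAP * flank
    out = []
    for i, c in enumerate(seq):
        if c == residue:
            out.append(
                SiteWindow(
                    protein_id=protein.id,
                    center_position=i + 1,
                    center_residue=residue,
                    peptide=padded[i : i + L],
                )
            )
    return out


def label_windows(
    windows: list[SiteWindow],
    positives: set[tuple[str, int]],
    modification_type: str,
) -> LabeledDataset:
    """Label windows positive if their (protein_id, position) is annotated,
    negative otherwise.

    Every annotated position must correspond to an extracted window (i.e.
    point at the stated residue type); offending annotations are reported
    together.
    """
    if not windows:
        raise ValueError("no windows to label")
    L = windows[0].length
    index = {(w.protein_id, w.center_position) for w in windows}
    offenders = sorted(p for p in positives if p not in index)
    if offenders:
        raise ValueError(
            "annotations do not point at the stated residue type: "
            + ", ".join(f"{pid}:{pos}" for pid, pos in offenders)
        )
    labeled = [
        replace(
            w,
            label="positive"
            if (w.protein_id, w.center_position) in positives
            else "negative",
        )
        for w in windows
    ]
    return LabeledDataset(labeled, modification_type, L)


def dedup_exact_flank(dataset: LabeledDataset) -> LabeledDataset:
    """Drop windows whose exact peptide already occurred with the same label.

    Deduplication is stable (first occurrence wins) and independent per label
    class; a peptide present in both classes is retained in both, with a
    warning.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for w in dataset.windows:
        key = (w.peptide, w.label)
        if key in seen:
            continue
        seen.add(key)
        kept.append(w)
    by_peptide: dict[str, set[str]] = {}
    for w in kept:
        by_peptide.setdefault(w.peptide, set()).add(w.label)
    conflicts = [p for p, ls in by_peptide.items() if {"positive", "negative"} <= ls]
    if conflicts:
        logger.warning(
            "%d peptide(s) occur as both positive and negative; keeping both",
            len(conflicts),
        )
    return LabeledDataset(kept, dataset.modification_type, dataset.window_length)


def read_annotations(path) -> pd.DataFrame:
    """Read a site-annotation TSV with columns protein_id, position, residue, label."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "position": int, "residue": str, "label": int},
    )
    required = {"protein_id", "position", "residue", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {sorted(missing)}")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("annotation labels must be 0 or 1")
    return df


def positives_from_annotations(df: pd.DataFrame) -> set[tuple[str, int]]:
    pos = df[df["label"] == 1]
    return set(zip(pos["protein_id"], pos["position"]))


def write_predictions(rows, path) -> None:
    """Write a prediction table as TSV with a header.

    ``rows`` are (protein_id, position, residue, peptide, score, stringency)
    tuples; scores must be in [0, 1] and are serialized in fixed decimal
    notation.
    """
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tpeptide\tscore\tstringency\n")
        for pid, pos, res, pep, score, stringency in rows:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} outside [0, 1] at {pid}:{pos}")
            fh.write(f"{pid}\t{pos}\t{res}\t{pep}\t{score:.6f}\t{stringency}\n")


def build_dataset(
    records: list[ProteinRecord],
    annotations: pd.DataFrame,
    modification_type: str,
    L: int,
    dedup: bool = True,
) -> LabeledDataset:
    """FASTA records + annotation table -> deduplicated labeled dataset."""
    residue = MODIFICATION_RESIDUE[modification_type]
    windows: list[SiteWindow] = []
    for rec in records:
        windows.extend(extract_windows(rec, residue, L))
    ann = annotations[annotations["residue"] == residue]
    dataset = label_windows(windows, positives_from_annotations(ann), modification_type)
    if dedup:
        dataset = dedup_exact_flank(dataset)
    return dataset
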