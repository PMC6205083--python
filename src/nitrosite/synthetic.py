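"""Synthetic labeled peptide datasets with known ground truth.

Negatives draw every flank position iid from a background distribution
over the 20 natural residues (uniform by default, which makes null
calibration exact; a natural-composition preset is available).  Positives
are identical except at a small set of planted offsets, where with mixing
weight e the planted residue is emitted instead of a background draw —
mimicking the position-specific preferences (e.g. adjacent basic residues)
seen around real modification sites.  A fraction of windows is truncated
at a terminus with gap padding so the encoders' gap paths are exercised.

The generator defines the study conditions for every downstream check:
defaults are windows of length 41, 1000 windows per class, two planted
offsets at mixing weight 0.8, terminal-gap probability 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alphabet import AA20, GAP, MODIFICATION_RESIDUE, natural_background, uniform_background
from .encoders import PssmModel
from .io import LabeledDataset, SiteWindow


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults are the standard study conditions."""

    modification_type: str = "Y-nitration"
    L: int = 41
    n_pos: int = 1000
    n_neg: int = 1000
    background: np.ndarray | None = None  # over AA20; None = uniform
    enrichments: tuple[tuple[int, str, float], ...] = ((-1, "K", 0.8), (2, "R", 0.8))
    terminal_gap_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.modification_type not in MODIFICATION_RESIDUE:
            raise ValueError(f"unknown modification type {self.modification_type!r}")
        if self.L % 2 != 1 or not (3 <= self.L <= 101):
            raise ValueError("L must be odd and in [3, 101]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one window per class")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 probabilities summing to 1")
        flank = (self.L - 1) // 2
        for offset, residue, e in self.enrichments:
            if offset == 0 or abs(offset) > flank:
                raise ValueError(f"enrichment offset {offset} outside the flanks")
            if residue not in AA20:
                raise ValueError(f"enrichment residue {residue!r} not a natural residue")
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"mixing weight {e} outside [0, 1]")
        if not (0.0 <= self.terminal_gap_prob <= 1.0):
            raise ValueError("terminal_gap_prob must be a probability")

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return uniform_background()
        return np.asarray(self.background, dtype=float)


@dataclass
class GroundTruth:
    """The planted signal: every (offset, residue, mixing weight) cell."""

    spec: SyntheticSpec
    planted: tuple[tuple[int, str, float], ...]


def natural_spec(**overrides) -> SyntheticSpec:
    """A spec preset with Swiss-Prot background composition."""
    return SyntheticSpec(background=natural_background(), **overrides)


def _draw_window(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    positive: bool,
    index: int,
) -> SiteWindow:
    center_residue = MODIFICATION_RESIDUE[spec.modification_type]
    flank = (spec.L - 1) // 2
    bg = spec.background_vector()
    symbols = list("".join(rng.choice(list(AA20), size=spec.L, p=bg)))
    symbols[flank] = center_residue
    if positive:
        for offset, residue, e in spec.enrichments:
            if rng.random() < e:
                symbols[flank + offset] = residue
    left_gaps = 0
    if rng.random() < spec.terminal_gap_prob:
        run = int(rng.integers(1, flank + 1))
        if rng.random() < 0.5:
            symbols[:run] = [GAP] * run
            left_gaps = run
        else:
            symbols[spec.L - run :] = [GAP] * run
    label = "positive" if positive else "negative"
    return SiteWindow(
        protein_id=f"syn{'p' if positive else 'n'}{index:05d}",
        center_position=flank + 1 - left_gaps,
        center_residue=center_residue,
        peptide="".join(symbols),
        label=label,
    )


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a labeled dataset plus the record of its planted signal."""
    rng = np.random.default_rng(abs(int(spec.seed)) % (2**31))
    windows = [_draw_window(rng, spec, True, i) for i in range(spec.n_pos)]
    windows += [_draw_window(rng, spec, False, i) for i in range(spec.n_neg)]
    dataset = LabeledDataset(windows, spec.modification_type, spec.L)
    return dataset, GroundTruth(spec=spec, planted=tuple(spec.enrichments))


def shuffle_labels(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly permute the labels, destroying any sequence-label association."""
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    labels = [w.label for w in dataset.windows]
    perm = rng.permutation(len(labels))
    shuffled = [
        replace(w, label=labels[perm[i]]) for i, w in enumerate(dataset.windows)
    ]
    return LabeledDataset(shuffled, dataset.modification_type, dataset.window_length)


def ground_truth_sign_check(model: PssmModel, truth: GroundTruth) -> float:
    """Fraction of planted (offset, residue) cells with a positive tendency score."""
    if not truth.planted:
        raise ValueError("no planted cells to check")
    sym = {a: i for i, a in enumerate(model.alphabet)}
    hits = 0
    for offset, residue, _e in truth.planted:
        col = model.column_of_offset(offset)
        if model.E[sym[residue], col] > 0:
            hits += 1
    return hits / len(truth.planted)


def to_files(dataset: LabeledDataset, fasta_path, annotations_path) -> None:
    """Materialize a synthetic dataset as the FASTA + annotation TSV pair
    consumed by the public entry points (one protein per window)."""
    from .alphabet import MODIFICATION_RESIDUE as MR

    residue = MR[dataset.modification_type]
    with open(fasta_path, "w") as fa, open(annotations_path, "w") as tsv:
        tsv.write("protein_id\tposition\tresidue\tlabel\n")
        for w in dataset.windows:
            fa.write(f">{w.protein_id}\n{w.core()}\n")
            label = 1 if w.label == "positive" else 0
            tsv.write(f"{w.protein_id}\t{w.center_position}\t{residue}\t{label}\n")
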