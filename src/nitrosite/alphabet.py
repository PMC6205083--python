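"""The 21-symbol peptide alphabet and the amino-acid property-factor table.

The alphabet is the 20 natural amino acids in the fixed canonical order
``ACDEFGHIKLMNPQRSTVWY`` followed by the gap symbol ``-`` used to pad
window termini.  The order is part of every fitted model's contract and is
serialized with model files.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 natural amino acids, canonical order.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: Gap symbol used to pad windows past the protein termini.
GAP: str = "-"

#: Full 21-symbol alphabet; the gap is always last.
ALPHABET: str = AA20 + GAP

#: Symbol -> index into ALPHABET.
SYMBOL_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: Ambiguity codes / nonstandard residues mapped to the gap symbol on input.
NONSTANDARD: frozenset[str] = frozenset("BJOUXZ*")

#: Residues that can carry the modifications handled here.
MODIFIABLE: frozenset[str] = frozenset("YWC")

#: Modification type -> center residue.
MODIFICATION_RESIDUE: dict[str, str] = {
    "Y-nitration": "Y",
    "W-nitration": "W",
    "C-nitrosylation": "C",
}

# Swiss-Prot background amino-acid frequencies (fractions, renormalized).
_NATURAL = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}


def natural_background() -> np.ndarray:
    """Background probabilities over :data:`AA20` from Swiss-Prot composition."""
    v = np.array([_NATURAL[a] for a in AA20], dtype=float)
    return v / v.sum()


def uniform_background() -> np.ndarray:
    """Uniform background probabilities over the 20 natural residues."""
    return np.full(20, 1.0 / 20.0)


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase ``seq`` and map nonstandard residues to the gap symbol.

    Ambiguity codes and rare residues (B, J, O, U, X, Z) have no row in the
    encoding tables; they are replaced by ``-`` with a logged warning.
    """
    seq = "".join(seq.split()).upper()
    bad = sorted({c for c in seq if c not in SYMBOL_INDEX})
    if bad:
        logger.warning(
            "sequence %s: nonstandard symbols %s mapped to gap", record_id, bad
        )
        seq = "".join(c if c in SYMBOL_INDEX else GAP for c in seq)
    return seq


def load_property_factors(path=None) -> pd.DataFrame:
    """Load a 20x10 amino-acid property-factor table.

    Without ``path``, loads the packaged table: a synthetic stand-in for the
    classical ten orthogonal property factors, derived by principal-component
    analysis of the complete AAindex property scales (one row per residue,
    ten orthogonal unit-variance factors).  Users may substitute any
    tab-separated table with a ``residue`` column and ten numeric columns.
    """
    if path is None:
        ref = importlib.resources.files("nitrosite.data").joinpath(
            "property_factors_synthetic.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", index_col="residue")
    else:
        table = pd.read_csv(path, sep="\t", index_col="residue")
    missing = sorted(set(AA20) - set(table.index))
    if missing:
        raise ValueError(f"property-factor table missing residues: {missing}")
    if table.shape[1] != 10:
        raise ValueError(
            f"property-factor table must have 10 factor columns, got {table.shape[1]}"
        )
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("property-factor table contains non-finite values")
    return table.loc[list(AA20)].astype(float)
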