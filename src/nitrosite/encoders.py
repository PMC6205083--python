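"""Feature encoders for site windows.

Four schemes turn an L-length window into numbers:

* **onehot** — 21 indicator bits per position (20 residues + gap), 21·L total.
* **pfr** — property-factor representation: 10 physicochemical factors per
  position, gaps contribute zeros, 10·L total.
* **kspace** — composition of k-spaced amino-acid pairs: for each k the
  frequency of every ordered natural-residue pair separated by exactly k
  intervening positions, 400 values per k (2000 for the default k = 0..4).
  Terminal gap runs are stripped first and the ungapped length L' enters the
  denominator L' − k + 1.
* **pssm** — a positive/negative tendency score per non-center position.
  Fitting contrasts, per position and symbol, the occurrence frequencies in
  positive vs. negative windows with a Welch two-sample t-test on the binary
  indicator vectors; the encoding value is E = sign(δ)·ln(|δ|+1) with
  δ = (f_pos − f_neg)/p.  E > 0 means the symbol favors modified sites at
  that position.  The center column is discarded (zero variance by
  construction), so the vector has L − 1 entries.

Encoders are scikit-learn transformers operating on sequences of peptides
(strings) or :class:`~nitrosite.io.SiteWindow` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .alphabet import AA20, ALPHABET, GAP, SYMBOL_INDEX, load_property_factors
from .io import LabeledDataset, SiteWindow

SCHEME_ORDER = ("onehot", "pfr", "kspace", "pssm")

DEFAULT_P_FLOOR = 1e-6


@dataclass(frozen=True)
class FeatureVector:
    """A concatenated numeric encoding of one window plus its layout."""

    values: np.ndarray
    scheme_tags: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if len(self.values) != sum(span for _, span in self.scheme_tags):
            raise ValueError("feature length does not match scheme spans")


def as_peptides(X) -> list[str]:
    """Normalize transformer input to a list of peptide strings."""
    if isinstance(X, LabeledDataset):
        return X.peptides
    out = []
    for item in X:
        if isinstance(item, SiteWindow):
            out.append(item.peptide)
        elif isinstance(item, str):
            out.append(item)
        else:
            raise TypeError(f"cannot encode object of type {type(item).__name__}")
    return out


def _index_matrix(peptides: list[str]) -> np.ndarray:
    """Map peptides (all same length) to a (n, L) matrix of alphabet indices."""
    if not peptides:
        raise ValueError("no peptides to encode")
    L = len(peptides[0])
    idx = np.empty((len(peptides), L), dtype=np.int64)
    for r, pep in enumerate(peptides):
        if len(pep) != L:
            raise ValueError(
                f"peptide {r} has length {len(pep)}, expected {L}"
            )
        for c, sym in enumerate(pep):
            try:
                idx[r, c] = SYMBOL_INDEX[sym]
            except KeyError:
                raise ValueError(
                    f"peptide {r}: symbol {sym!r} at position {c + 1} "
                    "is outside the alphabet"
                ) from None
    return idx


# ---------------------------------------------------------------------------
# one-hot
# ---------------------------------------------------------------------------


class WindowOneHotEncoder(TransformerMixin, BaseEstimator):
    """Binary indicator encoding: 21 bits per window position."""

    def fit(self, X, y=None):
        self.window_length_ = len(as_peptides(X)[0])
        return self

    def transform(self, X) -> np.ndarray:
        peptides = as_peptides(X)
        idx = _index_matrix(peptides)
        n, L = idx.shape
        out = np.zeros((n, L * len(ALPHABET)))
        cols = np.arange(L) * len(ALPHABET) + idx
        out[np.arange(n)[:, None], cols] = 1.0
        return out


# ---------------------------------------------------------------------------
# property factors
# ---------------------------------------------------------------------------


class PropertyFactorEncoder(TransformerMixin, BaseEstimator):
    """Ten physicochemical property factors per position; gaps encode as zeros."""

    def __init__(self, table=None):
        self.table = table

    def _factor_matrix(self) -> np.ndarray:
        table = self.table if self.table is not None else load_property_factors()
        missing = sorted(set(AA20) - set(table.index))
        if missing:
            raise ValueError(f"property-factor table missing residues: {missing}")
        mat = table.loc[list(AA20)].to_numpy(dtype=float)
        # gap row appended as zeros, matching the alphabet layout
        return np.vstack([mat, np.zeros(mat.shape[1])])

    def fit(self, X, y=None):
        self.factors_ = self._factor_matrix()
        self.window_length_ = len(as_peptides(X)[0])
        return self

    def transform(self, X) -> np.ndarray:
        factors = getattr(self, "factors_", None)
        if factors is None:
            factors = self._factor_matrix()
        idx = _index_matrix(as_peptides(X))
        n, L = idx.shape
        return factors[idx].reshape(n, L * factors.shape[1])


# ---------------------------------------------------------------------------
# k-space pair composition
# ---------------------------------------------------------------------------

_AA_IDX = {a: i for i, a in enumerate(AA20)}


def kspace_pair_counts(sequence: str, k: int) -> np.ndarray:
    """Count ordered natural-residue pairs separated by exactly k positions.

    Returns a 400-vector in row-major (first residue, second residue) order
    over the canonical 20-residue alphabet.  Pairs involving a gap are not
    counted.
    """
    counts = np.zeros(400)
    step = k + 1
    for i in range(len(sequence) - step):
        a, b = sequence[i], sequence[i + step]
        if a in _AA_IDX and b in _AA_IDX:
            counts[_AA_IDX[a] * 20 + _AA_IDX[b]] += 1
    return counts


class KSpacePairEncoder(TransformerMixin, BaseEstimator):
    """Composition of k-spaced amino-acid pairs over the ungapped window core.

    For each k the 400 ordered-pair counts are divided by L' − k + 1 where L'
    is the window length after stripping terminal gap runs (the printed
    normalization; the blocks are therefore not probability vectors).  A k
    admitting no pairs yields an all-zero block.
    """

    def __init__(self, k_values=(0, 1, 2, 3, 4)):
        self.k_values = k_values

    def fit(self, X, y=None):
        self.k_values_ = tuple(int(k) for k in self.k_values)
        if any(k < 0 for k in self.k_values_):
            raise ValueError("k values must be non-negative")
        return self

    def _encode_one(self, peptide: str, k_values) -> np.ndarray:
        core = peptide.strip(GAP)
        L_eff = len(core)
        if L_eff <= 0:
            raise ValueError("cannot k-space encode an all-gap peptide")
        blocks = []
        for k in k_values:
            if L_eff - k - 1 <= 0:
                blocks.append(np.zeros(400))
            else:
                blocks.append(kspace_pair_counts(core, k) / (L_eff - k + 1))
        return np.concatenate(blocks)

    def transform(self, X) -> np.ndarray:
        k_values = getattr(self, "k_values_", None) or tuple(
            int(k) for k in self.k_values
        )
        return np.array([self._encode_one(p, k_values) for p in as_peptides(X)])


# ---------------------------------------------------------------------------
# tendency PSSM
# ---------------------------------------------------------------------------


def position_symbol_pvalue(
    count_pos: int,
    n_pos: int,
    count_neg: int,
    n_neg: int,
    p_floor: float = DEFAULT_P_FLOOR,
) -> float:
    """Two-tailed Welch t-test p-value for one (position, symbol) cell.

    The two samples are binary indicator vectors: ``count`` ones among ``n``
    entries in each class.  Equal class means give p = 1 exactly; the
    degenerate zero-variance case with differing means returns ``p_floor``;
    all results are clamped to [p_floor, 1].
    """
    if not (0 <= count_pos <= n_pos and 0 <= count_neg <= n_neg):
        raise ValueError("counts must satisfy 0 <= count <= n")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 windows per class for a variance")
    if count_pos * n_neg == count_neg * n_pos:  # identical means, exact
        return 1.0
    v1 = count_pos * (n_pos - count_pos) / (n_pos * (n_pos - 1))
    v2 = count_neg * (n_neg - count_neg) / (n_neg * (n_neg - 1))
    se2 = v1 / n_pos + v2 / n_neg
    if se2 == 0.0:
        return p_floor
    t = (count_pos / n_pos - count_neg / n_neg) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / n_pos) ** 2 / (n_pos - 1) + (v2 / n_neg) ** 2 / (n_neg - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(1.0, max(p_floor, p)))


def _welch_pvalue_matrix(Cp, n_pos, Cn, n_neg, p_floor) -> np.ndarray:
    """Vectorized Welch p-values for count matrices (same contract as above)."""
    Cp = Cp.astype(float)
    Cn = Cn.astype(float)
    m1, m2 = Cp / n_pos, Cn / n_neg
    v1 = Cp * (n_pos - Cp) / (n_pos * (n_pos - 1))
    v2 = Cn * (n_neg - Cn) / (n_neg * (n_neg - 1))
    se2 = v1 / n_pos + v2 / n_neg
    equal = Cp * n_neg == Cn * n_pos
    degenerate = (se2 == 0.0) & ~equal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n_pos) ** 2 / (n_pos - 1) + (v2 / n_neg) ** 2 / (n_neg - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal, 1.0, p)
    p = np.where(degenerate, p_floor, p)
    return np.clip(p, p_floor, 1.0)


@dataclass
class PssmModel:
    """Fitted per-position symbol statistics contrasting positive vs. negative
    windows; the center column is excluded.

    Matrices are 21 × (L−1), rows in alphabet order, columns in window order
    with the center position removed.  ``E`` holds the signed log-tendency
    scores used for encoding.
    """

    alphabet: str
    L: int
    center_index: int  # 1-based position of the modified residue
    P: np.ndarray
    F_pos: np.ndarray
    F_neg: np.ndarray
    E: np.ndarray
    n_pos: int
    n_neg: int
    p_floor: float = DEFAULT_P_FLOOR

    def __post_init__(self):
        shape = (len(self.alphabet), self.L - 1)
        for name in ("P", "F_pos", "F_neg", "E"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"matrix {name} has shape {m.shape}, expected {shape}")

    def column_positions(self) -> list[int]:
        """1-based window positions corresponding to matrix columns."""
        return [j for j in range(1, self.L + 1) if j != self.center_index]

    def column_of_offset(self, offset: int) -> int:
        """Matrix column index for a center-relative offset (offset != 0)."""
        if offset == 0:
            raise ValueError("the center column is not part of the model")
        pos = self.center_index + offset
        if not (1 <= pos <= self.L):
            raise ValueError(f"offset {offset} outside the window")
        return pos - 1 if offset < 0 else pos - 2

    def encode(self, peptide: str) -> np.ndarray:
        if len(peptide) != self.L:
            raise ValueError(
                f"peptide length {len(peptide)} does not match model L={self.L}"
            )
        sym = {a: i for i, a in enumerate(self.alphabet)}
        out = np.empty(self.L - 1)
        col = 0
        for j, c in enumerate(peptide, start=1):
            if j == self.center_index:
                continue
            try:
                out[col] = self.E[sym[c], col]
            except KeyError:
                raise ValueError(f"symbol {c!r} at position {j} outside alphabet") from None
            col += 1
        return out

    # -- plain-text serialization -------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#nitrosite-pssm\t{self.FORMAT_VERSION}\n")
            fh.write(f"#alphabet\t{self.alphabet}\n")
            fh.write(f"#L\t{self.L}\n")
            fh.write(f"#center_index\t{self.center_index}\n")
            fh.write(f"#n_pos\t{self.n_pos}\n")
            fh.write(f"#n_neg\t{self.n_neg}\n")
            fh.write(f"#p_floor\t{self.p_floor!r}\n")
            for name in ("P", "F_pos", "F_neg", "E"):
                fh.write(f"#matrix\t{name}\n")
                for row in getattr(self, name):
                    fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "PssmModel":
        header: dict[str, str] = {}
        matrices: dict[str, list[list[float]]] = {}
        current = None
        with open(path) as fh:
            first = fh.readline().rstrip("\n").split("\t")
            if first[0] != "#nitrosite-pssm" or int(first[1]) != cls.FORMAT_VERSION:
                raise ValueError(f"{path}: not a recognized PSSM file")
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#matrix"):
                    current = line.split("\t")[1]
                    matrices[current] = []
                elif line.startswith("#"):
                    key, value = line[1:].split("\t")
                    header[key] = value
                else:
                    matrices[current].append([float(v) for v in line.split("\t")])
        try:
            return cls(
                alphabet=header["alphabet"],
                L=int(header["L"]),
                center_index=int(header["center_index"]),
                P=np.array(matrices["P"]),
                F_pos=np.array(matrices["F_pos"]),
                F_neg=np.array(matrices["F_neg"]),
                E=np.array(matrices["E"]),
                n_pos=int(header["n_pos"]),
                n_neg=int(header["n_neg"]),
                p_floor=float(header["p_floor"]),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: corrupted PSSM file ({exc})") from exc


def build_pssm(
    peptides,
    labels=None,
    p_floor: float = DEFAULT_P_FLOOR,
) -> PssmModel:
    """Fit the tendency PSSM from labeled windows.

    Accepts a :class:`LabeledDataset` or (peptides, binary labels).  Requires
    at least two windows per class.  Per non-center position j and symbol a:
    p-value from the Welch test on indicator vectors, observed frequencies
    f_pos and f_neg, δ = (f_pos − f_neg)/p (p clamped to [p_floor, 1]) and
    E = sign(δ)·ln(|δ|+1).
    """
    if isinstance(peptides, LabeledDataset):
        labels = peptides.labels
        peptides = peptides.peptides
    labels = np.asarray(labels, dtype=int)
    peptides = as_peptides(peptides)
    idx = _index_matrix(peptides)
    n, L = idx.shape
    if L % 2 != 1:
        raise ValueError("window length must be odd")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 windows per class to fit a PSSM, got {n_pos} pos / {n_neg} neg"
        )
    center = (L + 1) // 2  # 1-based
    cols = [j for j in range(L) if j != center - 1]
    A = len(ALPHABET)
    Cp = np.zeros((A, len(cols)), dtype=np.int64)
    Cn = np.zeros((A, len(cols)), dtype=np.int64)
    pos_idx = idx[labels == 1][:, cols]
    neg_idx = idx[labels == 0][:, cols]
    for c in range(len(cols)):
        Cp[:, c] = np.bincount(pos_idx[:, c], minlength=A)
        Cn[:, c] = np.bincount(neg_idx[:, c], minlength=A)
    P = _welch_pvalue_matrix(Cp, n_pos, Cn, n_neg, p_floor)
    F_pos = Cp / n_pos
    F_neg = Cn / n_neg
    delta = (F_pos - F_neg) / P
    E = np.sign(delta) * np.log1p(np.abs(delta))
    return PssmModel(
        alphabet=ALPHABET,
        L=L,
        center_index=center,
        P=P,
        F_pos=F_pos,
        F_neg=F_neg,
        E=E,
        n_pos=n_pos,
        n_neg=n_neg,
        p_floor=p_floor,
    )


class PssmEncoder(TransformerMixin, BaseEstimator):
    """Tendency-PSSM encoder: fit on labeled windows, emit L−1 scores per window."""

    def __init__(self, p_floor: float = DEFAULT_P_FLOOR, model: PssmModel | None = None):
        self.p_floor = p_floor
        self.model = model

    def fit(self, X, y=None):
        if self.model is not None:
            self.model_ = self.model
            return self
        if y is None and not isinstance(X, LabeledDataset):
            raise ValueError("PssmEncoder.fit requires labels (or a prefit model)")
        self.model_ = build_pssm(X, y, p_floor=self.p_floor)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise NotFittedError("PssmEncoder is not fitted")
        return np.array([self.model_.encode(p) for p in as_peptides(X)])


# ---------------------------------------------------------------------------
# combined featurizer
# ---------------------------------------------------------------------------


class WindowFeaturizer(TransformerMixin, BaseEstimator):
    """Concatenate any subset of the four schemes in the fixed canonical order
    onehot, pfr, kspace, pssm.

    The pssm scheme needs labels at fit time (or a prefit :class:`PssmModel`
    passed as ``pssm_model``).  ``scheme_spans_`` records the concatenation
    layout after fitting.
    """

    def __init__(
        self,
        schemes=("kspace", "pssm"),
        k_values=(0, 1, 2, 3, 4),
        property_table=None,
        p_floor: float = DEFAULT_P_FLOOR,
        pssm_model: PssmModel | None = None,
    ):
        self.schemes = schemes
        self.k_values = k_values
        self.property_table = property_table
        self.p_floor = p_floor
        self.pssm_model = pssm_model

    def _ordered_schemes(self) -> tuple[str, ...]:
        requested = set(self.schemes)
        unknown = requested - set(SCHEME_ORDER)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")
        if not requested:
            raise ValueError("at least one scheme is required")
        return tuple(s for s in SCHEME_ORDER if s in requested)

    def fit(self, X, y=None):
        order = self._ordered_schemes()
        peptides = as_peptides(X)
        L = len(peptides[0])
        encoders = {}
        for scheme in order:
            if scheme == "onehot":
                enc = WindowOneHotEncoder()
            elif scheme == "pfr":
                enc = PropertyFactorEncoder(table=self.property_table)
            elif scheme == "kspace":
                enc = KSpacePairEncoder(k_values=self.k_values)
            else:
                enc = PssmEncoder(p_floor=self.p_floor, model=self.pssm_model)
                if self.pssm_model is None and y is None and not isinstance(
                    X, LabeledDataset
                ):
                    raise ValueError(
                        "scheme 'pssm' requires labels at fit time or a prefit model"
                    )
            if isinstance(X, LabeledDataset):
                enc.fit(X)
            else:
                enc.fit(peptides, y)
            encoders[scheme] = enc
        spans = {
            "onehot": len(ALPHABET) * L,
            "pfr": 10 * L,
            "kspace": 400 * len(tuple(self.k_values)),
            "pssm": L - 1,
        }
        self.encoders_ = encoders
        self.scheme_spans_ = tuple((s, spans[s]) for s in order)
        self.window_length_ = L
        self.n_features_out_ = sum(span for _, span in self.scheme_spans_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "encoders_"):
            raise NotFittedError("WindowFeaturizer is not fitted")
        peptides = as_peptides(X)
        blocks = [self.encoders_[s].transform(peptides) for s, _ in self.scheme_spans_]
        out = np.hstack(blocks)
        if out.shape[1] != self.n_features_out_:
            raise AssertionError("feature layout mismatch")
        return out

    @property
    def pssm_model_(self) -> PssmModel | None:
        enc = getattr(self, "encoders_", {}).get("pssm")
        return getattr(enc, "model_", None) if enc is not None else None

    def feature_vector(self, window) -> FeatureVector:
        """Encode a single window, returning values plus the scheme layout."""
        values = self.transform([window])[0]
        return FeatureVector(values=values, scheme_tags=self.scheme_spans_)


def save_feature_matrix(X, path, scheme_tags=None) -> None:
    """Export a feature matrix as TSV (rows = windows, columns = features).

    With ``scheme_tags`` the columns are named ``<scheme>_<i>``.
    """
    import pandas as pd

    X = np.asarray(X)
    if scheme_tags is not None:
        names = [f"{tag}_{i}" for tag, span in scheme_tags for i in range(span)]
        if len(names) != X.shape[1]:
            raise ValueError("scheme tags do not match the matrix width")
    else:
        names = [f"f{i}" for i in range(X.shape[1])]
    pd.DataFrame(X, columns=names).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def _single(window, encoder, tag: str) -> FeatureVector:
    values = encoder.fit([window] if not isinstance(window, list) else window).transform(
        [window]
    )[0]
    return FeatureVector(values=values, scheme_tags=((tag, len(values)),))


def encode_onehot(window) -> FeatureVector:
    return _single(window, WindowOneHotEncoder(), "onehot")


def encode_pfr(window, table=None) -> FeatureVector:
    return _single(window, PropertyFactorEncoder(table=table), "pfr")


def encode_kspace(window, k_values=(0, 1, 2, 3, 4)) -> FeatureVector:
    return _single(window, KSpacePairEncoder(k_values=k_values), "kspace")


def encode_pssm(window, model: PssmModel) -> FeatureVector:
    values = PssmEncoder(model=model).fit([window]).transform([window])[0]
    return FeatureVector(values=values, scheme_tags=(("pssm", len(values)),))


def encode_combined(
    window,
    schemes,
    property_table=None,
    pssm_model: PssmModel | None = None,
    k_values=(0, 1, 2, 3, 4),
) -> FeatureVector:
    feat = WindowFeaturizer(
        schemes=schemes,
        k_values=k_values,
        property_table=property_table,
        pssm_model=pssm_model,
    )
    if "pssm" in set(schemes) and pssm_model is None:
        raise ValueError("scheme 'pssm' requires a prefit PssmModel")
    feat.fit([window])
    return feat.feature_vector(window)
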