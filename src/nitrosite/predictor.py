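"""High-level site predictor: featurizer + network + stringency thresholds,
with a versioned self-describing JSON archive for persistence."""

from __future__ import annotations

import json

import numpy as np

from .alphabet import ALPHABET, MODIFICATION_RESIDUE
from .encoders import PssmModel, WindowFeaturizer
from .evaluation import (
    CvReport,
    StringencyLevel,
    StringencyThresholds,
    cross_validate,
    select_thresholds,
)
from .io import LabeledDataset, ProteinRecord, extract_windows
from .network import DenseNetworkClassifier

ARCHIVE_VERSION = 1

STRINGENCIES = ("high", "medium", "low")


class SitePredictor:
    """Train, apply and persist a complete modification-site model.

    Wraps a :class:`WindowFeaturizer` (refit per CV fold during threshold
    selection, then fit on the full training data) and a
    :class:`DenseNetworkClassifier`.
    """

    def __init__(
        self,
        modification_type: str = "Y-nitration",
        window_length: int = 41,
        schemes=("kspace", "pssm"),
        classifier: DenseNetworkClassifier | None = None,
        target_specificities=(0.95, 0.90, 0.85),
        k_values=(0, 1, 2, 3, 4),
        property_table=None,
        seed: int = 0,
    ):
        if modification_type not in MODIFICATION_RESIDUE:
            raise ValueError(f"unknown modification type {modification_type!r}")
        self.modification_type = modification_type
        self.window_length = window_length
        self.schemes = tuple(schemes)
        self.classifier = (
            classifier if classifier is not None else DenseNetworkClassifier(seed=seed)
        )
        self.target_specificities = tuple(target_specificities)
        self.k_values = tuple(k_values)
        self.property_table = property_table
        self.seed = seed

    # -- fitting ------------------------------------------------------------

    def _new_featurizer(self) -> WindowFeaturizer:
        return WindowFeaturizer(
            schemes=self.schemes,
            k_values=self.k_values,
            property_table=self.property_table,
        )

    def fit(self, dataset: LabeledDataset, n_folds: int | None = 4):
        """Fit on the full dataset; optionally run CV first for thresholds.

        With ``n_folds`` set, an n-fold cross-validation (with per-fold
        encoder refits) produces the pooled ROC from which the stringency
        thresholds are selected; the report is kept as ``cv_report_``.
        """
        if dataset.modification_type != self.modification_type:
            raise ValueError(
                f"dataset is {dataset.modification_type}, predictor expects "
                f"{self.modification_type}"
            )
        self.cv_report_: CvReport | None = None
        self.thresholds_: StringencyThresholds | None = None
        if n_folds is not None:
            self.cv_report_ = cross_validate(
                dataset,
                self._new_featurizer(),
                self.classifier,
                n_folds=n_folds,
                seed=self.seed,
            )
            self.thresholds_ = select_thresholds(
                self.cv_report_.pooled_roc, self.target_specificities
            )
        self.featurizer_ = self._new_featurizer().fit(dataset)
        X = self.featurizer_.transform(dataset)
        self.classifier_ = self.classifier
        self.classifier_.fit(X, dataset.labels)
        return self

    # -- scoring ------------------------------------------------------------

    def score_windows(self, windows) -> np.ndarray:
        """Positive-class probability per window."""
        X = self.featurizer_.transform(windows)
        return self.classifier_.decision_scores(X)

    def stringency_of(self, score: float) -> str:
        """Highest stringency level a score attains, or 'none'."""
        if self.thresholds_ is None:
            return "none"
        for level in STRINGENCIES:
            if score >= self.thresholds_.cutoff_for(level):
                return level
        return "none"

    def predict_sites(self, records: list[ProteinRecord]):
        """Score every candidate residue of the model's type in the records.

        Returns (protein_id, position, residue, peptide, score, stringency)
        rows ready for :func:`nitrosite.io.write_predictions`.
        """
        residue = MODIFICATION_RESIDUE[self.modification_type]
        rows = []
        for rec in records:
            windows = extract_windows(rec, residue, self.window_length)
            if not windows:
                continue
            scores = self.score_windows(windows)
            for w, s in zip(windows, scores):
                rows.append(
                    (
                        w.protein_id,
                        w.center_position,
                        residue,
                        w.peptide,
                        float(s),
                        self.stringency_of(float(s)),
                    )
                )
        return rows

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        if not hasattr(self, "classifier_"):
            raise ValueError("cannot save an unfitted predictor")
        pssm = self.featurizer_.pssm_model_
        payload = {
            "format": "nitrosite-model",
            "version": ARCHIVE_VERSION,
            "alphabet": ALPHABET,
            "modification_type": self.modification_type,
            "window_length": self.window_length,
            "schemes": list(self.schemes),
            "k_values": list(self.k_values),
            "target_specificities": list(self.target_specificities),
            "seed": self.seed,
            "network": self.classifier_.to_dict(),
            "pssm": None
            if pssm is None
            else {
                "alphabet": pssm.alphabet,
                "L": pssm.L,
                "center_index": pssm.center_index,
                "n_pos": pssm.n_pos,
                "n_neg": pssm.n_neg,
                "p_floor": pssm.p_floor,
                "P": pssm.P.tolist(),
                "F_pos": pssm.F_pos.tolist(),
                "F_neg": pssm.F_neg.tolist(),
                "E": pssm.E.tolist(),
            },
            "property_table": None
            if self.property_table is None
            else {
                "index": list(self.property_table.index),
                "columns": list(self.property_table.columns),
                "values": self.property_table.to_numpy().tolist(),
            },
            "thresholds": None
            if self.thresholds_ is None
            else {
                level: {
                    "cutoff": getattr(self.thresholds_, level).cutoff,
                    "specificity": getattr(self.thresholds_, level).specificity,
                    "sensitivity": getattr(self.thresholds_, level).sensitivity,
                }
                for level in STRINGENCIES
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SitePredictor":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: corrupted model file ({exc})") from exc
        if payload.get("format") != "nitrosite-model":
            raise ValueError(f"{path}: not a recognized model file")
        if payload.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"{path}: model format version {payload.get('version')} "
                f"not supported (expected {ARCHIVE_VERSION})"
            )
        if payload["alphabet"] != ALPHABET:
            raise ValueError(
                f"{path}: alphabet {payload['alphabet']!r} does not match "
                f"this build's alphabet {ALPHABET!r}"
            )
        schemes = tuple(payload["schemes"])
        if "pssm" in schemes and payload["pssm"] is None:
            raise ValueError(f"{path}: scheme layout includes pssm but no PSSM stored")
        property_table = None
        if payload["property_table"] is not None:
            import pandas as pd

            pt = payload["property_table"]
            property_table = pd.DataFrame(
                pt["values"], index=pt["index"], columns=pt["columns"]
            )
        predictor = cls(
            modification_type=payload["modification_type"],
            window_length=payload["window_length"],
            schemes=schemes,
            target_specificities=tuple(payload["target_specificities"]),
            k_values=tuple(payload["k_values"]),
            property_table=property_table,
            seed=payload["seed"],
        )
        pssm = None
        if payload["pssm"] is not None:
            p = payload["pssm"]
            pssm = PssmModel(
                alphabet=p["alphabet"],
                L=p["L"],
                center_index=p["center_index"],
                P=np.array(p["P"]),
                F_pos=np.array(p["F_pos"]),
                F_neg=np.array(p["F_neg"]),
                E=np.array(p["E"]),
                n_pos=p["n_pos"],
                n_neg=p["n_neg"],
                p_floor=p["p_floor"],
            )
        feat = WindowFeaturizer(
            schemes=schemes,
            k_values=predictor.k_values,
            property_table=property_table,
            pssm_model=pssm,
        )
        # refit stateless encoders on a dummy window of the right length to
        # restore the layout; the pssm encoder reuses the stored model
        residue = MODIFICATION_RESIDUE[predictor.modification_type]
        flank = (predictor.window_length - 1) // 2
        dummy = "A" * flank + residue + "A" * flank
        feat.fit([dummy])
        predictor.featurizer_ = feat
        predictor.classifier_ = DenseNetworkClassifier.from_dict(payload["network"])
        predictor.classifier = predictor.classifier_
        predictor.cv_report_ = None
        predictor.thresholds_ = None
        if payload["thresholds"] is not None:
            levels = {
                level: StringencyLevel(**payload["thresholds"][level])
                for level in STRINGENCIES
            }
            predictor.thresholds_ = StringencyThresholds(
                high=levels["high"], medium=levels["medium"], low=levels["low"]
            )
        return predictor
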