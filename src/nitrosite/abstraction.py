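"""Layer-wise feature-abstraction analysis.

How much discriminative signal does each hidden layer carry, per unit of
dimensionality?  For every hidden layer i the inference-mode activations
are extracted for a train and a test partition, a small four-layer probe
MLP is retrained on them, and its test AUC A_i is converted to the
per-unit abstraction score S_i = (A_i − 0.5) / D_i, where D_i is the layer
width.  A PCA baseline compresses the raw features to the same D_i
(components fit on the train partition only) and is probed identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .evaluation import roc
from .network import DenseNetworkClassifier


@dataclass
class AbstractionEntry:
    source: str  # "layer" or "pca"
    layer: int  # hidden-layer index (1-based); for pca, the matched layer
    dimension: int
    auc: float
    score: float


@dataclass
class AbstractionReport:
    layers: list[AbstractionEntry]
    pca: list[AbstractionEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(e) for e in self.layers] + [vars(e) for e in self.pca]
        )

    @property
    def mean_layer_auc(self) -> float:
        return float(np.mean([e.auc for e in self.layers]))

    @property
    def mean_pca_auc(self) -> float:
        return float(np.mean([e.auc for e in self.pca]))


def extract_activations(model: DenseNetworkClassifier, layer: int, X) -> np.ndarray:
    """Inference-mode post-ReLU activations of hidden layer ``layer`` (1-based)."""
    return model.hidden_activations(X, layer)


def default_probe(seed: int = 0, epochs: int = 60) -> DenseNetworkClassifier:
    """The four-layer probe MLP: input, two ReLU hidden layers, softmax out."""
    return DenseNetworkClassifier(
        hidden_sizes=(64, 32),
        dropout_rates=(),
        learning_rate=0.01,
        momentum=0.9,
        l1=0.0,
        l2=1e-4,
        batch_size=50,
        epochs=epochs,
        seed=seed,
    )


def probe_mlp(
    train_features,
    train_labels,
    test_features,
    test_labels,
    probe: DenseNetworkClassifier | None = None,
    seed: int = 0,
) -> float:
    """Retrain the probe MLP on one feature set and return its test AUC."""
    clf = probe if probe is not None else default_probe(seed=seed)
    clf.seed = seed
    clf.fit(np.asarray(train_features, dtype=float), np.asarray(train_labels))
    scores = clf.decision_scores(np.asarray(test_features, dtype=float))
    return roc(scores, test_labels).auc


def pca_baseline(train_features, test_features, D: int, seed: int = 0):
    """Compress raw features to D components fit on the train partition only."""
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    limit = min(train_features.shape)
    if not (1 <= D <= limit):
        raise ValueError(f"target dimension {D} outside 1..{limit}")
    pca = PCA(n_components=D, random_state=seed)
    pca.fit(train_features)
    return pca.transform(train_features), pca.transform(test_features)


def abstraction_score(A: float, D: int) -> float:
    """Per-unit abstraction score S = (A − 0.5) / D."""
    if D < 1:
        raise ValueError("dimensionality must be >= 1")
    if not (0.0 <= A <= 1.0):
        raise ValueError("AUC must be in [0, 1]")
    return (A - 0.5) / D


def run_abstraction_analysis(
    model: DenseNetworkClassifier,
    X_train,
    y_train,
    X_test,
    y_test,
    probe: DenseNetworkClassifier | None = None,
    seed: int = 0,
) -> AbstractionReport:
    """Probe every hidden layer and its matched-dimension PCA baseline."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    layer_entries = []
    pca_entries = []
    for layer, width in enumerate(model.hidden_sizes, start=1):
        act_train = extract_activations(model, layer, X_train)
        act_test = extract_activations(model, layer, X_test)
        auc = probe_mlp(
            act_train, y_train, act_test, y_test, probe=probe,
            seed=(seed * 131 + layer) % (2**31),
        )
        layer_entries.append(
            AbstractionEntry(
                source="layer",
                layer=layer,
                dimension=width,
                auc=auc,
                score=abstraction_score(auc, width),
            )
        )
        D = min(width, min(X_train.shape))
        pc_train, pc_test = pca_baseline(X_train, X_test, D, seed=seed)
        auc_pca = probe_mlp(
            pc_train, y_train, pc_test, y_test, probe=probe,
            seed=(seed * 131 + 64 + layer) % (2**31),
        )
        pca_entries.append(
            AbstractionEntry(
                source="pca",
                layer=layer,
                dimension=D,
                auc=auc_pca,
                score=abstraction_score(auc_pca, D),
            )
        )
    return AbstractionReport(layers=layer_entries, pca=pca_entries)
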