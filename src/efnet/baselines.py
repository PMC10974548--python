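"""Feature adapters and classical-ML baselines.

Two paper-defined adapters turn a paired window into baseline-ready inputs:

* :func:`flatten_features` — row-major flattening to 1-D vectors of length
  15,000 (EEG 500x30), 1,800 (fNIRS 25x72) or 16,800 (both, EEG first).
* :func:`three_channel_reshape` — a 3-plane "image" for stock vision
  backbones: the 500 EEG rows are sliced into overlapping thirds
  [0,200), [150,350), [300,500) stacked depth-wise (200x30x3); the 25
  fNIRS rows are simply repeated on all three planes (25x72x3).

The stock classifiers (SVM, random forest, KNN) run at scikit-learn
defaults; reports record the library version, since "default parameters"
drift between releases.  Vision backbones (VGG/ResNet) are stock
architectures outside this package's scope; only the reshaping they consume
is implemented here.
"""

from __future__ import annotations

import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from efnet.preprocess import DatasetBundle
from efnet.splits import SplitSpec
from efnet.train import MetricsReport, compute_metrics

FLAT_LENGTHS = {"eeg": 15_000, "fnirs": 1_800, "both": 16_800}

EEG_SLICES = ((0, 200), (150, 350), (300, 500))

ML_KINDS = ("svm", "rf", "knn")


def flatten_features(sample, modality: str = "both") -> np.ndarray:
    """Row-major flatten of one window sample; EEG precedes fNIRS for 'both'."""
    if modality == "eeg":
        return np.asarray(sample.xe).reshape(-1)
    if modality == "fnirs":
        return np.asarray(sample.xf).reshape(-1)
    if modality == "both":
        return np.concatenate([
            np.asarray(sample.xe).reshape(-1),
            np.asarray(sample.xf).reshape(-1),
        ])
    raise ValueError("modality must be 'eeg', 'fnirs' or 'both'")


def flatten_bundle(bundle: DatasetBundle, modality: str = "both") -> np.ndarray:
    """Vectorized flattening of a whole bundle -> (n, length) matrix."""
    n = len(bundle)
    if modality == "eeg":
        return bundle.xe.reshape(n, -1)
    if modality == "fnirs":
        return bundle.xf.reshape(n, -1)
    if modality == "both":
        return np.concatenate(
            [bundle.xe.reshape(n, -1), bundle.xf.reshape(n, -1)], axis=1
        )
    raise ValueError("modality must be 'eeg', 'fnirs' or 'both'")


def three_channel_reshape(sample, modality: str) -> np.ndarray:
    """Build the 3-plane image a vision backbone expects.

    EEG -> (200, 30, 3) from the overlapping row slices; fNIRS -> (25, 72, 3)
    with all three planes identical.
    """
    if modality == "eeg":
        xe = np.asarray(sample.xe)
        if xe.shape != (500, 30):
            raise ValueError(f"EEG window must be (500, 30), got {xe.shape}")
        planes = [xe[a:b] for a, b in EEG_SLICES]
        return np.stack(planes, axis=-1)
    if modality == "fnirs":
        xf = np.asarray(sample.xf)
        if xf.shape != (25, 72):
            raise ValueError(f"fNIRS window must be (25, 72), got {xf.shape}")
        return np.repeat(xf[..., None], 3, axis=-1)
    raise ValueError("modality must be 'eeg' or 'fnirs'")


def _make_classifier(kind: str, seed: int):
    if kind == "svm":
        return SVC(random_state=seed)           # defaults; no probabilities
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier()
    raise ValueError(f"unknown baseline kind {kind!r}; choose from {ML_KINDS}")


def run_ml_baseline(kind: str, features: np.ndarray, labels: np.ndarray,
                    split: SplitSpec, seed: int = 0) -> MetricsReport:
    """Train a stock classifier on the train side, evaluate on the test side.

    ``features`` is the (n, d) flat matrix; ``split`` carries the sample
    indices.  Scores for AUROC come from ``decision_function`` when the
    classifier has one, otherwise from ``predict_proba``.
    """
    clf = _make_classifier(kind, seed)
    tr = np.asarray(split.train_idx)
    te = np.asarray(split.test_idx)
    clf.fit(features[tr], labels[tr])
    if hasattr(clf, "decision_function"):
        raw = clf.decision_function(features[te])
        # map monotonically into (0,1) so the shared 0.5-threshold metrics apply
        scores = 1.0 / (1.0 + np.exp(-raw))
    else:
        scores = clf.predict_proba(features[te])[:, 1]
    report = compute_metrics(labels[te], scores)
    report.extra.update(
        kind=kind, seed=seed, library=f"scikit-learn=={sklearn.__version__}",
    )
    return report


def run_dl_backbone_baseline(*args, **kwargs):  # pragma: no cover - guard only
    """Vision-backbone baselines need a deep-learning framework with stock
    VGG16/VGG19/ResNet50 implementations, which this package deliberately
    does not depend on.  Use :func:`three_channel_reshape` to produce their
    inputs and run the backbones in an environment that provides them."""
    raise NotImplementedError(
        "stock vision backbones are not bundled; this package implements "
        "only the 3-channel input reshaping (three_channel_reshape)"
    )
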