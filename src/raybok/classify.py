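"""Random-Forest annotation and the input-mode x scheme experiment harness.

One forest of bagged, fully grown ("deep") trees is trained per
classification scheme on the PCA-reduced bag-of-keypoints features; the
harness sweeps the requested input-preparation modes, fits codebook and PCA
on training images only, and fills an accuracy matrix with one cell per
(input mode, scheme) pair.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .enhancement import ClaheParams, NlmParams, PadParams, INPUT_MODES, prepare_input
from .features import BagOfKeypointsExtractor
from .images import read_gray
from .irma import SCHEMES, LabelTable, enumerate_classes

__all__ = [
    "RfConfig",
    "SchemeRandomForest",
    "EvaluationReport",
    "MODE_ROW_LABELS",
    "train_random_forest",
    "predict",
    "evaluate_accuracy",
    "run_experiment",
    "derive_seed",
]

#: Report row labels for each input mode, in canonical report order.
MODE_ROW_LABELS = {
    "padded": "Image Padding",
    "padded_layered": "Image Padding/Layered",
    "layered": "Image Layered",
    "clahe": "CLAHE Image",
    "nlmeans": "NLMEANS Image",
    "original": "Original Image",
}
REPORT_MODE_ORDER = ("padded", "padded_layered", "layered", "clahe", "nlmeans", "original")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from a single run seed."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class RfConfig:
    """Random-Forest configuration: 1,000 bagged, fully grown trees.

    ``max_depth=None`` grows each tree to purity; ``max_features='sqrt'`` is
    the standard per-split feature heuristic.
    """

    n_trees: int = 1000
    max_depth: int | None = None
    max_features: str | int = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class SchemeRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest over string class labels with vote-fraction output.

    Thin wrapper around :class:`sklearn.ensemble.RandomForestClassifier`;
    predictions are the majority vote over trees, ties resolved toward the
    lexicographically smallest label.
    """

    def __init__(self, n_trees=1000, max_depth=None, max_features="sqrt",
                 bootstrap=True, seed=0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features,
            bootstrap=self.bootstrap,
            random_state=self.seed,
            n_jobs=1,
        )
        self._rf.fit(X, y)
        self.classes_ = self._rf.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dim {X.shape[1]} does not match training "
                f"dim {self.n_features_in_}"
            )
        return X

    def predict(self, X):
        return self._rf.predict(self._check_X(X))

    def predict_vote_fractions(self, X):
        """Per-class vote fractions (rows sum to 1), columns = ``classes_``."""
        return self._rf.predict_proba(self._check_X(X))


def train_random_forest(features, labels, config: RfConfig = RfConfig()) -> SchemeRandomForest:
    """Train one bagged random forest on reduced features."""
    model = SchemeRandomForest(
        n_trees=config.n_trees, max_depth=config.max_depth,
        max_features=config.max_features, bootstrap=config.bootstrap,
        seed=config.seed,
    )
    return model.fit(features, labels)


def predict(model: SchemeRandomForest, features):
    """Labels plus per-class vote fractions for ``features``."""
    return model.predict(features), model.predict_vote_fractions(features)


def evaluate_accuracy(predicted, truth) -> float:
    """Exact-match fraction between predicted and true labels."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have the same length")
    if len(truth) == 0:
        raise ValueError("cannot evaluate accuracy on empty label vectors")
    return float(np.mean(predicted == truth))


@dataclass
class EvaluationReport:
    """Accuracy matrix over (input mode, scheme), mirroring the report tables."""

    accuracy: dict[tuple[str, str], float]
    class_counts: dict[tuple[str, str], int]
    unseen_test_classes: dict[tuple[str, str], int]
    modes: list[str]
    schemes: list[str]
    config_hash: str
    seed: int
    timings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, acc in self.accuracy.items():
            if not (0.0 <= acc <= 1.0):
                raise ValueError(f"accuracy {acc} for {key} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Rows = input modes (report order and labels), columns = schemes."""
        ordered = [m for m in REPORT_MODE_ORDER if m in self.modes]
        rows = {
            MODE_ROW_LABELS[m]: [self.accuracy[(m, s)] for s in self.schemes]
            for m in ordered
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(self.schemes))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("Input Image").to_csv(path, float_format="%.6f")

    def to_manifest(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "modes": self.modes,
            "schemes": self.schemes,
            "accuracy": {f"{m}/{s}": v for (m, s), v in sorted(self.accuracy.items())},
            "class_counts": {f"{m}/{s}": v for (m, s), v in sorted(self.class_counts.items())},
            "unseen_test_classes": {
                f"{m}/{s}": v for (m, s), v in sorted(self.unseen_test_classes.items())
            },
            "timings_sec": {k: round(v, 3) for k, v in self.timings.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _load_images(table: LabelTable, image_dir: str | Path) -> list[np.ndarray]:
    image_dir = Path(image_dir)
    return [read_gray(image_dir / image_id) for image_id, _ in table]


def run_experiment(
    train: LabelTable,
    train_dir: str | Path,
    test: LabelTable,
    test_dir: str | Path,
    modes=("padded", "padded_layered", "layered", "clahe", "nlmeans", "original"),
    schemes=SCHEMES,
    rf_config: RfConfig = RfConfig(),
    clahe: ClaheParams = ClaheParams(),
    nlm: NlmParams = NlmParams(),
    pad: PadParams = PadParams(),
    extractor_params: dict | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Full annotation experiment over input modes and classification schemes.

    For each mode: prepare train/test inputs, fit the bag-of-keypoints
    extractor (codebook + PCA) on the training images only, train one random
    forest per scheme, and evaluate exact-match accuracy on the test set.
    Any stage failure aborts with the stage name and cause.
    """
    modes = list(modes)
    schemes = list(schemes)
    if not modes or not schemes:
        raise ValueError("need at least one input mode and one scheme")
    for m in modes:
        if m not in INPUT_MODES:
            raise ValueError(f"unknown input mode {m!r}; expected one of {INPUT_MODES}")
    extractor_params = dict(extractor_params or {})

    cfg_repr = repr((sorted(extractor_params.items()), rf_config, clahe, nlm, pad,
                     tuple(modes), tuple(schemes), seed))
    config_hash = hashlib.sha256(cfg_repr.encode()).hexdigest()[:16]

    accuracy: dict[tuple[str, str], float] = {}
    class_counts: dict[tuple[str, str], int] = {}
    unseen: dict[tuple[str, str], int] = {}
    timings: dict[str, float] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc
        timings[name] = timings.get(name, 0.0) + (time.perf_counter() - t0)
        return out

    train_images = _stage("load_train", _load_images, train, train_dir)
    test_images = _stage("load_test", _load_images, test, test_dir)

    for mode in modes:
        prep = lambda imgs: [prepare_input(im, mode, clahe, nlm, pad) for im in imgs]
        train_prep = _stage(f"{mode}/prepare_train", prep, train_images)
        test_prep = _stage(f"{mode}/prepare_test", prep, test_images)

        extractor = BagOfKeypointsExtractor(
            random_state=derive_seed(seed, f"{mode}/codebook"), **extractor_params
        )
        Xtr = _stage(f"{mode}/fit_features", extractor.fit_transform, train_prep)
        Xte = _stage(f"{mode}/test_features", extractor.transform, test_prep)

        for scheme in schemes:
            ytr = train.labels(scheme)
            yte = test.labels(scheme)
            cfg = RfConfig(
                n_trees=rf_config.n_trees, max_depth=rf_config.max_depth,
                max_features=rf_config.max_features, bootstrap=rf_config.bootstrap,
                seed=derive_seed(seed, f"{mode}/{scheme}/rf"),
            )
            model = _stage(f"{mode}/{scheme}/train_rf", train_random_forest, Xtr, ytr, cfg)
            pred = _stage(f"{mode}/{scheme}/predict", model.predict, Xte)
            accuracy[(mode, scheme)] = evaluate_accuracy(pred, yte)
            train_classes = set(enumerate_classes(train, scheme))
            class_counts[(mode, scheme)] = len(train_classes)
            unseen[(mode, scheme)] = len(set(yte) - train_classes)

    return EvaluationReport(
        accuracy=accuracy,
        class_counts=class_counts,
        unseen_test_classes=unseen,
        modes=modes,
        schemes=schemes,
        config_hash=config_hash,
        seed=seed,
        timings=timings,
    )
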