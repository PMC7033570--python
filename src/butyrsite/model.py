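"""Training, prediction and evaluation of the butyrylation-site classifier.

The classifier chains the entropy-variation encoder and/or the k-spaced
pair encoder, per-feature min-max normalization fitted on the training
matrix (out-of-range test values are clipped to [0, 1], constant
features map to 0), and a random forest. Evaluation follows the study
protocol: stratified 3-fold cross-validation with pooled scores on a
single ROC, AUC by the Mann-Whitney convention (ties count 1/2), plus an
independent test, a window-half-width sweep and feature-set ablations.

Inside cross-validation the entropy systems, the normalizer and the
forest are all re-fitted per fold from that fold's training part only,
so held-out fragments never leak into system counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .cksaap import CKSAAPEncoder
from .entropy import IEEEncoder
from .io import Dataset, SequenceRecord, SiteAnnotation, build_dataset

FEATURE_SETS = ("iee", "cksaap", "both")


# ---------------------------------------------------------------- normalization

def fit_normalizer(train_matrix: np.ndarray) -> MinMaxScaler:
    """Fit per-feature min-max parameters on the training matrix."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.size == 0:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    return MinMaxScaler(clip=True).fit(train_matrix)


def apply_normalizer(params: MinMaxScaler, matrix: np.ndarray) -> np.ndarray:
    """Map features to [0, 1] with the training min/max; clip outside values."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != params.n_features_in_:
        raise ValueError(
            f"matrix has {matrix.shape[1]} features, normalizer expects "
            f"{params.n_features_in_}"
        )
    return params.transform(matrix)


# ---------------------------------------------------------------- classifier

class ButyrylationClassifier(ClassifierMixin, BaseEstimator):
    """Sequence-window classifier for lysine butyrylation.

    ``X`` is an array-like of equal-length, K-centered window strings;
    ``y`` is binary (1 = butyrylated). All randomness flows through
    ``random_state``.

    Parameters
    ----------
    features : {"iee", "cksaap", "both"}, default "both"
        Which encoder block(s) feed the forest.
    k_max : int, default 1
        Largest pair gap for the CKSAAP block.
    log_base : float, default 2.0
        Entropy logarithm base for the IEE block.
    n_estimators : int, default 100
        Trees in the forest.
    max_features : str or int, default "sqrt"
        Features considered per split.
    random_state : int or None
        Forest seed.
    """

    def __init__(
        self,
        features: str = "both",
        k_max: int = 1,
        log_base: float = 2.0,
        n_estimators: int = 100,
        max_features="sqrt",
        random_state: int | None = None,
    ):
        self.features = features
        self.k_max = k_max
        self.log_base = log_base
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def _encode(self, windows: Sequence[str]) -> np.ndarray:
        blocks = []
        if self.features in ("iee", "both"):
            blocks.append(self.iee_.transform(windows))
        if self.features in ("cksaap", "both"):
            blocks.append(self.cksaap_.transform(windows))
        return np.hstack(blocks)

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "ButyrylationClassifier":
        if self.features not in FEATURE_SETS:
            raise ValueError(
                f"features must be one of {FEATURE_SETS}, got {self.features!r}"
            )
        windows = [w.window if hasattr(w, "window") else w for w in X]
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"training data must contain both classes, got labels {classes}"
            )
        if not set(classes) <= {0, 1}:
            raise ValueError("labels must be binary 0/1 with 1 = butyrylated")
        if len({len(w) for w in windows}) != 1:
            raise ValueError("all training windows must share one length")
        self.window_length_ = len(windows[0])
        names: list[str] = []
        # the IEE systems are always built (they are part of the bundle and
        # feed the descriptive analyses) even if only CKSAAP features are used
        self.iee_ = IEEEncoder(log_base=self.log_base).fit(windows, y)
        self.cksaap_ = CKSAAPEncoder(k_max=self.k_max).fit(windows, y)
        if self.features in ("iee", "both"):
            names += list(self.iee_.feature_names_)
        if self.features in ("cksaap", "both"):
            names += list(self.cksaap_.feature_names_)
        self.feature_names_ = names
        raw = self._encode(windows)
        self.normalizer_ = fit_normalizer(raw)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
        ).fit(apply_normalizer(self.normalizer_, raw), y)
        self.classes_ = self.forest_.classes_
        return self

    def _check_windows(self, X: Sequence[str]) -> list[str]:
        if not hasattr(self, "forest_"):
            raise RuntimeError("classifier is not fitted")
        windows = [w.window if hasattr(w, "window") else w for w in X]
        for w in windows:
            if len(w) != self.window_length_:
                raise ValueError(
                    f"window length {len(w)} does not match the fitted "
                    f"window length {self.window_length_} (config mismatch)"
                )
        return windows

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        windows = self._check_windows(X)
        matrix = apply_normalizer(self.normalizer_, self._encode(windows))
        return self.forest_.predict_proba(matrix)

    def predict_scores(self, X: Sequence[str]) -> np.ndarray:
        """Positive-class probability per window, in [0, 1]."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)


# ---------------------------------------------------------------- ROC / AUC

@dataclass
class EvalResult:
    """ROC points, AUC and bookkeeping for one experiment."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    fold_assignments: np.ndarray | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auc": self.auc,
            "roc": {
                "fpr": self.fpr.tolist(),
                "tpr": self.tpr.tolist(),
                "thresholds": [float(t) for t in self.thresholds],
            },
            "fold_assignments": (
                self.fold_assignments.tolist()
                if self.fold_assignments is not None
                else None
            ),
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    **meta,
) -> EvalResult:
    """ROC by threshold sweep and AUC by the Mann-Whitney convention.

    Tied scores are grouped on the ROC and count 1/2 toward the AUC, so
    all-equal scores give exactly 0.5 and perfect separation gives 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes for a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return EvalResult(
        auc=auc, fpr=fpr, tpr=tpr, thresholds=thresholds,
        scores=scores, labels=labels, **meta,
    )


# ---------------------------------------------------------------- model bundle

@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reuse it."""

    classifier: ButyrylationClassifier
    window_half_width: int
    seed: int | None
    config: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier.forest_, directory / "forest.joblib")
        self.classifier.iee_.pos_system_.save(directory / "system_positive")
        self.classifier.iee_.neg_system_.save(directory / "system_negative")
        norm = self.classifier.normalizer_
        with open(directory / "normalizer.json", "w") as fh:
            json.dump(
                {
                    "data_min": norm.data_min_.tolist(),
                    "data_max": norm.data_max_.tolist(),
                },
                fh,
            )
        with open(directory / "config.json", "w") as fh:
            json.dump(
                {
                    "window_half_width": self.window_half_width,
                    "seed": self.seed,
                    "params": self.classifier.get_params(),
                    "feature_names": self.classifier.feature_names_,
                    **self.config,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        from .entropy import EntropySystem

        directory = Path(directory)
        with open(directory / "config.json") as fh:
            config = json.load(fh)
        clf = ButyrylationClassifier(**config["params"])
        clf.window_length_ = 2 * config["window_half_width"] + 1
        clf.iee_ = IEEEncoder(log_base=clf.log_base)
        clf.iee_.pos_system_ = EntropySystem.load(directory / "system_positive")
        clf.iee_.neg_system_ = EntropySystem.load(directory / "system_negative")
        clf.iee_.window_length_ = clf.window_length_
        from .entropy import iee_feature_names

        clf.iee_.feature_names_ = iee_feature_names(clf.window_length_)
        clf.cksaap_ = CKSAAPEncoder(k_max=clf.k_max).fit([])
        clf.feature_names_ = config["feature_names"]
        with open(directory / "normalizer.json") as fh:
            norm_data = json.load(fh)
        matrix = np.array([norm_data["data_min"], norm_data["data_max"]])
        clf.normalizer_ = MinMaxScaler(clip=True).fit(matrix)
        clf.forest_ = joblib.load(directory / "forest.joblib")
        clf.classes_ = clf.forest_.classes_
        return cls(
            classifier=clf,
            window_half_width=config["window_half_width"],
            seed=config["seed"],
            config={
                k: v
                for k, v in config.items()
                if k not in ("window_half_width", "seed", "params", "feature_names")
            },
        )


def train_model(
    train_dataset: Dataset,
    features: str = "both",
    k_max: int = 1,
    log_base: float = 2.0,
    n_estimators: int = 100,
    seed: int | None = 0,
) -> ModelBundle:
    """Fit systems, encoders, normalizer and forest on a labeled dataset."""
    clf = ButyrylationClassifier(
        features=features,
        k_max=k_max,
        log_base=log_base,
        n_estimators=n_estimators,
        random_state=seed,
    ).fit(train_dataset.windows, train_dataset.labels)
    return ModelBundle(
        classifier=clf,
        window_half_width=train_dataset.window_half_width,
        seed=seed,
        config={"role": train_dataset.role},
    )


def predict(
    bundle: ModelBundle,
    sequences: Iterable[SequenceRecord],
    sites: Iterable[SiteAnnotation],
) -> list[dict]:
    """Score candidate sites with a trained bundle.

    Fragments are extracted at the bundle's window half-width and scored
    by the forest; returns one record per site with the positive-class
    score and the 0.5-threshold label.
    """
    sites = list(sites)
    dataset = build_dataset(sequences, sites, bundle.window_half_width, role="test")
    scores = bundle.classifier.predict_scores(dataset.windows)
    return [
        {
            "protein_id": s.protein_id,
            "position": s.position,
            "score": float(score),
            "predicted_label": "positive" if score >= 0.5 else "negative",
        }
        for s, score in zip(sites, scores)
    ]


# ---------------------------------------------------------------- experiments

def cross_validate(
    dataset: Dataset,
    folds: int = 3,
    seed: int = 0,
    features: str = "both",
    k_max: int = 1,
    log_base: float = 2.0,
    n_estimators: int = 100,
    return_models: bool = False,
):
    """Stratified k-fold cross-validation with pooled-score ROC/AUC.

    Every fold re-fits the entropy systems, the normalizer and the
    forest on its training part only; each fragment is scored exactly
    once, and the pooled scores form a single ROC curve.
    """
    windows = dataset.windows
    y = dataset.labels
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold CV, "
            f"got class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    assignments = np.empty(len(y), dtype=int)
    models = []
    template = ButyrylationClassifier(
        features=features,
        k_max=k_max,
        log_base=log_base,
        n_estimators=n_estimators,
        random_state=seed,
    )
    for fold, (train_idx, test_idx) in enumerate(skf.split(windows, y)):
        clf = clone(template).fit(
            [windows[i] for i in train_idx], y[train_idx]
        )
        scores[test_idx] = clf.predict_scores([windows[i] for i in test_idx])
        assignments[test_idx] = fold
        if return_models:
            models.append((clf, train_idx, test_idx))
    result = roc_auc(
        scores,
        y,
        fold_assignments=assignments,
        seed=seed,
        config={
            "folds": folds,
            "features": features,
            "k_max": k_max,
            "log_base": log_base,
            "n_estimators": n_estimators,
            "window_half_width": dataset.window_half_width,
        },
    )
    if return_models:
        return result, models
    return result


def independent_test(
    train_dataset: Dataset,
    test_dataset: Dataset,
    seed: int = 0,
    **config,
) -> EvalResult:
    """Train on one dataset, score another, report ROC/AUC."""
    if train_dataset.window_half_width != test_dataset.window_half_width:
        raise ValueError("train and test datasets differ in window half-width")
    bundle = train_model(train_dataset, seed=seed, **config)
    scores = bundle.classifier.predict_scores(test_dataset.windows)
    return roc_auc(
        scores,
        test_dataset.labels,
        seed=seed,
        config={"window_half_width": train_dataset.window_half_width, **config},
    )


def sweep_window(
    sequences: Iterable[SequenceRecord],
    sites: Iterable[SiteAnnotation],
    n_values: Sequence[int] = tuple(range(10, 16)),
    folds: int = 3,
    seed: int = 0,
    **config,
) -> dict[int, EvalResult]:
    """Cross-validate at each window half-width; one EvalResult per N.

    The default grid 10..15 brackets the window sizes customary for
    lysine-PTM predictors; N = 13 is the production default elsewhere in
    the package.
    """
    if not n_values:
        raise ValueError("n_values must be non-empty")
    sequences = list(sequences)
    sites = list(sites)
    results: dict[int, EvalResult] = {}
    for n in n_values:
        dataset = build_dataset(sequences, sites, n)
        results[n] = cross_validate(dataset, folds=folds, seed=seed, **config)
    return results


def ablate_features(
    dataset: Dataset,
    folds: int = 3,
    seed: int = 0,
    k_max: int = 1,
    log_base: float = 2.0,
    n_estimators: int = 100,
) -> dict[str, EvalResult]:
    """Cross-validate with each feature block alone and combined.

    The same seed drives the fold split everywhere, so the three runs
    share identical fold assignments and differ only in the encoding.
    """
    return {
        fs: cross_validate(
            dataset,
            folds=folds,
            seed=seed,
            features=fs,
            k_max=k_max,
            log_base=log_base,
            n_estimators=n_estimators,
        )
        for fs in FEATURE_SETS
    }
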