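"""Classifier comparison, descriptor selection, metrics and applicability domain.

The QSAR stage trains three supervised learners (random forest, gradient
boosting, a small tanh neural network) on the prepared descriptor matrix,
ranks descriptors by random-forest importance, sweeps the top-k descriptor
subsets with the neural network, and evaluates everything with a nine-metric
confusion-matrix suite plus AUROC.  The operating threshold is the Youden
cutoff on the ROC curve, remapped so it sits at score 0.5; the applicability
domain then excludes drugs whose normalized score falls within a band around
that cutoff.

Learners are scikit-learn estimators configured to mirror the reference
hyperparameters (random forest: 100 trees, 81 candidate features per split,
minimum leaf size 5; gradient boosting: 48 stages of 2-split trees, learning
rate 0.02; neural network: one hidden layer of 3 tanh units).  No attempt is
made to reproduce any particular software's training trajectory; equivalence
is at the algorithm level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DataError

DEFAULT_K_LIST = (5, 6, 7, 8, 9, 10, 20, 30)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RandomForestParams:
    n_trees: int = 100
    features_per_split: int = 81
    min_branch_size: int = 5


@dataclass
class GradientBoostingParams:
    splits_per_tree: int = 2
    n_stages: int = 48
    learning_rate: float = 0.02


@dataclass
class NeuralNetworkParams:
    activation: str = "tanh"
    hidden_units: int = 3
    learning_rate: float = 0.1
    solver: str = "lbfgs"      # learning_rate applies to sgd/adam solvers
    max_iter: int = 2000
    boosting_stages: int = 0   # >0: average an ensemble of re-seeded nets


@dataclass
class ModelConfig:
    """Hyperparameters for the three learners and the hold-out split."""

    algorithm: str = "neural_network"
    rf: RandomForestParams = field(default_factory=RandomForestParams)
    gb: GradientBoostingParams = field(default_factory=GradientBoostingParams)
    nn: NeuralNetworkParams = field(default_factory=NeuralNetworkParams)
    validation_fraction: float = 0.25   # the 3:1 train:validation split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("random_forest", "gradient_boosting",
                                  "neural_network"):
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must be in (0, 1)")
        for name, value in (("n_trees", self.rf.n_trees),
                            ("features_per_split", self.rf.features_per_split),
                            ("min_branch_size", self.rf.min_branch_size),
                            ("splits_per_tree", self.gb.splits_per_tree),
                            ("n_stages", self.gb.n_stages),
                            ("gb learning_rate", self.gb.learning_rate),
                            ("hidden_units", self.nn.hidden_units),
                            ("nn learning_rate", self.nn.learning_rate)):
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Split and fit
# ---------------------------------------------------------------------------

def split_train_validation(matrix: pd.DataFrame, label_column: str = "label",
                           validation_fraction: float = 0.25,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 3:1 hold-out split, deterministic under ``seed``.

    Stratification keeps the validation class mix proportional (e.g. a
    60-positive / 108-negative table yields a 15 / 27 validation set).
    """
    labels = matrix[label_column]
    if labels.value_counts().min() < 4:
        raise DataError("each class needs at least 4 members for a 3:1 split")
    train, validation = train_test_split(
        matrix, test_size=validation_fraction, stratify=labels,
        random_state=seed)
    return (train.reset_index(drop=True), validation.reset_index(drop=True))


def _label_vector(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        return (arr == "positive").astype(int)
    return arr.astype(int)


def fit_model(X: pd.DataFrame, y, config: ModelConfig):
    """Fit the configured learner; returns a scorer with ``predict_proba``.

    Scores are the positive-class probability in [0, 1].  The neural network
    standardizes inputs internally (a practical requirement for a small
    multilayer perceptron); the tree ensembles consume raw descriptors.
    """
    if not all(pd.api.types.is_numeric_dtype(X[c]) for c in X.columns):
        raise DataError("all features must be numeric")
    y = _label_vector(y)
    n_features = X.shape[1]
    if config.algorithm == "random_forest":
        model = RandomForestClassifier(
            n_estimators=config.rf.n_trees,
            max_features=min(config.rf.features_per_split, n_features),
            min_samples_leaf=config.rf.min_branch_size,
            random_state=config.seed)
    elif config.algorithm == "gradient_boosting":
        model = GradientBoostingClassifier(
            n_estimators=config.gb.n_stages,
            learning_rate=config.gb.learning_rate,
            max_leaf_nodes=config.gb.splits_per_tree + 1,
            random_state=config.seed)
    else:
        nn = config.nn
        if nn.boosting_stages > 0:
            from sklearn.ensemble import VotingClassifier
            members = [
                (f"nn{i}", _make_mlp(nn, config.seed + i))
                for i in range(nn.boosting_stages)]
            core = VotingClassifier(members, voting="soft")
        else:
            core = _make_mlp(nn, config.seed)
        model = Pipeline([("scale", StandardScaler()), ("nn", core)])
    model.fit(X, y)
    return model


def _make_mlp(nn: NeuralNetworkParams, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(nn.hidden_units,), activation=nn.activation,
        solver=nn.solver, learning_rate_init=nn.learning_rate,
        max_iter=nn.max_iter, random_state=seed)


def predict_scores(model, X: pd.DataFrame) -> np.ndarray:
    """Positive-class scores in [0, 1]."""
    return model.predict_proba(X)[:, 1]


def rf_importance_ranking(model, feature_names: Sequence[str]) -> pd.DataFrame:
    """Descriptors ranked by total impurity-decrease contribution.

    Ties are broken alphabetically.  ``n_splits`` counts how many tree
    branches split on each descriptor across the forest.
    """
    if not hasattr(model, "estimators_"):
        raise DataError("model must be a fitted random forest")
    importance = model.feature_importances_
    split_counts = np.zeros(len(feature_names), dtype=int)
    for tree in model.estimators_:
        used = tree.tree_.feature
        for idx in used[used >= 0]:
            split_counts[idx] += 1
    ranking = pd.DataFrame({
        "descriptor": list(feature_names),
        "importance": importance,
        "n_splits": split_counts,
    }).sort_values(["importance", "descriptor"],
                   ascending=[False, True], kind="stable")
    return ranking.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROC, Youden cutoff, score normalization
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUROC (Mann-Whitney statistic, ties counted 1/2)."""
    y = _label_vector(labels)
    if len(np.unique(y)) < 2:
        raise DataError("ROC needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    auroc = float(roc_auc_score(y, scores))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auroc


def youden_cutoff(scores, labels) -> float:
    """The score threshold maximizing sensitivity + specificity - 1."""
    points, _ = roc_curve(scores, labels)
    real = points[np.isfinite(points["threshold"])]
    if len(real) < 2:
        raise DataError("degenerate ROC: cannot place a cutoff")
    j = (real["tpr"] - real["fpr"]).to_numpy()
    cut = float(real["threshold"].to_numpy()[int(np.argmax(j))])
    # Scores are probabilities; keep the cutoff strictly inside (0, 1) so
    # the normalization map is well defined.
    return min(max(cut, 1e-9), 1.0 - 1e-9)


def normalize_scores(scores, cutoff: float) -> np.ndarray:
    """Monotone piecewise-linear remap putting ``cutoff`` at 0.5.

    s' = 0.5 s / c for s <= c, else 0.5 + 0.5 (s - c) / (1 - c).  Strictly
    monotone, so the ROC point set — hence AUROC — is unchanged.
    """
    if not 0.0 < cutoff < 1.0:
        raise DataError("cutoff must be strictly inside (0, 1)")
    s = np.asarray(scores, dtype=float)
    return np.where(s <= cutoff,
                    0.5 * s / cutoff,
                    0.5 + 0.5 * (s - cutoff) / (1.0 - cutoff))


# ---------------------------------------------------------------------------
# Confusion-matrix metric suite
# ---------------------------------------------------------------------------

class ConfusionMatrix(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The nine threshold-based performance metrics (AUROC kept separate)."""

    accuracy: float
    precision: float
    npv: float
    recall: float
    specificity: float
    balanced_accuracy: float
    f1: float
    mcc: float
    zero_division_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k)
                for k in ("accuracy", "precision", "npv", "recall",
                          "specificity", "balanced_accuracy", "f1", "mcc")}


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """All threshold-based metrics from one confusion matrix.

    Any 0/0 ratio is defined as 0 and flagged; same convention for an MCC
    with a zero denominator.
    """
    tp, fp, fn, tn = cm
    if min(tp, fp, fn, tn) < 0:
        raise DataError("confusion-matrix counts must be >= 0")
    n = cm.n
    if n == 0:
        raise DataError("empty confusion matrix")
    flags = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    npv = ratio(tn, tn + fn, "npv")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    return MetricSet(
        accuracy=(tp + tn) / n, precision=precision, npv=npv, recall=recall,
        specificity=specificity, balanced_accuracy=(recall + specificity) / 2,
        f1=f1, mcc=float(mcc), zero_division_flags=tuple(flags))


def confusion_from_scores(scores_norm, labels,
                          threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix at a threshold; predictions are score > threshold."""
    y = _label_vector(labels)
    pred = np.asarray(scores_norm) > threshold
    return ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()), fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()), tn=int((~pred & (y == 0)).sum()))


# ---------------------------------------------------------------------------
# Model comparison and top-k sweep
# ---------------------------------------------------------------------------

def evaluate_model(model, train: pd.DataFrame, validation: pd.DataFrame,
                   features: Sequence[str],
                   label_column: str = "label") -> dict:
    """Train/validation AUROC plus thresholded metrics at the Youden cutoff.

    The cutoff is placed on the validation ROC, normalized to 0.5, and the
    confusion-matrix metrics are computed on the validation drugs at the
    normalized threshold.
    """
    features = list(features)
    scores_tr = predict_scores(model, train[features])
    scores_va = predict_scores(model, validation[features])
    _, auroc_tr = roc_curve(scores_tr, train[label_column])
    _, auroc_va = roc_curve(scores_va, validation[label_column])
    cutoff = youden_cutoff(scores_va, validation[label_column])
    normalized = normalize_scores(scores_va, cutoff)
    cm = confusion_from_scores(normalized, validation[label_column])
    metrics = compute_metrics(cm)
    return {"train_auroc": auroc_tr, "validation_auroc": auroc_va,
            "cutoff": cutoff, "confusion": cm, "metrics": metrics,
            "validation_scores": normalized}


def compare_algorithms(train: pd.DataFrame, validation: pd.DataFrame,
                       features: Sequence[str], config: ModelConfig,
                       label_column: str = "label") -> pd.DataFrame:
    """Fit all three learners on the same split; one metrics row each."""
    rows = []
    for algorithm in ("random_forest", "gradient_boosting", "neural_network"):
        cfg = ModelConfig(algorithm=algorithm, rf=config.rf, gb=config.gb,
                          nn=config.nn, seed=config.seed)
        model = fit_model(train[list(features)], train[label_column], cfg)
        ev = evaluate_model(model, train, validation, features, label_column)
        rows.append({"algorithm": algorithm,
                     "train_auroc": ev["train_auroc"],
                     "validation_auroc": ev["validation_auroc"],
                     "cutoff": ev["cutoff"],
                     **ev["metrics"].as_dict()})
    return pd.DataFrame(rows)


def top_k_model_sweep(train: pd.DataFrame, validation: pd.DataFrame,
                      ranking: pd.DataFrame, config: ModelConfig,
                      k_list: Sequence[int] = DEFAULT_K_LIST,
                      label_column: str = "label") -> pd.DataFrame:
    """Neural-network models on the top-k ranked descriptors, one row per k.

    The best k is the one maximizing validation AUROC (reported by the
    caller via the returned table).
    """
    ordered = ranking["descriptor"].tolist()
    rows = []
    for k in k_list:
        if k > len(ordered):
            raise DataError(f"k={k} exceeds {len(ordered)} descriptors")
        feats = ordered[:k]
        cfg = ModelConfig(algorithm="neural_network", rf=config.rf,
                          gb=config.gb, nn=config.nn, seed=config.seed)
        model = fit_model(train[feats], train[label_column], cfg)
        ev = evaluate_model(model, train, validation, feats, label_column)
        rows.append({"n_descriptors": k,
                     "train_auroc": ev["train_auroc"],
                     "validation_auroc": ev["validation_auroc"],
                     "cutoff": ev["cutoff"],
                     **ev["metrics"].as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Applicability domain and per-class accuracy
# ---------------------------------------------------------------------------

@dataclass
class ApplicabilityDomainResult:
    band: float
    retained_drugs: int
    confusion: ConfusionMatrix
    metrics: MetricSet
    retained_mask: np.ndarray


def applicability_domain(scores_norm, labels,
                         band: float) -> ApplicabilityDomainResult:
    """Exclude drugs within ``band`` of the normalized 0.5 cutoff.

    A drug is excluded iff |score - 0.5| <= band, so band 0 drops only exact
    ties at the cutoff.  Metrics are recomputed on the retained drugs.
    """
    s = np.asarray(scores_norm, dtype=float)
    retained = np.abs(s - 0.5) > band
    if not retained.any():
        raise DataError(f"band {band} excludes every drug")
    y = _label_vector(labels)[retained]
    cm = confusion_from_scores(s[retained], y)
    return ApplicabilityDomainResult(
        band=band, retained_drugs=int(retained.sum()), confusion=cm,
        metrics=compute_metrics(cm), retained_mask=retained)


def per_class_accuracy(drug_names, true_labels, predicted_labels,
                       atc_map: dict[str, str]) -> pd.DataFrame:
    """Per-4-character-ATC-class prediction counts and accuracy.

    Accuracy is the fraction of the class's drugs whose predicted label
    matches the signal-detection label; drugs absent from the ATC map are
    grouped under ``unmapped``.
    """
    frame = pd.DataFrame({
        "drug_name": list(drug_names),
        "true": _label_vector(true_labels),
        "pred": _label_vector(predicted_labels),
    })
    frame["atc_class"] = [
        str(atc_map[d])[:4] if d in atc_map and atc_map[d] else "unmapped"
        for d in frame["drug_name"]]
    rows = []
    for cls, grp in frame.groupby("atc_class"):
        rows.append({
            "atc_class": cls, "n_drugs": len(grp),
            "n_positive": int((grp["true"] == 1).sum()),
            "n_negative": int((grp["true"] == 0).sum()),
            "predicted_positive": int((grp["pred"] == 1).sum()),
            "predicted_negative": int((grp["pred"] == 0).sum()),
            "accuracy": float((grp["true"] == grp["pred"]).mean()),
        })
    return pd.DataFrame(rows).sort_values("atc_class").reset_index(drop=True)
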