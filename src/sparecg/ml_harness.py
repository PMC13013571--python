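"""Classification harness: leave-one-patient-out CV, KNN and decision-tree
models, Bayesian hyperparameter search, demographics, stratified reporting
and misclassification analysis.

Records come from patients, and records from the same patient are highly
correlated, so evaluation is leave-one-**patient**-out (LOPO): every fold
holds out all records of one patient, trains on the rest, and scores the
held-out records; overall metrics pool the per-record predictions.  The
positive class is "case" throughout; specificity equals the true negative
rate (TNR).

The hyperparameter search space is: KNN — one of 10 distance metrics ×
odd neighbour counts 1..99; decision tree — minimum leaf size 1..182.
Bayesian optimisation (Gaussian process surrogate, expected-improvement
acquisition) maximises LOPO accuracy over this space; spaces of at most
200 points are searched exhaustively instead.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm, rankdata
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.tree import DecisionTreeClassifier

CASE, CONTROL = "case", "control"

#: The 10 categorical KNN distance metrics of the search space.
KNN_METRICS = ("cityblock", "chebychev", "correlation", "cosine", "euclidean",
               "hamming", "jaccard", "minkowski", "seuclidean", "spearman")

KNN_NEIGHBOR_VALUES = tuple(range(1, 100, 2))  # odd 1..99
TREE_LEAF_VALUES = tuple(range(1, 183))        # 1..182

#: Minkowski exponent used when the `minkowski` metric is selected.  The
#: exponents 1 and 2 are already present as cityblock/euclidean, so the
#: distinct choice is 3.
MINKOWSKI_P = 3


# ---------------------------------------------------------------------------
# containers

@dataclass
class FeatureTable:
    """Per-record feature vectors keyed by patient, with binary labels.

    ``labels`` entries are "case" or "control".  ``ages``/``sexes`` may
    contain None when demographics are unknown.
    """

    record_ids: list[str]
    patient_ids: list[str]
    labels: list[str]
    X: np.ndarray
    feature_names: list[str]
    ages: list[float | None] = field(default_factory=list)
    sexes: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.record_ids)
        if self.X.shape != (n, len(self.feature_names)):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with {n} records x "
                f"{len(self.feature_names)} features"
            )
        if len(self.patient_ids) != n or len(self.labels) != n:
            raise ValueError("record_ids, patient_ids and labels must align")
        if len(set(self.record_ids)) != n:
            raise ValueError("record ids must be unique")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")
        if not self.ages:
            self.ages = [None] * n
        if not self.sexes:
            self.sexes = [None] * n

    def __len__(self) -> int:
        return len(self.record_ids)


@dataclass(frozen=True)
class ModelConfig:
    """One point of the hyperparameter space."""

    model: str = "knn"  # "knn" or "tree"
    knn_metric: str = "euclidean"
    knn_neighbors: int = 1
    tree_min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("knn", "tree"):
            raise ValueError(f"model must be 'knn' or 'tree', got {self.model!r}")
        if self.knn_metric not in KNN_METRICS:
            raise ValueError(f"unknown KNN metric {self.knn_metric!r}")
        if self.knn_neighbors not in KNN_NEIGHBOR_VALUES:
            raise ValueError("knn_neighbors must be odd, between 1 and 99")
        if self.tree_min_leaf not in TREE_LEAF_VALUES:
            raise ValueError("tree_min_leaf must lie in 1..182")


@dataclass(frozen=True)
class DemographicNormalization:
    """Optimised encoding of age and sex as extra features.

    Age maps linearly onto [Age1, Age1 + Age2]; sex maps to the scalar
    Sex1 (male) or Sex2 (female).  The published optimum is Age1=0.0103,
    Age2=0.9983, Sex1=0.0486, Sex2=0.0317.
    """

    age1: float = 0.0103
    age2: float = 0.9983
    sex1: float = 0.0486
    sex2: float = 0.0317


@dataclass
class CVResult:
    """Pooled leave-one-patient-out predictions and confusion metrics."""

    record_ids: list[str]
    truths: list[str]
    predictions: list[str]
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None

    @property
    def tnr(self) -> float | None:
        return self.specificity


# ---------------------------------------------------------------------------
# metrics

def confusion_metrics(tp: int, fn: int, fp: int, tn: int,
                      ) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    Case is the positive class.  Ratios with a zero denominator are
    returned as None (missing), never as zero.
    """
    counts = (tp, fn, fp, tn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    return accuracy, sensitivity, specificity


def _confusion_from_predictions(truths, predictions) -> tuple[int, int, int, int]:
    tp = sum(1 for t, p in zip(truths, predictions) if t == CASE and p == CASE)
    fn = sum(1 for t, p in zip(truths, predictions) if t == CASE and p == CONTROL)
    fp = sum(1 for t, p in zip(truths, predictions) if t == CONTROL and p == CASE)
    tn = sum(1 for t, p in zip(truths, predictions) if t == CONTROL and p == CONTROL)
    return tp, fn, fp, tn


# ---------------------------------------------------------------------------
# KNN on the 10-metric space

def _metric_distances(train_X: np.ndarray, test_X: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise (test x train) distances under one of the 10 named metrics."""
    if metric == "chebychev":  # study spelling of Chebyshev
        return cdist(test_X, train_X, metric="chebyshev")
    if metric == "minkowski":
        return cdist(test_X, train_X, metric="minkowski", p=MINKOWSKI_P)
    if metric == "seuclidean":
        v = np.var(train_X, axis=0, ddof=1)
        v[v == 0] = 1.0  # constant features contribute nothing
        return cdist(test_X, train_X, metric="seuclidean", V=v)
    if metric == "spearman":
        # correlation distance between within-row rank transforms
        tr = np.apply_along_axis(rankdata, 1, train_X)
        te = np.apply_along_axis(rankdata, 1, test_X)
        return cdist(te, tr, metric="correlation")
    return cdist(test_X, train_X, metric=metric)


def knn_predict(train_X: np.ndarray, train_y: list[str], test_X: np.ndarray,
                metric: str, n_neighbors: int) -> list[str]:
    """Majority-vote KNN with deterministic tie handling.

    Distance ties are broken by training-row order (stable sort); vote ties
    are broken toward "control" (prefer fewer false positives).
    """
    dist = _metric_distances(np.asarray(train_X, float), np.asarray(test_X, float), metric)
    dist = np.nan_to_num(dist, nan=np.inf)  # degenerate rows (zero variance)
    k = min(n_neighbors, dist.shape[1])
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    y = np.asarray(train_y, dtype=object)
    out = []
    for row in order:
        votes = Counter(y[row])
        out.append(CASE if votes[CASE] > votes[CONTROL] else CONTROL)
    return out


def _fit_predict(train_X, train_y, test_X, config: ModelConfig) -> list[str]:
    if config.model == "knn":
        return knn_predict(train_X, train_y, test_X,
                           config.knn_metric, config.knn_neighbors)
    tree = DecisionTreeClassifier(criterion="gini",
                                  min_samples_leaf=config.tree_min_leaf,
                                  random_state=config.seed)
    tree.fit(train_X, train_y)
    return list(tree.predict(test_X))


# ---------------------------------------------------------------------------
# leave-one-patient-out

def leave_one_patient_out_cv(table: FeatureTable, config: ModelConfig) -> CVResult:
    """One fold per unique patient; pooled per-record confusion metrics."""
    patients = list(dict.fromkeys(table.patient_ids))  # first-seen order
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    if len(set(table.labels)) < 2:
        raise ValueError("both case and control records are required")
    pid = np.asarray(table.patient_ids, dtype=object)
    labels = np.asarray(table.labels, dtype=object)
    predictions = np.empty(len(table), dtype=object)
    for patient in patients:
        held = pid == patient
        predictions[held] = _fit_predict(
            table.X[~held], list(labels[~held]), table.X[held], config
        )
    tp, fn, fp, tn = _confusion_from_predictions(table.labels, predictions)
    accuracy, sensitivity, specificity = confusion_metrics(tp, fn, fp, tn)
    return CVResult(record_ids=list(table.record_ids), truths=list(table.labels),
                    predictions=list(predictions), tp=tp, fn=fn, fp=fp, tn=tn,
                    accuracy=accuracy, sensitivity=sensitivity,
                    specificity=specificity)


def evaluate_on_controls(table: FeatureTable, config: ModelConfig,
                         test_X: np.ndarray) -> float:
    """Train on the full table and return the TNR on a control-only test set."""
    preds = _fit_predict(table.X, table.labels, np.asarray(test_X, float), config)
    return sum(p == CONTROL for p in preds) / len(preds)


# ---------------------------------------------------------------------------
# hyperparameter search

@dataclass
class OptimizationResult:
    best_config: ModelConfig
    best_accuracy: float
    optima: list[ModelConfig]     # all visited configs achieving best_accuracy
    n_evaluated: int


def _space(model: str, seed: int) -> list[ModelConfig]:
    if model == "knn":
        return [ModelConfig(model="knn", knn_metric=m, knn_neighbors=n, seed=seed)
                for m in KNN_METRICS for n in KNN_NEIGHBOR_VALUES]
    return [ModelConfig(model="tree", tree_min_leaf=leaf, seed=seed)
            for leaf in TREE_LEAF_VALUES]


def _encode(config: ModelConfig) -> np.ndarray:
    if config.model == "knn":
        onehot = np.zeros(len(KNN_METRICS))
        onehot[KNN_METRICS.index(config.knn_metric)] = 1.0
        return np.append(onehot, config.knn_neighbors / 99.0)
    return np.array([config.tree_min_leaf / 182.0])


def bayesian_optimize(table: FeatureTable, model: str = "knn",
                      n_iterations: int = 30, seed: int = 0,
                      space: list[ModelConfig] | None = None,
                      exhaustive_limit: int = 200) -> OptimizationResult:
    """Maximise LOPO accuracy over the hyperparameter space.

    Spaces of at most ``exhaustive_limit`` points are evaluated exhaustively;
    otherwise a Gaussian-process surrogate with expected-improvement
    acquisition proposes ``n_iterations`` evaluations (the first third
    random).  Deterministic given ``seed``.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    candidates = list(space) if space is not None else _space(model, seed)
    if not candidates:
        raise ValueError("empty search space")

    scores: dict[ModelConfig, float] = {}
    visited: list[ModelConfig] = []

    def evaluate(config: ModelConfig) -> float:
        acc = leave_one_patient_out_cv(table, config).accuracy
        scores[config] = acc
        visited.append(config)
        return acc

    if len(candidates) <= exhaustive_limit:
        for config in candidates:
            evaluate(config)
    else:
        rng = np.random.default_rng(seed)
        n_total = min(n_iterations, len(candidates))
        n_init = max(2, min(n_total, n_total // 3 + 1))
        init_idx = rng.choice(len(candidates), size=n_init, replace=False)
        for i in init_idx:
            evaluate(candidates[i])
        enc = np.array([_encode(c) for c in candidates])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-4,
            random_state=int(rng.integers(2**31)),
        )
        for _ in range(n_total - n_init):
            tried = np.array([c in scores for c in candidates])
            X_obs = np.array([_encode(c) for c in scores])
            y_obs = np.array(list(scores.values()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # kernel length-scale bound chatter
                gp.fit(X_obs, y_obs)
            mu, sigma = gp.predict(enc, return_std=True)
            best = y_obs.max()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best) / sigma
                ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma < 1e-12] = 0.0
            ei[tried] = -np.inf
            evaluate(candidates[int(np.argmax(ei))])

    best_accuracy = max(scores.values())
    optima = [c for c in visited if scores[c] == best_accuracy]
    return OptimizationResult(best_config=optima[0], best_accuracy=best_accuracy,
                              optima=optima, n_evaluated=len(visited))


def select_consensus_hyperparameters(
        per_combination_optima: list[tuple],
        query: int = 0) -> ModelConfig:
    """Resolve hyperparameter ties across (lead, N, k) combinations.

    Each entry is ``(lead, N, k, [optimal configs])``.  The modal config
    across all entries' optimal sets is taken; if it is optimal for the
    queried combination it is returned, otherwise the first entry of that
    combination's optimal list is.
    """
    if not per_combination_optima:
        raise ValueError("need at least one combination")
    counts: Counter = Counter()
    order: list[ModelConfig] = []
    for entry in per_combination_optima:
        for config in entry[3]:
            if config not in counts:
                order.append(config)
            counts[config] += 1
    if not counts:
        raise ValueError("every combination must have a nonempty optimal set")
    top = max(counts.values())
    mode = next(c for c in order if counts[c] == top)  # first-seen tie-break
    query_set = list(per_combination_optima[query][3])
    if not query_set:
        raise ValueError("queried combination has an empty optimal set")
    return mode if mode in query_set else query_set[0]


# ---------------------------------------------------------------------------
# demographics

def append_demographics(table: FeatureTable,
                        params: DemographicNormalization = DemographicNormalization(),
                        ) -> FeatureTable:
    """Append normalised age and sex feature columns.

    Age is min–max scaled over the table then mapped onto
    [Age1, Age1 + Age2]; sex becomes the scalar Sex1 (male) / Sex2 (female).
    """
    missing = [rid for rid, a, s in zip(table.record_ids, table.ages, table.sexes)
               if a is None or s is None]
    if missing:
        raise ValueError(f"records lacking age or sex: {missing}")
    ages = np.asarray(table.ages, dtype=float)
    lo, hi = ages.min(), ages.max()
    scaled = (ages - lo) / (hi - lo) if hi > lo else np.zeros_like(ages)
    age_feat = params.age1 + params.age2 * scaled
    sex_feat = np.array([params.sex1 if s == "male" else params.sex2
                         for s in table.sexes])
    X = np.column_stack([table.X, age_feat, sex_feat])
    return replace(table, X=X,
                   feature_names=table.feature_names + ["age_norm", "sex_norm"])


# ---------------------------------------------------------------------------
# stratified reporting

#: Default age bands; bands under 50 are pooled to avoid tiny strata.
DEFAULT_AGE_BANDS = (("<50", 0, 50), ("50-59", 50, 60), ("60-69", 60, 70),
                     ("70-79", 70, 80), ("80-89", 80, 90))


def stratified_report(result: CVResult, table: FeatureTable,
                      age_bands=DEFAULT_AGE_BANDS) -> pd.DataFrame:
    """Accuracy by age band × sex, plus marginals.

    Returns a tidy frame with columns (age_band, sex, n, accuracy); empty
    strata have n=0 and missing accuracy.  Count-weighted band accuracies
    pool exactly to the overall accuracy.
    """
    if any(a is None or s is None for a, s in zip(table.ages, table.sexes)):
        raise ValueError("stratified reporting requires ages and sexes for all records")
    correct = {rid: t == p for rid, t, p in
               zip(result.record_ids, result.truths, result.predictions)}
    frame = pd.DataFrame({
        "record_id": table.record_ids,
        "age": [float(a) for a in table.ages],
        "sex": table.sexes,
        "correct": [correct[rid] for rid in table.record_ids],
    })
    rows = []
    band_specs = list(age_bands) + [("all", -np.inf, np.inf)]
    for name, lo, hi in band_specs:
        in_band = frame[(frame.age >= lo) & (frame.age < hi)]
        for sex in ("male", "female", "all"):
            sub = in_band if sex == "all" else in_band[in_band.sex == sex]
            rows.append({
                "age_band": name, "sex": sex, "n": len(sub),
                "accuracy": sub.correct.mean() if len(sub) else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# misclassification analysis

def misclassification_analysis(per_configuration_predictions: dict[str, list[str]],
                               truth: dict[str, str],
                               threshold: float = 0.75) -> dict[str, str]:
    """Records wrong in at least ``threshold`` of their classifications.

    A record is flagged iff its wrong-prediction count is at least
    ceil(threshold × number of predictions) — e.g. 12 of 16 at 0.75.
    Flagged cases are tagged "false-negative", flagged controls
    "false-positive".
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    flagged: dict[str, str] = {}
    for record_id, preds in per_configuration_predictions.items():
        if not preds:
            raise ValueError(f"record {record_id} has no predictions")
        true_label = truth[record_id]
        wrong = sum(p != true_label for p in preds)
        if wrong >= math.ceil(threshold * len(preds)):
            flagged[record_id] = ("false-negative" if true_label == CASE
                                  else "false-positive")
    return flagged
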