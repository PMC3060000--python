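"""kNN ensemble QSAR with applicability domains, consensus scoring and evaluation.

The classifier ensemble follows the variable-selection kNN tradition: for
each internal training/test split a simulated-annealing search looks for
small descriptor subsets whose leave-one-out kNN classification of the
training compounds is accurate; models that also classify the internal test
split well (CCR >= ``accept_ccr``) are retained.  Each retained model carries
an applicability domain: a compound farther (on average, over its k nearest
training neighbors in the model's descriptor subspace) than
``mean + Z * sd`` of the training nearest-neighbor distances is outside the
domain and contributes no vote.

Consensus scoring averages the binary votes (nontoxic = 0, toxic = 1) of all
covering models; dual thresholds (T1 <= T2) convert the score into
nontoxic / inconclusive / toxic calls.  The evaluation metric throughout is
the correct classification rate CCR = 0.5 * (sensitivity + specificity),
i.e. balanced accuracy, computed over covered, conclusive compounds only,
with coverage reported alongside.

A random-forest companion (scikit-learn) is provided behind the same scoring
scale; only the consensus/evaluation layer around it is specific to this
package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .qhts_io import DescriptorMatrix

__all__ = [
    "ConsensusPrediction",
    "EvaluationReport",
    "KnnConfig",
    "KnnModel",
    "RandomForestModel",
    "classify_with_thresholds",
    "consensus_predict",
    "consensus_scores",
    "evaluate",
    "knn_predict",
    "pooled_consensus",
    "threshold_heatmap",
    "train_knn_ensemble",
    "train_random_forest",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Configuration and model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnnConfig:
    """Hyperparameters of the kNN ensemble search.

    ``k_range`` is inclusive.  The annealer proposes single-descriptor
    add/remove/swap moves, accepts by the Metropolis rule on leave-one-out
    training CCR, and cools geometrically; the initial temperature is
    calibrated so that roughly half of the initially-probed worsening moves
    would be accepted.
    """

    k_range: tuple[int, int] = (1, 5)
    subset_size_range: tuple[int, int] = (5, 40)
    accept_ccr: float = 0.70
    z_ad: float = 0.5
    n_proposals: int = 100       # proposals per temperature level
    cooling: float = 0.9
    min_acceptance: float = 0.01  # stop when acceptance rate drops below this
    max_temperatures: int = 30
    seed: int = 0


@dataclass
class KnnModel:
    """A single kNN classifier: descriptor subset + training references + AD."""

    descriptor_subset: tuple[str, ...]
    k: int
    training_ids: tuple[str, ...]
    training_x: np.ndarray       # rows aligned with training_ids, cols with subset
    training_labels: np.ndarray  # 0 = nontoxic, 1 = toxic
    ad_cutoff: float
    training_ccr: float
    test_ccr: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.descriptor_subset:
            raise ValueError("descriptor subset must be non-empty")
        if not self.ad_cutoff > 0:
            raise ValueError("ad_cutoff must be positive")


@dataclass(frozen=True)
class ConsensusPrediction:
    compound_id: str
    score: float | None          # mean of binary votes over covering models
    n_models_covering: int
    call: str                    # toxic | nontoxic | inconclusive | not_covered


@dataclass(frozen=True)
class EvaluationReport:
    """CCR / sensitivity / specificity over conclusive calls, plus coverage."""

    ccr: float | None
    sensitivity: float | None
    specificity: float | None
    coverage: float
    n_evaluated: int
    n_conclusive: int


# ---------------------------------------------------------------------------
# kNN internals
# ---------------------------------------------------------------------------

def _vote(neighbor_labels: np.ndarray, neighbor_dists: np.ndarray, k: int) -> int:
    """Majority vote; even-k ties fall back to inverse-distance weights, then 0."""
    pos = int(neighbor_labels.sum())
    if 2 * pos > k:
        return 1
    if 2 * pos < k:
        return 0
    w = 1.0 / (neighbor_dists + _EPS)
    s_pos = float(w[neighbor_labels == 1].sum())
    s_neg = float(w[neighbor_labels == 0].sum())
    return 1 if s_pos > s_neg else 0


def _knn_predict_batch(
    xq: np.ndarray, x_train: np.ndarray, y_train: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and mean k-nearest distance for each query row."""
    d = cdist(xq, x_train)
    k_eff = min(k, x_train.shape[0])
    idx = np.argpartition(d, k_eff - 1, axis=1)[:, :k_eff]
    rows = np.arange(d.shape[0])[:, None]
    nd = d[rows, idx]
    preds = np.array(
        [_vote(y_train[idx[i]], nd[i], k_eff) for i in range(d.shape[0])], dtype=int
    )
    return preds, nd.mean(axis=1)


def _loo_predictions(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    k_eff = min(k, x.shape[0] - 1)
    idx = np.argpartition(d, k_eff - 1, axis=1)[:, :k_eff]
    rows = np.arange(d.shape[0])[:, None]
    nd = d[rows, idx]
    return np.array([_vote(y[idx[i]], nd[i], k_eff) for i in range(x.shape[0])], dtype=int)


def _ccr_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sens = float((y_pred[y_true == 1] == 1).mean()) if (y_true == 1).any() else 0.0
    spec = float((y_pred[y_true == 0] == 0).mean()) if (y_true == 0).any() else 0.0
    return 0.5 * (sens + spec)


def _loo_ccr(x: np.ndarray, y: np.ndarray, k: int) -> float:
    return _ccr_from_predictions(y, _loo_predictions(x, y, k))


def _propose(
    subset: list[int], n_desc: int, size_range: tuple[int, int], rng: np.random.Generator
) -> list[int]:
    """Swap one descriptor in/out, or grow/shrink by one within the size bounds."""
    inside = set(subset)
    outside = [j for j in range(n_desc) if j not in inside]
    lo, hi = size_range
    moves = []
    if outside and subset:
        moves.append("swap")
    if outside and len(subset) < hi:
        moves.append("add")
    if len(subset) > lo and len(subset) > 1:
        moves.append("remove")
    if not moves:
        return list(subset)
    move = moves[rng.integers(len(moves))]
    new = list(subset)
    if move == "swap":
        new[rng.integers(len(new))] = outside[rng.integers(len(outside))]
    elif move == "add":
        new.append(outside[rng.integers(len(outside))])
    else:
        new.pop(rng.integers(len(new)))
    return new


def _anneal_subset(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    config: KnnConfig,
    rng: np.random.Generator,
) -> tuple[list[int], float]:
    """Simulated-annealing search for a descriptor subset maximizing LOO CCR."""
    n_desc = x.shape[1]
    lo = max(1, min(config.subset_size_range[0], n_desc))
    hi = min(config.subset_size_range[1], n_desc)
    size_range = (lo, hi)
    size0 = int(rng.integers(lo, hi + 1))
    subset = list(rng.choice(n_desc, size=size0, replace=False))
    score = _loo_ccr(x[:, subset], y, k)
    best_subset, best_score = list(subset), score

    # Calibrate T0 from the magnitude of worsening moves near the start.
    drops = []
    for _ in range(12):
        cand = _propose(subset, n_desc, size_range, rng)
        s = _loo_ccr(x[:, cand], y, k)
        if s < score:
            drops.append(score - s)
    t = (float(np.median(drops)) / math.log(2.0)) if drops else 0.05
    t = max(t, 1e-4)

    for _level in range(config.max_temperatures):
        accepted = 0
        for _ in range(config.n_proposals):
            cand = _propose(subset, n_desc, size_range, rng)
            s = _loo_ccr(x[:, cand], y, k)
            delta = s - score
            if delta >= 0 or rng.random() < math.exp(delta / t):
                subset, score = cand, s
                accepted += 1
                if score > best_score:
                    best_subset, best_score = list(subset), score
        t *= config.cooling
        if accepted / config.n_proposals < config.min_acceptance:
            break
    return best_subset, best_score


def _ad_cutoff(x: np.ndarray, k: int, z: float) -> float:
    """Applicability-domain distance D = mean + Z * sd of training NN distances.

    The statistic matches prediction time: each training compound's mean
    distance to its k nearest other training compounds.
    """
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    k_eff = min(k, x.shape[0] - 1)
    nd = np.sort(d, axis=1)[:, :k_eff].mean(axis=1)
    cutoff = float(nd.mean() + z * nd.std())
    return max(cutoff, _EPS)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_knn_ensemble(
    internal_splits: Sequence[tuple[Sequence[str], Sequence[str]]],
    matrix: DescriptorMatrix,
    labels: Mapping[str, int],
    config: KnnConfig = KnnConfig(),
) -> list[KnnModel]:
    """Train one annealed kNN model per (internal split, k) and keep the good ones.

    A model is retained when its CCR on the internal test split reaches
    ``config.accept_ccr``; its applicability-domain cutoff is computed from
    its own training compounds in its own descriptor subspace.
    """
    rng = np.random.default_rng(config.seed)
    names = matrix.descriptor_names
    models: list[KnnModel] = []
    for split_no, (train_ids, test_ids) in enumerate(internal_splits):
        train_ids, test_ids = list(train_ids), list(test_ids)
        x_train = matrix.subset_compounds(train_ids).values
        y_train = np.array([labels[c] for c in train_ids], dtype=int)
        if len(set(y_train)) < 2:
            raise ValueError(f"internal split {split_no}: training side has a single class")
        x_test = matrix.subset_compounds(test_ids).values
        y_test = np.array([labels[c] for c in test_ids], dtype=int)
        n_before = len(models)
        for k in range(config.k_range[0], config.k_range[1] + 1):
            subset, train_ccr = _anneal_subset(x_train, y_train, k, config, rng)
            preds, _ = _knn_predict_batch(x_test[:, subset], x_train[:, subset], y_train, k)
            test_ccr = _ccr_from_predictions(y_test, preds)
            if test_ccr >= config.accept_ccr:
                models.append(
                    KnnModel(
                        descriptor_subset=tuple(names[j] for j in subset),
                        k=k,
                        training_ids=tuple(train_ids),
                        training_x=x_train[:, subset].copy(),
                        training_labels=y_train,
                        ad_cutoff=_ad_cutoff(x_train[:, subset], k, config.z_ad),
                        training_ccr=train_ccr,
                        test_ccr=test_ccr,
                    )
                )
        if len(models) == n_before:
            warnings.warn(
                f"internal split {split_no}: no model reached CCR {config.accept_ccr:.2f}"
            )
    return models


def knn_predict(model: KnnModel, vector) -> tuple[int, bool]:
    """Classify one compound with one model; second element is in-domain status."""
    xq = _extract_vector(model.descriptor_subset, vector)
    preds, mean_dist = _knn_predict_batch(
        xq[None, :], model.training_x, model.training_labels, model.k
    )
    return int(preds[0]), bool(mean_dist[0] <= model.ad_cutoff)


def _extract_vector(subset: Sequence[str], vector) -> np.ndarray:
    if isinstance(vector, pd.Series):
        missing = [n for n in subset if n not in vector.index]
        if missing:
            raise ValueError(f"vector lacks descriptors: {missing[:5]}")
        return vector[list(subset)].to_numpy(dtype=float)
    if isinstance(vector, Mapping):
        missing = [n for n in subset if n not in vector]
        if missing:
            raise ValueError(f"vector lacks descriptors: {missing[:5]}")
        return np.array([float(vector[n]) for n in subset])
    arr = np.asarray(vector, dtype=float)
    if arr.shape != (len(subset),):
        raise ValueError(f"expected vector of length {len(subset)}, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Random forest companion
# ---------------------------------------------------------------------------

@dataclass
class RandomForestModel:
    """Off-the-shelf random forest behind the consensus-score interface."""

    classifier: RandomForestClassifier
    descriptor_names: tuple[str, ...]

    def predict_scores(self, matrix: DescriptorMatrix) -> pd.Series:
        """Probability of the toxic class, on the [0, 1] consensus scale."""
        x = matrix.data[list(self.descriptor_names)].to_numpy()
        proba = self.classifier.predict_proba(x)
        toxic_col = list(self.classifier.classes_).index(1)
        return pd.Series(proba[:, toxic_col], index=matrix.compound_ids)

    @property
    def importances(self) -> pd.Series:
        return pd.Series(
            self.classifier.feature_importances_, index=list(self.descriptor_names)
        ).sort_values(ascending=False)


def train_random_forest(
    matrix: DescriptorMatrix,
    labels: Mapping[str, int],
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestModel:
    y = np.array([labels[c] for c in matrix.compound_ids], dtype=int)
    if len(set(y)) < 2:
        raise ValueError("random forest needs both classes in the training set")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(matrix.values, y)
    return RandomForestModel(classifier=clf, descriptor_names=tuple(matrix.descriptor_names))


# ---------------------------------------------------------------------------
# Consensus scoring and classification
# ---------------------------------------------------------------------------

def consensus_scores(
    models: Sequence[KnnModel], matrix: DescriptorMatrix
) -> tuple[pd.Series, pd.Series]:
    """Consensus score and covering-model count for every compound in ``matrix``.

    The score is the mean binary vote over models whose applicability domain
    contains the compound; compounds covered by no model get a NaN score.
    """
    if not models:
        raise ValueError("need at least one model")
    n = matrix.shape[0]
    vote_sum = np.zeros(n)
    cover = np.zeros(n, dtype=int)
    for model in models:
        x = matrix.data[list(model.descriptor_subset)].to_numpy()
        preds, mean_dist = _knn_predict_batch(x, model.training_x, model.training_labels, model.k)
        in_ad = mean_dist <= model.ad_cutoff
        vote_sum[in_ad] += preds[in_ad]
        cover += in_ad.astype(int)
    with np.errstate(invalid="ignore"):
        score = np.where(cover > 0, vote_sum / np.maximum(cover, 1), np.nan)
    ids = matrix.compound_ids
    return pd.Series(score, index=ids), pd.Series(cover, index=ids)


def consensus_predict(
    models: Sequence[KnnModel],
    vector,
    compound_id: str = "",
    t1: float = 0.5,
    t2: float = 0.5,
) -> ConsensusPrediction:
    if not models:
        raise ValueError("need at least one model")
    votes = []
    covering = 0
    for model in models:
        pred, in_ad = knn_predict(model, vector)
        if in_ad:
            votes.append(pred)
            covering += 1
    if covering == 0:
        return ConsensusPrediction(compound_id, None, 0, "not_covered")
    score = float(np.mean(votes))
    return ConsensusPrediction(
        compound_id, score, covering, classify_with_thresholds(score, t1, t2)
    )


def classify_with_thresholds(score: float, t1: float, t2: float) -> str:
    """Dual-threshold call: <= T1 nontoxic, >= T2 toxic, between inconclusive.

    With T1 == T2 (single-threshold classification) the comparisons become
    strict and a score exactly at the threshold is inconclusive.
    """
    if not (0.0 <= t1 <= t2 <= 1.0):
        raise ValueError(f"need 0 <= t1 <= t2 <= 1, got t1={t1}, t2={t2}")
    if t1 == t2:
        if score < t1:
            return "nontoxic"
        if score > t2:
            return "toxic"
        return "inconclusive"
    if score <= t1:
        return "nontoxic"
    if score >= t2:
        return "toxic"
    return "inconclusive"


def calls_from_scores(
    scores: Mapping[str, float] | pd.Series, t1: float, t2: float
) -> dict[str, str]:
    """Vector form of :func:`classify_with_thresholds`; NaN scores -> not_covered."""
    items = scores.items() if isinstance(scores, Mapping) else scores.items()
    calls = {}
    for cid, s in items:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            calls[cid] = "not_covered"
        else:
            calls[cid] = classify_with_thresholds(float(s), t1, t2)
    return calls


def evaluate(calls: Mapping[str, str], truth: Mapping[str, int]) -> EvaluationReport:
    """Score calls against truth.

    Sensitivity (specificity) is the correctly predicted fraction of toxic
    (nontoxic) compounds among covered, conclusive calls; coverage is the
    conclusive fraction of all evaluated compounds; CCR = 0.5 * (sens + spec),
    undefined when a class has no conclusive calls.
    """
    ids = [c for c in calls if c in truth]
    if not ids:
        raise ValueError("no compounds with both a call and a truth label")
    conclusive = [c for c in ids if calls[c] in ("toxic", "nontoxic")]
    coverage = len(conclusive) / len(ids)
    tox = [c for c in conclusive if truth[c] == 1]
    non = [c for c in conclusive if truth[c] == 0]
    sens = (sum(calls[c] == "toxic" for c in tox) / len(tox)) if tox else None
    spec = (sum(calls[c] == "nontoxic" for c in non) / len(non)) if non else None
    ccr = 0.5 * (sens + spec) if (sens is not None and spec is not None) else None
    return EvaluationReport(
        ccr=ccr,
        sensitivity=sens,
        specificity=spec,
        coverage=coverage,
        n_evaluated=len(ids),
        n_conclusive=len(conclusive),
    )


def pooled_consensus(knn_scores: pd.Series, rf_scores: pd.Series) -> pd.Series:
    """Average kNN consensus and random-forest scores per compound.

    Both inputs live on the same [0, 1] toxic-probability scale, so pooling
    is a plain mean; a compound uncovered by the kNN ensemble (NaN score)
    falls back to the forest score alone.  Keeping the learners separate is
    the default reporting mode — this pooled mode serves averaged
    classifications across all models of both kinds.
    """
    df = pd.concat({"knn": pd.Series(knn_scores), "rf": pd.Series(rf_scores)}, axis=1)
    return df.mean(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# Ensemble serialization
# ---------------------------------------------------------------------------

def ensemble_to_dict(models: Sequence[KnnModel], meta: Mapping | None = None) -> dict:
    """JSON-ready document holding every model's subset, references and cutoff."""
    return {
        "meta": dict(meta or {}),
        "models": [
            {
                "descriptor_subset": list(m.descriptor_subset),
                "k": m.k,
                "training_ids": list(m.training_ids),
                "training_x": m.training_x.tolist(),
                "training_labels": m.training_labels.tolist(),
                "ad_cutoff": m.ad_cutoff,
                "training_ccr": m.training_ccr,
                "test_ccr": m.test_ccr,
            }
            for m in models
        ],
    }


def ensemble_from_dict(doc: Mapping) -> list[KnnModel]:
    return [
        KnnModel(
            descriptor_subset=tuple(m["descriptor_subset"]),
            k=int(m["k"]),
            training_ids=tuple(m["training_ids"]),
            training_x=np.asarray(m["training_x"], dtype=float),
            training_labels=np.asarray(m["training_labels"], dtype=int),
            ad_cutoff=float(m["ad_cutoff"]),
            training_ccr=float(m["training_ccr"]),
            test_ccr=None if m.get("test_ccr") is None else float(m["test_ccr"]),
        )
        for m in doc["models"]
    ]


@dataclass(frozen=True)
class HeatmapGrids:
    thresholds: np.ndarray   # shared T1 / T2 axis
    ccr: np.ndarray          # ccr[i, j] for t1 = thresholds[i], t2 = thresholds[j]
    coverage: np.ndarray     # NaN where t1 > t2 or the metric is undefined


def threshold_heatmap(
    scores: Mapping[str, float] | pd.Series,
    truth: Mapping[str, int],
    grid_step: float = 0.05,
) -> HeatmapGrids:
    """CCR and coverage over every valid (T1, T2) threshold pair.

    The diagonal (T1 == T2) reproduces single-threshold classification;
    widening the inconclusive zone can only shrink coverage.
    """
    ts = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    n = len(ts)
    ccr = np.full((n, n), np.nan)
    cov = np.full((n, n), np.nan)
    for i, t1 in enumerate(ts):
        for j, t2 in enumerate(ts):
            if t1 > t2:
                continue
            report = evaluate(calls_from_scores(scores, float(t1), float(t2)), truth)
            cov[i, j] = report.coverage
            if report.ccr is not None:
                ccr[i, j] = report.ccr
    return HeatmapGrids(thresholds=ts, ccr=ccr, coverage=cov)
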