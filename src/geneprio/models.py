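"""The four classifiers, the 0-100 gene score, evaluation and explanation.

Model kinds and their fixed hyperparameters:

* ``lr`` — unpenalized logistic regression, Newton-CG solver.
* ``svc`` — linear support vector classifier, squared hinge loss, C=0.1,
  L2 penalty, tolerance 1e-5. The printed decision rule is the signum of
  the margin, which cannot rank; for scoring, the margin is mapped through
  a logistic and scaled to 0-100.
* ``mlp`` — multilayer perceptron, two hidden layers of 8 tanh units,
  L-BFGS, tolerance 1e-5, at most 60 iterations.
* ``cnn`` — the 1D convnet of :class:`geneprio._nn.CNNClassifier`.

A gene's score is ``Score(g) = 100 * e^{z2} / (e^{z1} + e^{z2})`` where
``z2``/``z1`` are the positive/negative class inputs to the softmax; genes
scoring strictly above 50 are "credible".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import mannwhitneyu
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from ._nn import CNNClassifier
from .features import ScalerParams, standardize
from .types import FEATURE_NAMES, ScoredGene

logger = logging.getLogger(__name__)

MODEL_KINDS = ("lr", "svc", "mlp", "cnn")
CREDIBLE_THRESHOLD = 50.0


@dataclass(frozen=True)
class LinearModelParams:
    w: np.ndarray
    b: float


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


# ---------------------------------------------------------------------------
# closed-form scoring primitives


def logistic_probability(params: LinearModelParams, x: np.ndarray) -> float:
    """P(Y=1|x) = e^{w.x+b} / (1 + e^{w.x+b}), computed overflow-safe."""
    return float(expit(np.dot(params.w, x) + params.b))


def svc_decision(params: LinearModelParams, x: np.ndarray) -> int:
    """Signum of the margin: 1 / 0 / -1 for positive / zero / negative."""
    margin = np.dot(params.w, x) + params.b
    return int(np.sign(margin))


def softmax_score(z1: float, z2: float) -> float:
    """100 * e^{z2} / (e^{z1} + e^{z2}), stable for any magnitudes."""
    return float(100.0 * expit(z2 - z1))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """A trained classifier plus the scoring contract.

    ``scores`` returns the 0-100 gene score per row; ``predict`` applies the
    strict >50 credibility rule. The feature order and any scaler are part
    of the artifact so candidates are always scored in the training frame.
    """

    kind: str
    estimator: object
    scaler: ScalerParams | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    seed: int | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(X)
        if self.kind == "svc":
            margin = self.estimator.decision_function(X)
            return 100.0 * expit(margin)
        proba = self.estimator.predict_proba(X)
        return 100.0 * proba[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) > CREDIBLE_THRESHOLD).astype(int)

    @property
    def linear_params(self) -> LinearModelParams:
        if self.kind not in {"lr", "svc"}:
            raise ValueError(f"{self.kind} is not a linear model")
        return LinearModelParams(
            w=np.asarray(self.estimator.coef_).ravel(),
            b=float(np.asarray(self.estimator.intercept_).ravel()[0]),
        )


def _make_estimator(kind: str, config: dict, seed: int):
    cfg = dict(config or {})
    if kind == "lr":
        # C=inf == no penalty (the penalty= spelling is deprecated in sklearn)
        return LogisticRegression(C=cfg.pop("C", np.inf), solver="newton-cg",
                                  max_iter=cfg.pop("max_iter", 200), **cfg)
    if kind == "svc":
        return LinearSVC(tol=cfg.pop("tol", 1e-5), loss="squared_hinge",
                         C=cfg.pop("C", 0.1), penalty="l2", **cfg)
    if kind == "mlp":
        return MLPClassifier(
            activation="tanh", solver="lbfgs",
            hidden_layer_sizes=cfg.pop("hidden_layer_sizes", (8, 8)),
            tol=cfg.pop("tol", 1e-5), max_iter=cfg.pop("max_iter", 60),
            random_state=seed, **cfg,
        )
    if kind == "cnn":
        return CNNClassifier(seed=seed, **cfg)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def train_model(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
    scaler: ScalerParams | None = None,
    fit_scaler: bool = False,
) -> FittedModel:
    """Fit one classifier on (already standardized) features.

    Pass ``fit_scaler=True`` to learn z-scoring from ``X`` and bake it into
    the artifact (the usual path when X is raw feature counts).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must be binary 0/1, got classes {classes}")
    if fit_scaler:
        Xs, scaler = standardize(X)
    else:
        Xs = scaler.transform(X) if scaler is not None else X
    if (Xs.std(axis=0) == 0).all():
        logger.warning("all features constant; model will be at chance level")
    est = _make_estimator(kind, config or {}, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xs, y)
    return FittedModel(kind=kind, estimator=est, scaler=scaler, seed=seed)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(model: FittedModel | None, X: np.ndarray, y: np.ndarray,
             y_pred: np.ndarray | None = None) -> Metrics:
    """Accuracy/precision/recall/F1 with the credible class positive.

    Zero-division cases (no predicted or no true positives) yield metric 0.
    """
    y = np.asarray(y, dtype=int)
    if y_pred is None:
        y_pred = model.predict(X)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y == 1)))
    fp = int(np.sum((y_pred == 1) & (y == 0)))
    fn = int(np.sum((y_pred == 0) & (y == 1)))
    tn = int(np.sum((y_pred == 0) & (y == 0)))
    acc = (tp + tn) / len(y) if len(y) else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return Metrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


@dataclass
class CVReport:
    grid: list[dict]
    fold_metrics: list[list[Metrics]]  # per setting, per fold
    mean_f1: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mean_f1:
            self.mean_f1 = [float(np.mean([m.f1 for m in fm]))
                            for fm in self.fold_metrics]

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.mean_f1))

    @property
    def best_setting(self) -> dict:
        return self.grid[self.best_index]

    def mean_metrics(self, index: int | None = None) -> Metrics:
        fm = self.fold_metrics[self.best_index if index is None else index]
        return Metrics(*(float(np.mean([getattr(m, f) for m in fm]))
                         for f in ("accuracy", "precision", "recall", "f1")))


def cross_validate(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[dict] | None = None,
    folds: int = 4,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold grid search; every sample validated once per setting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError(f"need >= 2 folds, got {folds}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"{folds} folds but smallest class has {counts.min()} samples"
        )
    grid = list(grid) if grid else [{}]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    fold_metrics = []
    for setting in grid:
        per_fold = []
        for tr_idx, va_idx in splits:
            m = train_model(kind, X[tr_idx], y[tr_idx], config=setting,
                            seed=seed, fit_scaler=True)
            per_fold.append(evaluate(m, X[va_idx], y[va_idx]))
        fold_metrics.append(per_fold)
    return CVReport(grid=grid, fold_metrics=fold_metrics)


# ---------------------------------------------------------------------------
# prioritization


def prioritize(model: FittedModel, gene_ids: Sequence[str], X: np.ndarray) -> list[ScoredGene]:
    """Score candidates and rank them (descending score, gene-id tie-break)."""
    if len(gene_ids) == 0:
        return []
    scores = model.scores(X)
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return [
        ScoredGene(gene_id=gene_ids[i], score=float(scores[i]), rank=rank)
        for rank, i in enumerate(order, start=1)
    ]


def select_eval_groups(
    ranked: Sequence[ScoredGene], k: int = 10
) -> tuple[list[ScoredGene], list[ScoredGene], list[ScoredGene]]:
    """(CTk, CLk, NTk): top-k credible, bottom-k credible, top-k non-credible.

    Groups truncate when fewer genes are available; with under 2k credible
    genes CTk and CLk overlap.
    """
    credible = [g for g in ranked if g.credible]
    non_credible = [g for g in ranked if not g.credible]
    return credible[:k], credible[-k:], non_credible[:k]


def rank_sum_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration when both groups are
    small (n <= 8) and tie-free, else tie-corrected normal approximation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# local-surrogate explanation


def explain(
    score_fn: Callable[[np.ndarray], np.ndarray] | FittedModel,
    x: np.ndarray,
    background: np.ndarray,
    n_perturb: int = 1000,
    seed: int = 0,
    kernel_width: float | None = None,
) -> np.ndarray:
    """Local linear surrogate of the model around one instance.

    Perturbations are drawn per-feature from a normal with the background's
    mean and sd, weighted by exp(-d^2 / width^2) on standardized distance to
    ``x``, and a weighted ridge surrogate is fitted to the model's scores in
    the standardized frame. Returns the surrogate coefficients per feature.
    """
    if isinstance(score_fn, FittedModel):
        model = score_fn
        score_fn = model.scores
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    d = x.shape[0]
    if n_perturb < 10 * d:
        logger.warning("n_perturb=%d is small for %d features; surrogate may be "
                       "unstable", n_perturb, d)
    rng = np.random.default_rng(seed)
    mu = background.mean(axis=0)
    sd = background.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = rng.standard_normal((n_perturb, d))
    Xp = mu + Z * sd
    Xp[0] = x  # anchor the instance itself
    Zstd = (Xp - mu) / sd
    xstd = (x - mu) / sd
    if kernel_width is None:
        kernel_width = np.sqrt(d) * 0.75
    dist = np.linalg.norm(Zstd - xstd, axis=1)
    weights = np.exp(-(dist**2) / kernel_width**2)
    yhat = np.asarray(score_fn(Xp), dtype=float)
    reg = Ridge(alpha=1.0)
    reg.fit(Zstd, yhat, sample_weight=weights)
    return np.asarray(reg.coef_, dtype=float)


def aggregate_importance(explanations: Iterable[np.ndarray]) -> np.ndarray:
    """Mean |surrogate weight| per feature, scaled so the max is 100."""
    W = np.abs(np.asarray(list(explanations), dtype=float))
    if W.size == 0:
        raise ValueError("need at least one explanation")
    mean_abs = W.mean(axis=0)
    top = mean_abs.max()
    if top == 0:
        logger.warning("all surrogate weights are zero; importance undefined")
        return np.zeros_like(mean_abs)
    return 100.0 * mean_abs / top
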