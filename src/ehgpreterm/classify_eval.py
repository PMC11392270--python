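"""Classifier training, confusion/ROC metrics, repeated leak-free
evaluation, averaged ROC curves and decision boundaries, and the
two-feature linear composite biomarker.

The five classifier configurations mirror widely used defaults: linear and
quadratic discriminant analysis in their "pseudo" variants (a singular
covariance falls back to a pseudo-inverse instead of failing), Gaussian
naive Bayes with empirical class priors, and SVMs with 3rd-order polynomial
and RBF kernels solved by SMO.  The premature class is the positive class
(label 1) throughout, and every model exposes a continuous score oriented
so that larger means more premature-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .errors import ParameterError
from .records_io import FeatureTable
from .resampling import LeakAudit, PartitionPlan, smote_oversample
from .util import child_seed

CLASSIFIER_KINDS = (
    "lda_pseudo",
    "qda_pseudo",
    "gnb_empirical",
    "svm_poly3",
    "svm_rbf",
)

DISPLAY_NAMES = {
    "lda_pseudo": "LDA",
    "qda_pseudo": "QDA",
    "gnb_empirical": "Naive Bayes",
    "svm_poly3": "SVM Poly3",
    "svm_rbf": "SVM RBF",
}

METRIC_NAMES = ("Se", "Sp", "PPV", "NPV", "CA", "AUC")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    options: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(
                f"unknown classifier {self.kind!r}; known: {CLASSIFIER_KINDS}"
            )

    @property
    def display_name(self) -> str:
        return DISPLAY_NAMES[self.kind]


def _make_estimator(spec: ClassifierSpec, seed: int):
    opts = dict(spec.options)
    if spec.kind == "lda_pseudo":
        # the SVD solver handles singular pooled covariance like a pseudo-inverse
        return LinearDiscriminantAnalysis(solver="svd", **opts)
    if spec.kind == "qda_pseudo":
        # a tiny covariance regularizer plays the role of the pseudo-inverse:
        # rank-deficient class covariances train and predict without failure
        return QuadraticDiscriminantAnalysis(reg_param=opts.pop("reg_param", 1e-9), **opts)
    if spec.kind == "gnb_empirical":
        return GaussianNB(**opts)  # default priors are the empirical frequencies
    if spec.kind == "svm_poly3":
        return SVC(kernel="poly", degree=3, random_state=seed, **opts)
    if spec.kind == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **opts)
    raise ParameterError(spec.kind)


class _FastLDA:
    """Closed-form two-class LDA with pooled-covariance pseudo-inverse.

    Lightweight equivalent of the sklearn estimator for the inner
    feature-selection loop (same decision rule; a fraction of the fit cost).
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FastLDA":
        X0, X1 = X[y == 0], X[y == 1]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n = len(X)
        S = (
            (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
        ) / max(n - 2, 1)
        w = np.linalg.pinv(np.atleast_2d(S)) @ (mu1 - mu0)
        self._w = w
        self._b = -0.5 * (mu0 + mu1) @ w + np.log(len(X1) / len(X0))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X @ self._w + self._b > 0).astype(int)


class _FastGNB:
    """Gaussian naive Bayes with empirical priors (sklearn-equivalent)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FastGNB":
        eps = 1e-9 * X.var(axis=0).max()
        self._stats = []
        n = len(X)
        for c in (0, 1):
            Xc = X[y == c]
            self._stats.append(
                (Xc.mean(axis=0), Xc.var(axis=0) + eps, np.log(len(Xc) / n))
            )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        ll = np.empty((len(X), 2))
        for c, (mu, var, logprior) in enumerate(self._stats):
            ll[:, c] = logprior - 0.5 * (
                np.log(2 * np.pi * var) + (X - mu) ** 2 / var
            ).sum(axis=1)
        return (ll[:, 1] > ll[:, 0]).astype(int)


def _fast_estimator(spec: ClassifierSpec, seed: int):
    """Estimator for the inner CV loop: closed-form for LDA/GNB, sklearn
    otherwise."""
    if spec.kind == "lda_pseudo" and not spec.options:
        return _FastLDA()
    if spec.kind == "gnb_empirical" and not spec.options:
        return _FastGNB()
    return _make_estimator(spec, seed)


@dataclass
class TrainedModel:
    """Opaque trained classifier: hard predictions + premature likelihood."""

    spec: ClassifierSpec
    feature_names: tuple[str, ...]
    estimator: object

    def _X(self, X) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.values[list(self.feature_names)]
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._X(X)), dtype=int)

    def likelihood(self, X) -> np.ndarray:
        """P(premature)-like score in [0, 1]; margin classifiers are squashed
        through a logistic so the 0.5 level matches their decision boundary."""
        X = self._X(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            col = list(est.classes_).index(1)
            return proba[:, col]
        dec = est.decision_function(X)
        if est.classes_[0] == 1:  # orient: positive margin => premature
            dec = -dec
        return 1.0 / (1.0 + np.exp(-dec))

    def score(self, X) -> np.ndarray:
        return self.likelihood(X)


def train_classifier(
    spec: ClassifierSpec,
    train: FeatureTable,
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier on a (typically SMOTE-balanced) training table."""
    if len(set(train.y)) < 2:
        raise ParameterError("training data must contain both classes")
    est = _make_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings from pseudo variants
        est.fit(train.values.to_numpy(dtype=float), train.y)
    return TrainedModel(
        spec=spec, feature_names=tuple(train.feature_names), estimator=est
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    TP: int
    FN: int
    TN: int
    FP: int
    Se: float
    Sp: float
    PPV: float
    NPV: float
    CA: float
    AUC: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> Metrics:
    """Exact count arithmetic for Se, Sp, PPV, NPV, CA (premature == 1)."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.size == 0:
        raise ParameterError("empty input")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    return Metrics(
        TP=tp,
        FN=fn,
        TN=tn,
        FP=fp,
        Se=_ratio(tp, tp + fn, "Se"),
        Sp=_ratio(tn, tn + fp, "Sp"),
        PPV=_ratio(tp, tp + fp, "PPV"),
        NPV=_ratio(tn, tn + fn, "NPV"),
        CA=_ratio(tp + tn, tp + fn + tn + fp, "CA"),
    )


@dataclass
class ROCCurve:
    fpr: np.ndarray  # 1 - Sp, non-decreasing, starts 0 ends 1
    tpr: np.ndarray  # Se
    auc: float


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> ROCCurve:
    """ROC curve and trapezoidal AUC; equals the Mann-Whitney pair count
    with ties counted one half."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels)) < 2:
        raise ParameterError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class AverageROC:
    grid: np.ndarray
    mean_se: np.ndarray
    sd_se: np.ndarray


def average_roc(curves: Sequence[ROCCurve], n_grid: int = 101) -> AverageROC:
    """Vertical (fixed false-positive-rate) averaging onto a uniform grid."""
    if not curves:
        raise ParameterError("need at least one ROC curve")
    grid = np.linspace(0.0, 1.0, n_grid)
    interp = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    sd = interp.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_grid)
    return AverageROC(grid=grid, mean_se=interp.mean(axis=0), sd_se=sd)


# ---------------------------------------------------------------------------
# Repeated leak-free evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationSummary:
    spec: ClassifierSpec
    feature_names: tuple[str, ...]
    n_reps: int
    test_metrics: pd.DataFrame  # one row per repetition
    train_metrics: pd.DataFrame
    test_curves: list[ROCCurve]
    models: list[TrainedModel]
    skipped: dict[str, int] = field(default_factory=dict)

    def _agg(self, df: pd.DataFrame) -> dict[str, tuple[float, float]]:
        out = {}
        for m in METRIC_NAMES:
            col = df[m].dropna()
            mean = float(col.mean()) if len(col) else float("nan")
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            out[m] = (mean, sd)
        return out

    @property
    def test_summary(self) -> dict[str, tuple[float, float]]:
        return self._agg(self.test_metrics)

    @property
    def train_summary(self) -> dict[str, tuple[float, float]]:
        return self._agg(self.train_metrics)

    def table_row(self) -> dict[str, str]:
        return {
            "classifier": self.spec.display_name,
            **{
                m: f"{mean * (100 if m != 'AUC' else 1):.1f} +/- {sd * (100 if m != 'AUC' else 1):.1f}"
                if m != "AUC"
                else f"{mean:.2f} +/- {sd:.2f}"
                for m, (mean, sd) in self.test_summary.items()
            },
        }


def _metrics_with_auc(y, pred, scores) -> dict[str, float]:
    m = confusion_metrics(y, pred).as_dict()
    try:
        m["AUC"] = roc_auc(y, scores).auc
    except ParameterError:
        m["AUC"] = float("nan")
    return m


def repeated_evaluation(
    table: FeatureTable,
    feature_names: Sequence[str],
    spec: ClassifierSpec,
    plans: Sequence[PartitionPlan],
    base_seed: int = 0,
    audit: LeakAudit | None = None,
    k_neighbors: int = 5,
) -> EvaluationSummary:
    """Train on each persisted SMOTE-balanced training partition and
    evaluate on the untouched test partition (and the raw training one)."""
    table = table.canonical().select_features(feature_names)
    test_rows, train_rows, curves, models = [], [], [], []
    for plan in plans:
        tr = table.subset(plan.train_ids)
        te = table.subset(plan.test_ids)
        bal, syn = smote_oversample(
            tr, k_neighbors=k_neighbors, seed=child_seed(base_seed, plan.repetition_index, 7)
        )
        if audit is not None:
            audit.check(syn, allowed_ids=plan.train_ids, forbidden_ids=plan.test_ids)
        model = train_classifier(
            spec, bal, seed=child_seed(base_seed, plan.repetition_index, 11)
        )
        te_scores = model.likelihood(te.values)
        tr_scores = model.likelihood(tr.values)
        test_rows.append(_metrics_with_auc(te.y, model.predict(te.values), te_scores))
        train_rows.append(_metrics_with_auc(tr.y, model.predict(tr.values), tr_scores))
        try:
            curves.append(roc_auc(te.y, te_scores))
        except ParameterError:
            pass
        models.append(model)
    return EvaluationSummary(
        spec=spec,
        feature_names=tuple(feature_names),
        n_reps=len(plans),
        test_metrics=pd.DataFrame(test_rows),
        train_metrics=pd.DataFrame(train_rows),
        test_curves=curves,
        models=models,
    )


# ---------------------------------------------------------------------------
# Decision boundaries
# ---------------------------------------------------------------------------


@dataclass
class BoundaryArtifact:
    mode: str  # "threshold_1d" | "isoline_2d"
    threshold: float | None = None
    n_models: int = 0
    n_skipped: int = 0
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    likelihood: np.ndarray | None = None
    contours: list[np.ndarray] = field(default_factory=list)


def average_threshold_1d(
    models: Sequence[TrainedModel],
    lo: float,
    hi: float,
    n_scan: int = 256,
    tol: float = 1e-10,
) -> BoundaryArtifact:
    """Average single-feature decision threshold across trained models.

    Each model's threshold is located by bisection on (likelihood - 0.5);
    models whose score never crosses 0.5 inside [lo, hi] are skipped."""
    thresholds = []
    skipped = 0
    grid = np.linspace(lo, hi, n_scan)
    for model in models:
        g = model.likelihood(grid[:, None]) - 0.5
        sign = np.sign(g)
        idx = np.nonzero(sign[:-1] != sign[1:])[0]
        zeros = np.nonzero(g == 0.0)[0]
        if len(zeros) and (len(idx) == 0 or zeros[0] <= idx[0]):
            thresholds.append(grid[zeros[0]])
            continue
        if len(idx) == 0:
            skipped += 1
            continue
        a, b = grid[idx[0]], grid[idx[0] + 1]
        fa = g[idx[0]]
        while b - a > tol:
            mid = 0.5 * (a + b)
            fm = float(model.likelihood(np.array([[mid]]))[0] - 0.5)
            if np.sign(fm) == np.sign(fa):
                a, fa = mid, fm
            else:
                b = mid
        thresholds.append(0.5 * (a + b))
    if skipped:
        warnings.warn(f"{skipped} model(s) had no 0.5 crossing in range", stacklevel=2)
    return BoundaryArtifact(
        mode="threshold_1d",
        threshold=float(np.mean(thresholds)) if thresholds else float("nan"),
        n_models=len(thresholds),
        n_skipped=skipped,
    )


def average_boundary_2d(
    models: Sequence[TrainedModel],
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    n_grid: int = 200,
) -> BoundaryArtifact:
    """Mean premature-likelihood matrix on a grid + its 0.5-level isoline."""
    from skimage import measure

    gx = np.linspace(*x_range, n_grid)
    gy = np.linspace(*y_range, n_grid)
    XX, YY = np.meshgrid(gx, gy)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    acc = np.zeros(len(pts))
    for model in models:
        acc += model.likelihood(pts)
    mat = (acc / len(models)).reshape(n_grid, n_grid)
    contours = []
    for c in measure.find_contours(mat, 0.5):
        # contour coords are (row=y index, col=x index) -> feature units
        xs = np.interp(c[:, 1], np.arange(n_grid), gx)
        ys = np.interp(c[:, 0], np.arange(n_grid), gy)
        contours.append(np.column_stack([xs, ys]))
    return BoundaryArtifact(
        mode="isoline_2d",
        n_models=len(models),
        grid_x=gx,
        grid_y=gy,
        likelihood=mat,
        contours=contours,
    )


# ---------------------------------------------------------------------------
# Composite biomarker
# ---------------------------------------------------------------------------

#: weights of the linear composite biomarker y = sign(x^T w - b) on inputs
#: x = (PA_S3_B0Lp, MF_S2_B3); larger scores mean higher premature risk
BIOMARKER_WEIGHTS = (5.98, -4.02)
BIOMARKER_OFFSET = -12.78


def composite_biomarker(pa: float, mf: float) -> tuple[float, int]:
    """Linear discriminant score of (PA in the FWL band, MF in band B3).

    Returns ``(score, label)`` with label +1 (premature risk) when the score
    is positive and -1 (term) otherwise.
    """
    if not (np.isfinite(pa) and np.isfinite(mf)):
        raise ParameterError("biomarker inputs must be finite")
    w1, w2 = BIOMARKER_WEIGHTS
    score = w1 * pa + w2 * mf - BIOMARKER_OFFSET
    return float(score), (1 if score > 0 else -1)
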