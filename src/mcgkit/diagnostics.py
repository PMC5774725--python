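"""Group comparison and rule-out performance evaluation.

Implements the statistical arm of the analysis: one-way ANOVA group
comparison of the 10 predictors, elastic-net logistic regression of
patient vs control (glmnet parameterization: objective
(1/n) * deviance/2-free log-loss + lambda * [(1-alpha)/2 ||b||^2 +
alpha ||b||_1] on standardized predictors), ROC/AUC, confusion metrics at
a probability cut-off, prevalence-adjusted negative predictive value via
Bayes' theorem, and repeated stratified k-fold cross-validation with
apparent-performance comparison.

Model definitions (shared patient group A):
    model 1: A vs (B + C)    model 2: A vs B    model 3: A vs C
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .cohort import PREDICTORS

MODEL_CONTROLS = {1: ("B", "C"), 2: ("B",), 3: ("C",)}


def make_binary_response(table: pd.DataFrame, model_id: int = 1) -> pd.DataFrame:
    """Subset a cohort table to one model's groups and add ``is_patient``.

    The positive class is always the patient group A; controls are B + C,
    B only, or C only for models 1, 2 and 3.
    """
    if model_id not in MODEL_CONTROLS:
        raise ValueError(f"model_id must be one of {sorted(MODEL_CONTROLS)}")
    controls = MODEL_CONTROLS[model_id]
    sub = table[table["group"].isin(("A",) + controls)].copy()
    sub["is_patient"] = (sub["group"] == "A").astype(int)
    return sub


# ---------------------------------------------------------------------------
# group comparison (ANOVA + protected pairwise tests)

def compare_groups(
    table: pd.DataFrame, predictors: tuple[str, ...] = PREDICTORS, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-predictor group means +/- SD with ANOVA and pairwise flags.

    One-way ANOVA across the groups present in the table, then pairwise
    Welch t-tests for every group pair.  Pairwise significance flags are
    Fisher-protected: a pair is marked ('*' at p<0.05, '**' at p<0.01)
    only when the omnibus F is itself significant at ``alpha``, keeping
    the per-predictor false-flag rate near the nominal level under the
    null.
    """
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for pred in predictors:
        samples = [table.loc[table["group"] == g, pred].to_numpy() for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs at least two subjects")
        if all(np.var(s) == 0 for s in samples):
            raise ValueError(f"zero within-group variance for {pred}")
        f_stat, p_val = stats.f_oneway(*samples)
        row: dict[str, object] = {"predictor": pred, "F": float(f_stat), "p": float(p_val)}
        for g, s in zip(groups, samples):
            row[f"mean_{g}"] = float(np.mean(s))
            row[f"sd_{g}"] = float(np.std(s, ddof=1))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                _, p_pair = stats.ttest_ind(samples[i], samples[j], equal_var=False)
                key = f"{groups[i]}_vs_{groups[j]}"
                row[f"p_{key}"] = float(p_pair)
                flag = ""
                if p_val < alpha:  # protected LSD gate
                    if p_pair < 0.01:
                        flag = "**"
                    elif p_pair < 0.05:
                        flag = "*"
                row[f"sig_{key}"] = flag
        rows.append(row)
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# elastic-net logistic regression (glmnet parameterization)

@dataclass
class LogitModel:
    """Fitted penalized logistic model with its standardization state.

    Coefficients are on the standardized-predictor scale; ``predict_risk``
    applies the stored means/SDs, so raw feature tables can be scored
    directly.
    """

    intercept: float
    coef: np.ndarray
    alpha: float
    lam: float
    feature_names: tuple[str, ...]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    lambda_path: np.ndarray | None = field(default=None, repr=False)
    cv_deviance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.coef.size:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model ({self.coef.size})"
            )
        z = (x - self.standardize_mean) / self.standardize_sd
        return self.intercept + z @ self.coef


def _design(table_or_array, feature_names: tuple[str, ...]) -> np.ndarray:
    if isinstance(table_or_array, pd.DataFrame):
        return table_or_array.loc[:, list(feature_names)].to_numpy(dtype=float)
    return np.asarray(table_or_array, dtype=float)


def _lambda_path(
    z: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 40, ratio: float = 1e-3
) -> np.ndarray:
    """Geometric lambda path from the smallest all-zero lambda downward."""
    n = y.size
    p_bar = y.mean()
    score = np.abs(z.T @ (y - p_bar)) / n
    lam_max = score.max() / max(alpha, 1e-3)
    return lam_max * np.power(ratio, np.linspace(0.0, 1.0, n_lambda))


def _fit_at_lambda(
    z: np.ndarray, y: np.ndarray, alpha: float, lam: float, seed: int | None
) -> tuple[float, np.ndarray]:
    """Solve the glmnet objective at one lambda via saga (C = 1/(n*lam))."""
    n = y.size
    if alpha > 0 and lam > 0:
        # beyond the entry point of the L1 path the solution is exactly the
        # null model; saga converges poorly there, so return it analytically
        p_bar = y.mean()
        lam_entry = np.max(np.abs(z.T @ (y - p_bar))) / (n * alpha)
        if lam >= lam_entry:
            return float(np.log(p_bar / (1 - p_bar))), np.zeros(z.shape[1])
    if lam == 0.0:
        clf = LogisticRegression(solver="lbfgs", C=np.inf, max_iter=5000, tol=1e-10)
    else:
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (n * lam),
            max_iter=200_000,
            tol=1e-10,
            random_state=seed,
        )
    clf.fit(z, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def fit_penalized_logit(
    table: pd.DataFrame,
    alpha: float = 0.3,
    lambda_rule: str | float = "auto",
    seed: int | None = 0,
    feature_names: tuple[str, ...] = PREDICTORS,
    response: str = "is_patient",
    cv_folds: int = 10,
    n_lambda: int = 40,
) -> LogitModel:
    """Fit the elastic-net logistic model of patient vs control.

    Predictors are standardized internally (the stored means/SDs travel
    with the model).  ``lambda_rule='auto'`` picks the deviance-minimizing
    lambda by stratified ``cv_folds``-fold cross-validation over a
    geometric lambda path; a float fixes lambda directly.  ``alpha`` is
    the L1 mixing weight of the penalty (0 = ridge, 1 = lasso).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    y = table[response].to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else None
    if y is None:
        raise TypeError("fit_penalized_logit expects a DataFrame with a response column")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("response must contain both classes (0 and 1)")
    x = _design(table, feature_names)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd

    lambda_path = None
    cv_dev = None
    if isinstance(lambda_rule, str):
        if lambda_rule != "auto":
            raise ValueError("lambda_rule must be 'auto' or a number")
        lambda_path = _lambda_path(z, y, alpha, n_lambda=n_lambda)
        min_class = int(min(np.sum(y == 0), np.sum(y == 1)))
        folds = min(cv_folds, min_class)
        if folds < 2:
            raise ValueError("too few subjects per class for internal lambda selection")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        dev = np.zeros(lambda_path.size)
        for tr, te in splitter.split(z, y):
            for k, lam_k in enumerate(lambda_path):
                b0, b = _fit_at_lambda(z[tr], y[tr], alpha, lam_k, seed)
                eta = b0 + z[te] @ b
                p = 1.0 / (1.0 + np.exp(-eta))
                p = np.clip(p, 1e-12, 1 - 1e-12)
                dev[k] += -2.0 * np.sum(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        cv_dev = dev / y.size
        lam = float(lambda_path[int(np.argmin(cv_dev))])
    else:
        lam = float(lambda_rule)
        if lam < 0:
            raise ValueError("lambda must be >= 0")

    intercept, coef = _fit_at_lambda(z, y, alpha, lam, seed)
    return LogitModel(
        intercept=intercept,
        coef=coef,
        alpha=alpha,
        lam=lam,
        feature_names=tuple(feature_names),
        standardize_mean=mu,
        standardize_sd=sd,
        lambda_path=lambda_path,
        cv_deviance=cv_dev,
    )


def predict_risk(model: LogitModel, features) -> np.ndarray:
    """Predicted patient probability, strictly inside (0, 1)."""
    eta = model.linear_predictor(_design(features, model.feature_names))
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# ROC / confusion / cut-off / NPV

@dataclass(frozen=True)
class RocCurve:
    """ROC operating points; thresholds descend as in sklearn."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC (Mann-Whitney identity, ties counted 1/2)."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(labels, probabilities)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(labels, probabilities)))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts; positives are patients classified at probability >= cut-off."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_at_cutoff(
    probabilities: np.ndarray, labels: np.ndarray, cutoff: float
) -> ConfusionCounts:
    """Confusion counts classifying positive at probability >= ``cutoff``."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be inside (0, 1)")
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(probabilities, dtype=float) >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def select_cutoff(
    probabilities: np.ndarray, labels: np.ndarray, min_sensitivity: float = 0.90
) -> float:
    """Largest cut-off whose sensitivity exceeds ``min_sensitivity``.

    Maximizes specificity subject to the sensitivity floor: candidate
    cut-offs are the observed score values, scanned from the top; the
    highest one at which the sensitivity strictly exceeds the floor is
    returned.  If even classifying everyone positive cannot exceed the
    floor, raises ValueError reporting the attainable maximum.  With all
    scores identical the single candidate is returned (sensitivity 100 %).
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(probabilities, dtype=float)
    if not labels.any():
        raise ValueError("no positive cases; sensitivity undefined")
    pos = scores[labels]
    best = None
    for c in np.unique(scores)[::-1]:
        sens = np.mean(pos >= c)
        if sens > min_sensitivity:
            best = float(c)
            break
    if best is None:
        raise ValueError(
            f"no cut-off attains sensitivity > {min_sensitivity:.2f}; "
            f"maximum attainable is {np.mean(pos >= scores.min()):.3f}"
        )
    return best


def npv_from_prevalence(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Prevalence-adjusted negative predictive value (Bayes' theorem).

    NPV = spec * (1 - prev) / [ (1 - sens) * prev + spec * (1 - prev) ].
    All inputs are proportions in [0, 1].
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = (1.0 - sensitivity) * prevalence + specificity * (1.0 - prevalence)
    if denom == 0.0:
        raise ValueError("NPV undefined: no subject tests negative under these parameters")
    return specificity * (1.0 - prevalence) / denom


# ---------------------------------------------------------------------------
# repeated stratified cross-validation

@dataclass(frozen=True)
class CvSpec:
    """Repeated stratified k-fold specification."""

    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class PerformanceReport:
    """One row of a model-performance table (percent scale).

    ``npv_pct`` is recomputed from the (averaged) sensitivity/specificity
    via the prevalence-adjusted Bayes formula, not averaged per fold.
    """

    auc: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    npv_pct: float
    prevalence: float
    cross_validated: bool
    model_id: int | None = None
    n: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "model_id": self.model_id,
            "cross_validated": self.cross_validated,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "npv_pct": self.npv_pct,
            "prevalence": self.prevalence,
            "n": self.n,
        }


def _npv_or_nan(sens: float, spec: float, prev: float) -> float:
    """NPV, or NaN at a degenerate operating point where nobody tests negative."""
    try:
        return npv_from_prevalence(sens, spec, prev)
    except ValueError:
        return float("nan")


def _evaluate_at_cutoff(probs, y, cutoff):
    cm = confusion_at_cutoff(probs, y, cutoff)
    return cm.sensitivity, cm.specificity


def repeated_stratified_cv(
    table: pd.DataFrame,
    cv: CvSpec = CvSpec(),
    alpha: float = 0.3,
    cutoff: float | None = 0.2,
    min_sensitivity: float = 0.90,
    prevalence: float = 0.15,
    lambda_rule: str | float = "auto",
    lambda_select: str = "once",
    model_id: int | None = None,
    feature_names: tuple[str, ...] = PREDICTORS,
) -> tuple[PerformanceReport, PerformanceReport]:
    """Cross-validated and apparent rule-out performance of one model.

    Per repeat, a stratified k-fold split (class ratio preserved within
    one subject per fold) trains the elastic-net model on k-1 folds and
    scores the held-out fold; sensitivity, specificity and AUC are
    averaged over all folds x repeats and the NPV is recomputed from the
    averaged sensitivity/specificity.  The apparent report refits on the
    full table and scores the same subjects.

    ``cutoff=None`` selects the cut-off on each training portion by the
    sensitivity-floor rule; a float uses that fixed a-priori cut-off.
    ``lambda_select='once'`` tunes lambda a single time on the full table
    and reuses it in every fold (fast); ``'per-fold'`` re-tunes within
    each training portion.
    """
    if "is_patient" not in table.columns:
        raise ValueError("table must carry an 'is_patient' response (see make_binary_response)")
    y = table["is_patient"].to_numpy(dtype=int)
    n_minority = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_minority < cv.folds:
        raise ValueError(
            f"minority class ({n_minority}) too small for {cv.folds}-fold stratification"
        )
    if lambda_select not in ("once", "per-fold"):
        raise ValueError("lambda_select must be 'once' or 'per-fold'")

    full_model = fit_penalized_logit(
        table, alpha=alpha, lambda_rule=lambda_rule, seed=cv.seed, feature_names=feature_names
    )
    fold_lambda_rule = full_model.lam if lambda_select == "once" else lambda_rule

    if not cv.stratified:
        raise NotImplementedError("only stratified splitting is supported")
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    senss, specs, aucs = [], [], []
    x_all = table.reset_index(drop=True)
    for tr_idx, te_idx in splitter.split(np.zeros(len(y)), y):
        train = x_all.iloc[tr_idx]
        test = x_all.iloc[te_idx]
        m = fit_penalized_logit(
            train, alpha=alpha, lambda_rule=fold_lambda_rule, seed=cv.seed,
            feature_names=feature_names,
        )
        p_te = predict_risk(m, test)
        y_te = test["is_patient"].to_numpy(dtype=int)
        if cutoff is None:
            p_tr = predict_risk(m, train)
            c = select_cutoff(p_tr, train["is_patient"].to_numpy(), min_sensitivity)
        else:
            c = cutoff
        sens, spec = _evaluate_at_cutoff(p_te, y_te, c)
        senss.append(sens)
        specs.append(spec)
        if np.unique(y_te).size == 2:
            aucs.append(roc_auc(p_te, y_te).auc)
    mean_sens = float(np.mean(senss))
    mean_spec = float(np.mean(specs))
    cv_report = PerformanceReport(
        auc=float(np.mean(aucs)),
        cutoff=float(cutoff) if cutoff is not None else float("nan"),
        sensitivity_pct=100.0 * mean_sens,
        specificity_pct=100.0 * mean_spec,
        npv_pct=100.0 * _npv_or_nan(mean_sens, mean_spec, prevalence),
        prevalence=prevalence,
        cross_validated=True,
        model_id=model_id,
        n=len(y),
    )

    p_full = predict_risk(full_model, x_all)
    if cutoff is None:
        c_full = select_cutoff(p_full, y, min_sensitivity)
    else:
        c_full = cutoff
    app_sens, app_spec = _evaluate_at_cutoff(p_full, y, c_full)
    apparent = PerformanceReport(
        auc=roc_auc(p_full, y).auc,
        cutoff=float(c_full),
        sensitivity_pct=100.0 * app_sens,
        specificity_pct=100.0 * app_spec,
        npv_pct=100.0 * _npv_or_nan(app_sens, app_spec, prevalence),
        prevalence=prevalence,
        cross_validated=False,
        model_id=model_id,
        n=len(y),
    )
    return cv_report, apparent
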