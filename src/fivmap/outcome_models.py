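"""Outcome model battery: binary and ordinal logistic regression on infarct volumes.

The battery relates follow-up infarct volume (FIV) — total and split into
high/moderate/low mRS-relevance classes — to 90-day functional outcome:

* binary logistic regression for favorable outcome (mRS <= 2), and
* proportional-odds ordinal logistic regression for the full mRS shift.

Every volume coefficient is reported in the favorable direction: positive
beta means larger volume increases the odds of a better outcome, and the
odds ratio is presented per 10 mL (``or_per_10mL = exp(10 * beta_per_mL)``),
with Wald 95% confidence intervals. Model quality is scored by AIC and by
the c-statistic: ROC AUC for the binary outcome, and for the ordinal outcome
the weighted average of the K-1 cumulative-dichotomy AUCs with weights
n_below x n_above, which is identical to all-pairs concordance over pairs
with different outcome levels. Correlated binary-model AUCs are compared
with DeLong's test; ordinal c-statistics with a paired bootstrap, since
DeLong is defined for binary labels only.

The standard roster comprises ten models: binary univariable on total /
high / moderate / low FIV (1-4) and multivariable on the three class
volumes (5), then the same five specifications as proportional-odds models
(6-10); each exists unadjusted and adjusted for the fixed covariate set
(age, sex, diabetes, atrial fibrillation, prior stroke or pre-stroke
disability, treatment allocation, occlusion site, onset-to-treatment time,
collateral score).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ModelSpec",
    "FitResult",
    "PredictorEstimate",
    "ConvergenceError",
    "MODEL_ROSTER",
    "ADJUSTMENT_COVARIATES",
    "VOLUME_PREDICTORS",
    "fit_logistic",
    "fit_ordinal",
    "fit_model",
    "fit_roster",
    "c_statistic_binary",
    "c_statistic_ordinal",
    "delong_compare",
    "bootstrap_compare_ordinal",
    "aic",
    "favorable",
]

VOLUME_PREDICTORS = ("fiv_total", "fiv_high", "fiv_mod", "fiv_low")

#: fixed adjustment set; occlusion_site expands to dummies with M1 (the most
#: common site) as reference.
ADJUSTMENT_COVARIATES = (
    "age",
    "sex",
    "diabetes",
    "atrial_fibrillation",
    "prior_stroke_or_prestroke_mrs_gt0",
    "treatment_allocation",
    "occlusion_site",
    "onset_to_treatment_min",
    "collateral_score",
)


class ConvergenceError(RuntimeError):
    """Fit failed to converge (e.g. complete separation)."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one model in the battery."""

    outcome: str  # 'favorable_binary' | 'mrs_ordinal'
    predictors: tuple[str, ...]
    adjusted: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("favorable_binary", "mrs_ordinal"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        unknown = set(self.predictors) - set(VOLUME_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")
        if "fiv_total" in self.predictors and len(self.predictors) > 1:
            raise ValueError(
                "fiv_total is the sum of its sub-volumes; combining them in one "
                "model is collinear by construction"
            )


#: Ten-model standard roster.
MODEL_ROSTER: tuple[ModelSpec, ...] = tuple(
    ModelSpec(outcome=outc, predictors=preds, name=f"model_{i}")
    for i, (outc, preds) in enumerate(
        [
            ("favorable_binary", ("fiv_total",)),
            ("favorable_binary", ("fiv_high",)),
            ("favorable_binary", ("fiv_mod",)),
            ("favorable_binary", ("fiv_low",)),
            ("favorable_binary", ("fiv_high", "fiv_mod", "fiv_low")),
            ("mrs_ordinal", ("fiv_total",)),
            ("mrs_ordinal", ("fiv_high",)),
            ("mrs_ordinal", ("fiv_mod",)),
            ("mrs_ordinal", ("fiv_low",)),
            ("mrs_ordinal", ("fiv_high", "fiv_mod", "fiv_low")),
        ],
        start=1,
    )
)


@dataclass(frozen=True)
class PredictorEstimate:
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p_value: float
    or_per_10mL: float | None = None
    or_ci95_low: float | None = None
    or_ci95_high: float | None = None


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, PredictorEstimate]
    loglik: float
    aic: float
    c_statistic: float
    n_used: int
    n_excluded: int
    converged: bool
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def estimate(self, term: str) -> PredictorEstimate:
        return self.estimates[term]


def favorable(mrs: Sequence[int] | pd.Series) -> np.ndarray:
    """Favorable functional outcome indicator: mRS <= 2 at 90 days."""
    return (np.asarray(mrs) <= 2).astype(int)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik (k estimated parameters)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 2.0 * k - 2.0 * loglik


def _covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand the fixed adjustment set into numeric columns."""
    out = pd.DataFrame(index=cohort.index)
    out["age"] = pd.to_numeric(cohort["age"])
    out["sex"] = pd.to_numeric(cohort["sex"])
    out["diabetes"] = pd.to_numeric(cohort["diabetes"])
    out["atrial_fibrillation"] = pd.to_numeric(cohort["atrial_fibrillation"])
    out["prior_stroke_or_prestroke_mrs_gt0"] = pd.to_numeric(
        cohort["prior_stroke_or_prestroke_mrs_gt0"]
    )
    ta = cohort["treatment_allocation"]
    out["evt"] = (ta == "EVT").astype(int) if ta.dtype == object else pd.to_numeric(ta)
    site = cohort["occlusion_site"].astype(str)
    out["occlusion_ICA_T"] = (site == "ICA-T").astype(int)
    out["occlusion_M2"] = (site == "M2").astype(int)
    out["onset_to_treatment_min"] = pd.to_numeric(cohort["onset_to_treatment_min"])
    out["collateral_score"] = pd.to_numeric(cohort["collateral_score"])
    return out


def _design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, int]:
    cols = list(spec.predictors)
    X = cohort[cols].apply(pd.to_numeric).copy()
    if spec.adjusted:
        X = pd.concat([X, _covariate_frame(cohort)], axis=1)
    y = pd.to_numeric(cohort["mrs_90d"])
    keep = X.notna().all(axis=1) & y.notna()
    n_excluded = int((~keep).sum())
    return X.loc[keep], y.loc[keep].astype(int), n_excluded


def _volume_estimates(names, params, bse, pvals) -> dict[str, PredictorEstimate]:
    zcrit = stats.norm.ppf(0.975)
    out = {}
    np_err = np.seterr(over="ignore")  # extreme CIs may overflow to inf on the OR scale
    for name, b, se, p in zip(names, params, bse, pvals):
        lo, hi = b - zcrit * se, b + zcrit * se
        est = PredictorEstimate(
            beta=float(b),
            se=float(se),
            ci95_low=float(lo),
            ci95_high=float(hi),
            p_value=float(p),
        )
        if name in VOLUME_PREDICTORS:
            est = PredictorEstimate(
                beta=float(b),
                se=float(se),
                ci95_low=float(lo),
                ci95_high=float(hi),
                p_value=float(p),
                or_per_10mL=float(np.exp(10.0 * b)),
                or_ci95_low=float(np.exp(10.0 * lo)),
                or_ci95_high=float(np.exp(10.0 * hi)),
            )
        out[name] = est
    np.seterr(**np_err)
    return out


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood binary logistic fit for favorable outcome (mRS <= 2).

    Complete-case analysis; excluded rows are counted in ``n_excluded``.
    Raises :class:`ConvergenceError` on separation/non-convergence and
    ``ValueError`` when the outcome has a single class or < 20 complete cases.
    """
    if spec.outcome != "favorable_binary":
        raise ValueError("fit_logistic requires a favorable_binary spec")
    X, mrs, n_excluded = _design(cohort, spec)
    if len(X) < 20:
        raise ValueError(f"need >= 20 complete cases, got {len(X)}")
    y = favorable(mrs)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, Xc)
            fit = model.fit(disp=0, maxiter=100, method="newton", tol=1e-10)
            if not fit.mle_retvals.get("converged", True):
                fit = model.fit(disp=0, maxiter=500, method="bfgs", gtol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(
            "logistic fit failed (possible complete separation); consider fewer "
            f"predictors or more data: {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
        raise ConvergenceError("logistic fit did not converge (separation likely)")
    names = list(Xc.columns)
    estimates = _volume_estimates(names, fit.params, fit.bse, fit.pvalues)
    scores = np.asarray(fit.predict(Xc))
    k = len(names)
    return FitResult(
        spec=spec,
        estimates=estimates,
        loglik=float(fit.llf),
        aic=aic(float(fit.llf), k),
        c_statistic=c_statistic_binary(scores, y),
        n_used=len(X),
        n_excluded=n_excluded,
        converged=True,
        scores=scores,
        labels=np.asarray(y),
    )


def fit_ordinal(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Proportional-odds ordinal logistic fit of the full mRS distribution.

    The latent model is logit P(mRS <= k) = alpha_k + x beta with shared
    slopes across cut-points; beta is reported in the favorable direction
    (positive = shift towards better outcome), matching the binary fit's
    orientation. The c-statistic uses the linear predictor against the
    ordinal labels via cumulative dichotomies.
    """
    if spec.outcome != "mrs_ordinal":
        raise ValueError("fit_ordinal requires an mrs_ordinal spec")
    X, mrs, n_excluded = _design(cohort, spec)
    levels = np.unique(mrs)
    if len(levels) < 2:
        raise ValueError("mRS outcome has fewer than 2 observed levels")
    endog = pd.Categorical(mrs, categories=sorted(levels), ordered=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(endog, X, distr="logit")
            fit = model.fit(method="bfgs", disp=0, maxiter=500, gtol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"ordinal fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise ConvergenceError("ordinal fit did not converge (non-finite standard errors)")
    k_exog = X.shape[1]
    # statsmodels parameterises P(y<=k) = F(threshold_k - x b); negate b so
    # positive beta means better outcome, as in the binary model.
    beta = -np.asarray(fit.params[:k_exog])
    bse = np.asarray(fit.bse[:k_exog])
    pvals = np.asarray(fit.pvalues[:k_exog])
    estimates = _volume_estimates(list(X.columns), beta, bse, pvals)
    # Higher linear predictor = higher predicted mRS (worse outcome).
    scores = np.asarray(X @ np.asarray(fit.params[:k_exog]))
    k = len(fit.params)
    return FitResult(
        spec=spec,
        estimates=estimates,
        loglik=float(fit.llf),
        aic=aic(float(fit.llf), k),
        c_statistic=c_statistic_ordinal(scores, mrs.to_numpy()),
        n_used=len(X),
        n_excluded=n_excluded,
        converged=True,
        scores=scores,
        labels=mrs.to_numpy(),
    )


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    if spec.outcome == "favorable_binary":
        return fit_logistic(cohort, spec)
    return fit_ordinal(cohort, spec)


def fit_roster(
    cohort: pd.DataFrame, adjusted: str = "both", roster: Sequence[ModelSpec] = MODEL_ROSTER
) -> dict[str, FitResult]:
    """Fit the ten-model roster; ``adjusted`` in {'no', 'yes', 'both'}.

    Adjusted variants are separate one-model-per-row fits appending the full
    covariate set, keyed ``<name>_adjusted``.
    """
    if adjusted not in ("no", "yes", "both"):
        raise ValueError("adjusted must be 'no', 'yes' or 'both'")
    out: dict[str, FitResult] = {}
    for spec in roster:
        if adjusted in ("no", "both"):
            out[spec.name] = fit_model(cohort, spec)
        if adjusted in ("yes", "both"):
            adj = ModelSpec(spec.outcome, spec.predictors, adjusted=True, name=spec.name)
            out[f"{spec.name}_adjusted"] = fit_model(cohort, adj)
    return out


def c_statistic_binary(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney rank-sum estimator with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("c-statistic undefined: both outcome classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def c_statistic_ordinal(scores, ordinal_labels) -> float:
    """Concordance index for an ordinal outcome.

    The probability that of two randomly chosen subjects with different
    outcome levels, the one with the higher level also has the higher score
    (half credit for score ties): the natural generalisation of the binary
    AUC built from the dichotomy ROCs. Computed as the average of the
    level-pair AUCs weighted by the number of pairs n_k * n_l, which is
    algebraically identical to all-discordant-pairs concordance; at K = 2 it
    reduces exactly to :func:`c_statistic_binary`.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(ordinal_labels)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("c-statistic undefined for a single outcome level")
    num = 0.0
    den = 0.0
    for i, lo in enumerate(levels[:-1]):
        for hi in levels[i + 1 :]:
            sel = (y == lo) | (y == hi)
            w = float((y == lo).sum() * (y == hi).sum())
            num += w * c_statistic_binary(scores[sel], (y[sel] == hi).astype(int))
            den += w
    return float(num / den)


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """DeLong structural components via mid-rank placements."""
    m, n = len(pos_scores), len(neg_scores)
    allsc = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(allsc)
    rank_pos_internal = stats.rankdata(pos_scores)
    rank_neg_internal = stats.rankdata(neg_scores)
    v10 = (ranks[:m] - rank_pos_internal) / n  # per-positive placement
    v01 = 1.0 - (ranks[m:] - rank_neg_internal) / m  # per-negative placement
    auc = v10.mean()
    return auc, v10, v01


def delong_compare(scores_a, scores_b, labels) -> dict:
    """DeLong's test for two correlated ROC AUCs on the same subjects.

    Returns ``{'auc_a', 'auc_b', 'z', 'p', 'var_diff', 'degenerate'}``; a
    zero-variance difference (e.g. identical score vectors) yields z = 0,
    p = 1 with the degenerate flag set.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must have equal length")
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValueError("both outcome classes must be present")
    m, n = int(pos.sum()), int((~pos).sum())
    auc_a, v10_a, v01_a = _placements(scores_a[pos], scores_a[~pos])
    auc_b, v10_b, v01_b = _placements(scores_b[pos], scores_b[~pos])
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0 or not math.isfinite(var_diff):
        return {
            "auc_a": float(auc_a),
            "auc_b": float(auc_b),
            "z": 0.0,
            "p": 1.0,
            "var_diff": max(float(var_diff), 0.0),
            "degenerate": True,
        }
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    return {
        "auc_a": float(auc_a),
        "auc_b": float(auc_b),
        "z": float(z),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "var_diff": float(var_diff),
        "degenerate": False,
    }


def bootstrap_compare_ordinal(
    scores_a, scores_b, ordinal_labels, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Paired-bootstrap comparison of two ordinal c-statistics on the same subjects."""
    rng = np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(ordinal_labels)
    n = len(y)
    c_a = c_statistic_ordinal(scores_a, y)
    c_b = c_statistic_ordinal(scores_b, y)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, n)
        diffs[b] = c_statistic_ordinal(scores_a[idx], y[idx]) - c_statistic_ordinal(
            scores_b[idx], y[idx]
        )
    se = diffs.std(ddof=1)
    if se == 0:
        return {"c_a": c_a, "c_b": c_b, "z": 0.0, "p": 1.0, "degenerate": True}
    z = (c_a - c_b) / se
    return {
        "c_a": float(c_a),
        "c_b": float(c_b),
        "z": float(z),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "degenerate": False,
    }
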