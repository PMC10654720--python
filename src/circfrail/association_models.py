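"""Outcome models linking baseline rest-activity metrics to frailty.

Three families of models are provided, each taking a tidy analysis table
with one row per subject (plus a long table of repeated scores):

* Cox proportional-hazards models of incident frailty with follow-up
  rounded to the nearest integer year (minimum 1) and Efron tie
  handling, one standardized rhythm metric at a time plus covariates;
* a Fine-Gray competing-risk variant treating death as a competing
  event, implemented as an IPCW-weighted partial likelihood (subjects
  who die remain in later risk sets, down-weighted by the censoring
  survival ratio G(t)/G(T_death));
* random-slope linear mixed models for the longitudinal composite
  frailty score (and grip/gait/BMI components), with metric × time as
  the effect of interest, and a cumulative-logit random-intercept model
  for the ordinal 0-2 fatigue score.

Continuous predictors are standardized to unit SD in the analysis
sample; a predictor coded ``direction="decrease"`` is negated after
z-scoring so that a hazard ratio above 1 reads "higher hazard per 1-SD
*decrease*", the convention used for protective metrics such as
amplitude, IS and M10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess1
import statsmodels.formula.api as smf

from .errors import ConfigurationError, DegenerateSignalError, ModelFitError

logger = logging.getLogger(__name__)

#: fully adjusted covariate set for the survival models
DEFAULT_COVARIATES = (
    "age", "female", "education", "sleep_duration", "sleep_fragmentation",
    "vascular_burden", "vascular_risk",
)


@dataclass
class ModelResult:
    """Fitted effect estimates with their uncertainty and provenance."""

    model_type: str
    terms: pd.DataFrame          # index: term; estimate, se, ci_low, ci_high, p
    n: int
    n_events: int
    metadata: dict = field(default_factory=dict)

    def hazard_ratios(self) -> pd.DataFrame:
        """Estimates exponentiated to the hazard-ratio scale."""
        out = self.terms.copy()
        for col in ("estimate", "ci_low", "ci_high"):
            out[col] = np.exp(out[col])
        return out.rename(columns={"estimate": "hr"})

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]


# ----------------------------------------------------------------------
# predictor preparation
# ----------------------------------------------------------------------

def standardize_predictor(
    values: pd.Series, direction: str = "increase"
) -> tuple[pd.Series, dict]:
    """Z-score a predictor; ``direction="decrease"`` negates the z-score.

    After negation a fitted HR > 1 means higher hazard per 1-SD decrease
    of the raw variable.  Applying "decrease" twice restores the original
    coding.
    """
    if direction not in ("increase", "decrease"):
        raise ConfigurationError(f"unknown direction '{direction}'")
    x = pd.to_numeric(values)
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateSignalError("cannot standardize a zero-SD predictor")
    z = (x - mu) / sd
    if direction == "decrease":
        z = -z
    return z, {"mean": mu, "sd": sd, "direction": direction}


def round_followup(times) -> np.ndarray:
    """Round follow-up to the nearest integer year (.5 rounds up), min 1.

    Grouping events into whole years is what makes ties deliberate; the
    one-year floor reflects that the cohort's minimum follow-up is one
    annual visit.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ConfigurationError("follow-up times must be positive")
    return np.maximum(np.floor(t + 0.5), 1.0)


# ----------------------------------------------------------------------
# Cox proportional hazards
# ----------------------------------------------------------------------

def fit_cox(
    table: pd.DataFrame,
    metric: str,
    covariates=DEFAULT_COVARIATES,
    direction: str = "increase",
    duration_col: str = "followup_years",
    event_col: str = "frailty_event",
    round_years: bool = True,
    min_events: int = 10,
) -> ModelResult:
    """Cox model of incident frailty for one standardized metric.

    Complete-case on the metric and covariates; Efron approximation for
    the year-grouped ties.  The fitted lifelines object is kept in
    ``metadata["fitter"]`` for survival-curve prediction.
    """
    covariates = [c for c in covariates if c in table.columns]
    cols = [metric, duration_col, event_col] + covariates
    df = table[cols].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < min_events:
        raise ModelFitError(f"only {n_events} events; need >= {min_events}")
    z, meta = standardize_predictor(df[metric], direction)
    df[metric] = z
    if round_years:
        df[duration_col] = round_followup(df[duration_col])
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:       # lifelines raises on non-convergence
        raise ModelFitError(f"Cox fit failed for {metric}: {exc}") from exc
    s = cph.summary
    terms = pd.DataFrame(
        {
            "estimate": s["coef"],
            "se": s["se(coef)"],
            "ci_low": s["coef lower 95%"],
            "ci_high": s["coef upper 95%"],
            "p": s["p"],
        }
    )
    return ModelResult(
        "cox", terms, n=len(df), n_events=n_events,
        metadata={"metric": metric, "standardization": meta, "fitter": cph,
                  "covariates": covariates},
    )


# ----------------------------------------------------------------------
# Fine-Gray competing risks
# ----------------------------------------------------------------------

def _censoring_survival(durations: np.ndarray, event: np.ndarray):
    """Left-continuous Kaplan-Meier of the censoring distribution."""
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=(event == 0))
    grid = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_minus(t: float) -> float:
        idx = np.searchsorted(grid, t, side="left") - 1
        return float(surv[idx]) if idx >= 0 else 1.0

    return g_minus


def fit_competing_risk(
    table: pd.DataFrame,
    metric: str,
    covariates=DEFAULT_COVARIATES,
    direction: str = "increase",
    duration_col: str = "followup_years",
    event_col: str = "event_type",
    round_years: bool = True,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> ModelResult:
    """Fine-Gray subdistribution-hazard model with death competing.

    ``event_col`` codes 0 = censored, 1 = frailty, 2 = death.  Subjects
    who die stay in the risk sets of later frailty events with weight
    G(t-)/G(T_i-), where G is the Kaplan-Meier censoring survival; the
    weighted partial likelihood (Breslow ties) is maximized by Newton
    iteration.  Reported SEs are model-based and ignore the uncertainty
    of the estimated weights.  Without any deaths the model reduces to
    the ordinary Cox fit (a warning is issued).
    """
    covariates = [c for c in covariates if c in table.columns]
    cols = [metric, duration_col, event_col] + covariates
    df = table[cols].dropna().copy()
    z, meta = standardize_predictor(df[metric], direction)
    df[metric] = z
    T = df[duration_col].to_numpy(dtype=float)
    if round_years:
        T = round_followup(T)
    ev = df[event_col].to_numpy(dtype=int)
    if not np.any(ev == 2):
        warnings.warn("no competing deaths present: Fine-Gray reduces to Cox")
    X = df[[metric] + covariates].to_numpy(dtype=float)
    n, p = X.shape
    n_events = int((ev == 1).sum())
    if n_events < 10:
        raise ModelFitError(f"only {n_events} frailty events; need >= 10")
    g_minus = _censoring_survival(T, ev)
    event_times = np.unique(T[ev == 1])
    # weight matrix: row per event time, column per subject
    W = np.zeros((event_times.size, n))
    event_rows = []
    for k, t in enumerate(event_times):
        at_risk = T >= t
        W[k, at_risk] = 1.0
        died_before = (ev == 2) & (T < t)
        if died_before.any():
            gt = g_minus(t)
            gi = np.array([g_minus(ti) for ti in T[died_before]])
            W[k, died_before] = gt / np.maximum(gi, 1e-12)
        event_rows.append(np.flatnonzero((T == t) & (ev == 1)))

    def loglik_grad_hess(beta):
        eta = X @ beta
        r = np.exp(np.clip(eta, -30, 30))
        ll, grad = 0.0, np.zeros(p)
        hess = np.zeros((p, p))
        for k in range(event_times.size):
            w = W[k]
            rw = w * r
            s0 = rw.sum()
            s1 = X.T @ rw
            s2 = (X * rw[:, None]).T @ X
            rows = event_rows[k]
            d = len(rows)
            ll += eta[rows].sum() - d * np.log(s0)
            grad += X[rows].sum(axis=0) - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        return ll, grad, hess

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(max_iter):
        ll, grad, hess = loglik_grad_hess(beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelFitError("singular information matrix") from exc
        step_size = 1.0
        while step_size > 1e-4:
            cand = beta - step_size * step
            ll_new = loglik_grad_hess(cand)[0]
            if ll_new >= ll:
                break
            step_size /= 2.0
        beta = beta - step_size * step
        if abs(ll - ll_old) < tol and np.linalg.norm(grad) < 1e-6:
            break
        ll_old = ll
    else:
        ll, grad, hess = loglik_grad_hess(beta)
        if np.linalg.norm(grad) > 1e-3:
            raise ModelFitError(
                f"Fine-Gray did not converge (|grad| = {np.linalg.norm(grad):.2e})"
            )
    _, _, hess = loglik_grad_hess(beta)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zval))
    names = [metric] + covariates
    terms = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - 1.959963984540054 * se,
            "ci_high": beta + 1.959963984540054 * se,
            "p": pvals,
        },
        index=names,
    )
    return ModelResult(
        "fine_gray", terms, n=n, n_events=n_events,
        metadata={"metric": metric, "standardization": meta,
                  "n_deaths": int((ev == 2).sum()), "covariates": covariates},
    )


# ----------------------------------------------------------------------
# linear mixed models
# ----------------------------------------------------------------------

def _mixedlm_result(fit, model_type: str, n_subjects: int, meta: dict
                    ) -> ModelResult:
    fe = fit.fe_params
    ci = fit.conf_int().loc[fe.index]
    terms = pd.DataFrame(
        {
            "estimate": fe,
            "se": fit.bse.loc[fe.index],
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues.loc[fe.index],
        }
    )
    meta = dict(meta)
    meta["fit"] = fit
    return ModelResult(model_type, terms, n=n_subjects,
                       n_events=int(fit.nobs), metadata=meta)


def fit_frailty_lmm(
    long_table: pd.DataFrame,
    metric: str,
    covariates=(),
    outcome: str = "composite_score",
    direction: str = "increase",
    subject_col: str = "subject_id",
    time_col: str = "time",
    covariate_time_interactions: bool = True,
) -> ModelResult:
    """Random-slope mixed model for a longitudinal frailty outcome.

    Fixed effects: time, the standardized metric, metric × time, plus
    each covariate and (optionally) its interaction with time.  Random
    effects: per-subject intercept and time slope with an unstructured
    2×2 covariance, fitted by REML.  If the random-effects covariance is
    singular the model is refitted with a random intercept only (flagged
    in metadata).
    """
    covariates = [c for c in covariates if c in long_table.columns]
    cols = [subject_col, time_col, outcome, metric] + covariates
    df = long_table[cols].dropna().copy()
    n_subj = df[subject_col].nunique()
    visits_per = df.groupby(subject_col).size()
    if (visits_per >= 2).mean() < 0.5:
        raise ModelFitError("fewer than half the subjects have >= 2 visits")
    if metric in df.columns:
        df["_metric"], meta = standardize_predictor(df[metric], direction)
    rhs = [time_col, "_metric", f"_metric:{time_col}"]
    for c in covariates:
        rhs.append(c)
        if covariate_time_interactions:
            rhs.append(f"{c}:{time_col}")
    formula = f"{outcome} ~ " + " + ".join(rhs)
    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[subject_col],
                            re_formula=f"~{time_col}")
        try:
            fit = model.fit(reml=True, method="lbfgs")
            cov_re = fit.cov_re.to_numpy()
            if not np.all(np.linalg.eigvalsh(cov_re) > 1e-12):
                degenerate = True
        except (np.linalg.LinAlgError, ValueError):
            degenerate = True
        if degenerate:
            logger.warning("singular random-effects covariance; "
                           "falling back to random intercept only")
            model = smf.mixedlm(formula, df, groups=df[subject_col])
            fit = model.fit(reml=True, method="lbfgs")
    result = _mixedlm_result(
        fit, "lmm", n_subj,
        {"metric": metric, "outcome": outcome, "standardization": meta,
         "formula": formula, "random_intercept_only": degenerate},
    )
    result.terms = result.terms.rename(
        index={"_metric": metric, f"_metric:{time_col}": f"{metric}:{time_col}"}
    )
    return result


# ----------------------------------------------------------------------
# cumulative-logit random-intercept model (ordinal fatigue)
# ----------------------------------------------------------------------

def fit_ordinal_mixed(
    long_table: pd.DataFrame,
    outcome: str,
    predictors,
    subject_col: str = "subject_id",
    n_quad: int = 25,
) -> ModelResult:
    """Proportional-odds model with a subject random intercept.

    P(Y ≤ k | u) = logistic(θ_k − xβ − u), u ~ N(0, σ²), fitted by
    maximum likelihood with Gauss-Hermite quadrature over the random
    intercept.  Outcome levels must be consecutive integers starting at
    0; every level must occur in the data.
    """
    predictors = list(predictors)
    df = long_table[[subject_col, outcome] + predictors].dropna().copy()
    y = df[outcome].to_numpy(dtype=int)
    levels = np.unique(y)
    n_levels = int(levels.max()) + 1
    if not np.array_equal(levels, np.arange(n_levels)) or n_levels < 3:
        raise ModelFitError(
            f"outcome levels observed {levels.tolist()}; need all of "
            f"0..{max(2, n_levels - 1)}"
        )
    X = df[predictors].to_numpy(dtype=float)
    subj, subj_idx = np.unique(df[subject_col].to_numpy(), return_inverse=True)
    n_subj = subj.size
    p = X.shape[1]
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(wts) - 0.5 * np.log(np.pi)
    n_thresh = n_levels - 1

    def unpack(theta):
        cuts = np.empty(n_thresh)
        cuts[0] = theta[0]
        cuts[1:] = theta[0] + np.cumsum(np.exp(theta[1:n_thresh]))
        beta = theta[n_thresh:n_thresh + p]
        sigma = np.exp(theta[-1])
        return cuts, beta, sigma

    def nll(theta):
        cuts, beta, sigma = unpack(theta)
        eta = X @ beta
        u = np.sqrt(2.0) * sigma * nodes                  # (Q,)
        lin = eta[:, None] + u[None, :]                   # (N, Q)
        upper = np.where(y[:, None] < n_thresh,
                         expit(cuts[np.minimum(y, n_thresh - 1)][:, None] - lin),
                         1.0)
        lower = np.where(y[:, None] > 0,
                         expit(cuts[np.maximum(y - 1, 0)][:, None] - lin),
                         0.0)
        probs = np.clip(upper - lower, 1e-12, 1.0)
        log_obs = np.log(probs)                           # (N, Q)
        per_subj = np.zeros((n_subj, n_quad))
        np.add.at(per_subj, subj_idx, log_obs)
        m = per_subj.max(axis=1, keepdims=True)
        lik = np.log(np.exp(per_subj - m + log_w[None, :]).sum(axis=1)) + m[:, 0]
        return -float(lik.sum())

    theta0 = np.concatenate([[-0.5, 0.0], np.zeros(p), [np.log(0.5)]])
    res = optimize.minimize(nll, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        raise ModelFitError(f"ordinal mixed model did not converge: {res.message}")
    theta = res.x
    hess = approx_hess1(theta, nll)
    try:
        cov_theta = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(hess)
    cuts, beta, sigma = unpack(theta)
    # delta method for the second threshold (θ1 = θ0 + exp(t1))
    names = [f"threshold_{k}" for k in range(n_thresh)] + predictors
    est = np.concatenate([cuts, beta])
    J = np.zeros((n_thresh + p, theta.size))
    J[0, 0] = 1.0
    for k in range(1, n_thresh):
        J[k, 0] = 1.0
        for m in range(1, k + 1):
            J[k, m] = np.exp(theta[m])
    for j in range(p):
        J[n_thresh + j, n_thresh + j] = 1.0
    cov = J @ cov_theta @ J.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    zval = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    terms = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "p": 2 * stats.norm.sf(np.abs(zval)),
        },
        index=names,
    )
    return ModelResult(
        "ordinal_mixed", terms, n=n_subj, n_events=len(df),
        metadata={"sigma_u": float(sigma), "loglik": -float(res.fun)},
    )


def fit_component_models(
    long_table: pd.DataFrame,
    metric: str,
    component: str,
    covariates=(),
    direction: str = "increase",
    subject_col: str = "subject_id",
    time_col: str = "time",
) -> ModelResult:
    """Longitudinal model for one frailty component.

    grip/gait/BMI reuse the random-slope linear mixed model; the ordinal
    fatigue score (0-2) uses the cumulative-logit random-intercept model
    with time, metric and metric × time as predictors.
    """
    outcome_cols = {"grip": "grip_strength", "gait": "gait_time",
                    "bmi": "bmi", "fatigue": "fatigue_score"}
    if component not in outcome_cols:
        raise ConfigurationError(
            f"component must be one of {sorted(outcome_cols)}"
        )
    outcome = outcome_cols[component]
    if component != "fatigue":
        return fit_frailty_lmm(
            long_table, metric, covariates, outcome=outcome,
            direction=direction, subject_col=subject_col, time_col=time_col,
        )
    df = long_table.copy()
    df["_metric"], meta = standardize_predictor(df[metric], direction)
    df["_metric_time"] = df["_metric"] * df[time_col]
    predictors = [time_col, "_metric", "_metric_time"] + [
        c for c in covariates if c in df.columns
    ]
    result = fit_ordinal_mixed(df, outcome, predictors, subject_col=subject_col)
    result.terms = result.terms.rename(
        index={"_metric": metric, "_metric_time": f"{metric}:{time_col}"}
    )
    result.metadata.update({"metric": metric, "standardization": meta})
    return result


# ----------------------------------------------------------------------
# sensitivity analyses and predictions
# ----------------------------------------------------------------------

def sensitivity_suite(
    table: pd.DataFrame,
    metric: str,
    covariates=DEFAULT_COVARIATES,
    direction: str = "increase",
    scenarios=("adjust_ad_pd", "low_activity", "age_lt_80", "age_ge_80"),
) -> dict[str, ModelResult]:
    """Re-fit the Cox model under the prespecified robustness scenarios.

    ``adjust_ad_pd`` adds baseline Alzheimer's/Parkinson's diagnoses as
    covariates; ``low_activity`` restricts to subjects at or below the
    median total daily activity; the age scenarios stratify at 80 years.
    Scenarios whose stratum is empty (or too small to fit) are skipped
    with a log entry.
    """
    out: dict[str, ModelResult] = {}
    for scen in scenarios:
        sub, covs = table, list(covariates)
        if scen == "adjust_ad_pd":
            covs = covs + [c for c in ("ad_diagnosis", "pd_diagnosis")
                           if c in table.columns]
        elif scen == "low_activity":
            med = table["total_activity"].median()
            sub = table[table["total_activity"] <= med]
        elif scen == "age_lt_80":
            sub = table[table["age"] < 80]
        elif scen == "age_ge_80":
            sub = table[table["age"] >= 80]
        else:
            raise ConfigurationError(f"unknown scenario '{scen}'")
        if len(sub) == 0:
            logger.warning("scenario %s: empty stratum, skipped", scen)
            continue
        try:
            res = fit_cox(sub, metric, covs, direction=direction)
        except ModelFitError as exc:
            logger.warning("scenario %s skipped: %s", scen, exc)
            continue
        res.metadata["scenario"] = scen
        out[scen] = res
    return out


def predicted_curves(
    result: ModelResult,
    table: pd.DataFrame,
    percentiles=(10, 90),
    time_grid=None,
) -> pd.DataFrame:
    """Predicted survival (Cox) or score trajectory (LMM) at metric percentiles.

    Produces one curve per requested percentile of the *raw* metric with
    all other covariates held at their analysis-sample means, as a tidy
    plot-ready frame (columns: percentile, time, value[, lo, hi]).
    """
    for q in percentiles:
        if not 0 < q < 100:
            raise ConfigurationError("percentiles must lie in (0, 100)")
    metric = result.metadata["metric"]
    std = result.metadata["standardization"]
    raw = pd.to_numeric(table[metric]).dropna()
    rows = []
    if result.model_type == "cox":
        cph: CoxPHFitter = result.metadata["fitter"]
        covs = result.metadata["covariates"]
        prof = {c: [float(pd.to_numeric(table[c]).mean())] * len(percentiles)
                for c in covs}
        zvals = []
        for q in percentiles:
            v = float(np.percentile(raw, q))
            z = (v - std["mean"]) / std["sd"]
            zvals.append(-z if std["direction"] == "decrease" else z)
        prof[metric] = zvals
        X = pd.DataFrame(prof)
        sf = cph.predict_survival_function(X)
        for j, q in enumerate(percentiles):
            for t, v in sf[j].items():
                rows.append({"percentile": q, "time": float(t),
                             "value": float(v)})
        return pd.DataFrame(rows)
    # mixed model trajectory with a delta-method CI band
    fit = result.metadata["fit"]
    fe = fit.fe_params
    cov_fe = fit.cov_params().loc[fe.index, fe.index].to_numpy()
    time_col = "time"
    if time_grid is None:
        time_grid = np.arange(0.0, 16.5, 1.0)
    for q in percentiles:
        v = float(np.percentile(raw, q))
        z = (v - std["mean"]) / std["sd"]
        if std["direction"] == "decrease":
            z = -z
        for t in time_grid:
            x = np.zeros(fe.size)
            for i, name in enumerate(fe.index):
                if name == "Intercept":
                    x[i] = 1.0
                elif name == time_col:
                    x[i] = t
                elif name == "_metric":
                    x[i] = z
                elif name == f"_metric:{time_col}":
                    x[i] = z * t
                elif name.endswith(f":{time_col}"):
                    base = name.split(":")[0]
                    x[i] = float(pd.to_numeric(table[base]).mean()) * t
                else:
                    x[i] = float(pd.to_numeric(table[name]).mean())
            mu = float(x @ fe.to_numpy())
            var = float(x @ cov_fe @ x)
            half = 1.959963984540054 * np.sqrt(max(var, 0.0))
            rows.append({"percentile": q, "time": float(t), "value": mu,
                         "lo": mu - half, "hi": mu + half})
    return pd.DataFrame(rows)


def metric_correlations(metrics: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix of the baseline rhythm metrics."""
    numeric = metrics.select_dtypes(include=[np.number]).dropna()
    rho, _ = stats.spearmanr(numeric.to_numpy())
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=numeric.columns, columns=numeric.columns)
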