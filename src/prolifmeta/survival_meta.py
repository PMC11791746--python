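"""Cox proportional-hazards estimation and heterogeneity-gated meta-analysis.

Per cohort, the association between a gene's expression (standardized to unit
SD within the cohort, so the hazard ratio is per-SD and comparable across
platforms) and relapse within a fixed horizon is estimated by Cox regression,
optionally adjusted for a proliferation score.  Per-cohort log hazard ratios
are pooled by inverse-variance weighting; between-cohort heterogeneity is
tested with Cochran's Q, and when the Q test is significant at p < 0.05 the
DerSimonian-Laird random-effects model is used instead of the fixed-effects
model.

The Cox fitter maximizes the partial likelihood with Efron handling of tied
event times by Newton iteration with step-halving; standard errors come from
the inverse observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CohortCollection

logger = logging.getLogger(__name__)

#: default analysis horizon: 5-year relapse-free survival.
DEFAULT_HORIZON_MONTHS = 60.0


class SurvivalError(ValueError):
    pass


class ConvergenceError(SurvivalError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """One per-cohort effect (log hazard ratio or Fisher-z correlation)."""

    cohort_id: str
    effect: float
    se: float
    n: int
    effect_type: str  # "fisher_z" or "log_hr"
    stratum: str = "all"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise SurvivalError(f"se must be > 0, got {self.se}")
        if self.effect_type not in ("fisher_z", "log_hr"):
            raise SurvivalError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_type == "fisher_z" and self.n < 4:
            raise SurvivalError("fisher_z estimates require n >= 4")


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity diagnostics.

    ``pooled_effect`` and the CI are on the effect scale (log HR or Fisher
    z); use :meth:`as_hazard_ratio` / :meth:`as_correlation` for reporting.
    """

    pooled_effect: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    Q: float
    df: int
    p_Q: float
    tau2: float
    model: str          # "fixed" or "random"
    k: int
    effect_type: str

    def as_hazard_ratio(self) -> tuple[float, float, float]:
        """(HR, ci_lo, ci_hi) on the hazard-ratio scale."""
        if self.effect_type != "log_hr":
            raise SurvivalError("not a log hazard-ratio meta-result")
        return tuple(float(np.exp(v)) for v in
                     (self.pooled_effect, self.ci_lo, self.ci_hi))

    def as_correlation(self) -> tuple[float, float, float]:
        """(r, ci_lo, ci_hi) back-transformed from Fisher z."""
        if self.effect_type != "fisher_z":
            raise SurvivalError("not a Fisher-z meta-result")
        return tuple(float(np.tanh(v)) for v in
                     (self.pooled_effect, self.ci_lo, self.ci_hi))


def restrict_followup(
    times, events, horizon_months: float = DEFAULT_HORIZON_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor observations beyond the horizon.

    Observations with time strictly beyond the horizon get
    ``time := horizon, event := 0``; others are unchanged.
    """
    t = np.asarray(times, dtype=float).copy()
    e = np.asarray(events, dtype=float).astype(int).copy()
    if (t < 0).any():
        raise SurvivalError("negative survival times")
    if horizon_months <= 0:
        raise SurvivalError("horizon must be > 0")
    beyond = t > horizon_months
    t[beyond] = horizon_months
    e[beyond] = 0
    return t, e


def _efron_ll_grad_info(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, score, and observed information."""
    eta = X @ beta
    # guard against overflow in degenerate steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        sR = w[risk].sum()
        xR = (w[risk, None] * X[risk]).sum(axis=0)
        xxR = (w[risk, None, None] * X[risk, :, None] * X[risk, None, :]).sum(axis=0)
        sD = w[dead].sum()
        xD = (w[dead, None] * X[dead]).sum(axis=0)
        xxD = (w[dead, None, None] * X[dead, :, None] * X[dead, None, :]).sum(axis=0)
        ll += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        for ell in range(d):
            f = ell / d
            denom = sR - f * sD
            num = xR - f * xD
            xbar = num / denom
            ll -= np.log(denom)
            grad -= xbar
            info += (xxR - f * xxD) / denom - np.outer(xbar, xbar)
    return ll, grad, info


def cox_fit(
    times,
    events,
    covariates,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Fit a Cox proportional-hazards model by Newton iteration.

    Parameters
    ----------
    times, events:
        Observed times and 0/1 event indicators.
    covariates:
        1-D array, Series, or n x p DataFrame/array.
    ties:
        "efron" (default) or "breslow" tie handling.

    Returns a DataFrame indexed by covariate with columns coef, se, z, p.
    Raises on zero events, constant covariates, non-convergence, or monotone
    likelihood (perfect separation).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float).astype(int)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = [covariates.name or "x"]
        X = covariates.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != t.size or t.size != e.size:
        raise SurvivalError("times, events and covariates must be aligned")
    if e.sum() < 1:
        raise SurvivalError("at least one event is required")
    if (X.std(axis=0) == 0).any():
        const = [names[i] for i in range(X.shape[1]) if X[:, i].std() == 0]
        raise SurvivalError(f"constant covariate(s): {const}")
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown tie handling {ties!r}")
    if ties == "breslow":
        ll_fn = _breslow_ll_grad_info
    else:
        ll_fn = _efron_ll_grad_info

    # center covariates for numerical stability; leaves coef unchanged
    mu = X.mean(axis=0)
    Xc = X - mu

    beta = np.zeros(X.shape[1])
    ll, grad, info = ll_fn(beta, t, e, Xc)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise SurvivalError(
                f"singular information matrix (collinear covariates?): {err}"
            ) from err
        new_beta = beta + step
        new_ll, new_grad, new_info = ll_fn(new_beta, t, e, Xc)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = ll_fn(new_beta, t, e, Xc)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        # a per-SD log HR beyond ~e^15 is never a finite MLE in practice:
        # the likelihood is monotone and the score only flattens out
        if np.max(np.abs(beta)) > 15:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation): "
                f"coefficient diverging, beta={beta}"
            )
    else:
        raise ConvergenceError(
            f"Newton iteration did not converge in {max_iter} steps "
            f"(max |score| = {np.max(np.abs(grad)):.3g})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise SurvivalError(f"singular information at the optimum: {err}") from err
    if (np.diag(cov) <= 0).any():
        raise SurvivalError(
            "non-positive-definite information at the optimum (flat or "
            "degenerate partial likelihood)"
        )
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"coef": beta, "se": se, "z": z, "p": p}, index=names)


def _breslow_ll_grad_info(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow tie handling: all tied events share the full risk-set denominator."""
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        sR = w[risk].sum()
        xR = (w[risk, None] * X[risk]).sum(axis=0)
        xxR = (w[risk, None, None] * X[risk, :, None] * X[risk, None, :]).sum(axis=0)
        xbar = xR / sR
        ll += eta[dead].sum() - d * np.log(sR)
        grad += X[dead].sum(axis=0) - d * xbar
        info += d * (xxR / sR - np.outer(xbar, xbar))
    return ll, grad, info


def per_dataset_gene_hr(
    collection: CohortCollection,
    gene: str,
    adjust_scores: dict[str, pd.Series] | None = None,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    standardize: bool = True,
    stratum: str = "all",
    ties: str = "efron",
) -> list[EffectEstimate]:
    """Per-cohort log hazard ratio of a gene, optionally score-adjusted.

    Per cohort: the gene is standardized to unit SD within the cohort (so the
    HR is per-SD), follow-up is restricted to the horizon, and a Cox model is
    fit with the gene alone or with the cohort's adjustment score as a second
    covariate.  Cohorts where the fit is impossible (no events, constant
    gene, separation) are skipped with a logged reason.
    """
    estimates: list[EffectEstimate] = []
    found_anywhere = False
    for cohort in collection:
        if gene not in cohort.genes:
            logger.info("cohort %s: gene %r absent; skipped", cohort.cohort_id, gene)
            continue
        found_anywhere = True
        t_all, e_all, mask = cohort.survival()
        if t_all.size == 0:
            logger.info("cohort %s: no survival data; skipped", cohort.cohort_id)
            continue
        x = cohort.gene_values(gene).to_numpy(dtype=float)[mask]
        if standardize:
            sd = x.std(ddof=1)
            if sd == 0:
                logger.info("cohort %s: gene %r constant; skipped",
                            cohort.cohort_id, gene)
                continue
            x = (x - x.mean()) / sd
        t, e = restrict_followup(t_all, e_all, horizon_months)
        cols = {gene: x}
        if adjust_scores is not None:
            score = adjust_scores.get(cohort.cohort_id)
            if score is None:
                logger.info("cohort %s: no adjustment score; skipped",
                            cohort.cohort_id)
                continue
            cols["adjustment"] = score.loc[cohort.samples[mask]].to_numpy(dtype=float)
        covs = pd.DataFrame(cols)
        try:
            fit = cox_fit(t, e, covs, ties=ties)
        except SurvivalError as err:
            logger.info("cohort %s: Cox fit failed (%s); skipped",
                        cohort.cohort_id, err)
            continue
        estimates.append(
            EffectEstimate(
                cohort_id=cohort.cohort_id,
                effect=float(fit.loc[gene, "coef"]),
                se=float(fit.loc[gene, "se"]),
                n=int(t.size),
                effect_type="log_hr",
                stratum=stratum,
            )
        )
    if not found_anywhere:
        raise SurvivalError(f"gene {gene!r} absent in every cohort")
    return estimates


def cochran_q(estimates: list[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic with its chi-square p-value."""
    k = len(estimates)
    if k < 2:
        raise SurvivalError("Cochran's Q requires at least 2 estimates")
    e = np.array([est.effect for est in estimates])
    w = np.array([1.0 / est.se**2 for est in estimates])
    pooled = (w * e).sum() / w.sum()
    Q = float((w * (e - pooled) ** 2).sum())
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df))
    return Q, df, p_Q


def meta_effect(estimates: list[EffectEstimate], model: str = "auto") -> MetaResult:
    """Inverse-variance meta-analysis with a heterogeneity-gated model choice.

    ``model="fixed"``: pooled = sum(w_i e_i)/sum(w_i), w_i = 1/se_i^2.
    ``model="random"``: DerSimonian-Laird
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` with weights
    ``1/(se_i^2 + tau2)``.  ``model="auto"`` (default) uses random effects iff
    the Q test has p < 0.05.  CI is pooled +/- 1.96 se; p is two-sided normal.
    """
    k = len(estimates)
    if k == 0:
        raise SurvivalError("meta-analysis requires at least one estimate")
    types = {est.effect_type for est in estimates}
    if len(types) > 1:
        raise SurvivalError(f"mixed effect types: {sorted(types)}")
    effect_type = types.pop()
    if model not in ("auto", "fixed", "random"):
        raise SurvivalError(f"unknown model {model!r}")

    e = np.array([est.effect for est in estimates])
    se = np.array([est.se for est in estimates])
    w = 1.0 / se**2

    if k == 1:
        Q, df, p_Q = 0.0, 0, 1.0
    else:
        Q, df, p_Q = cochran_q(estimates)

    chosen = model
    if model == "auto":
        chosen = "random" if p_Q < 0.05 else "fixed"

    tau2 = 0.0
    if chosen == "random" and k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    weights = 1.0 / (se**2 + tau2)
    pooled = float((weights * e).sum() / weights.sum())
    pooled_se = float(1.0 / np.sqrt(weights.sum()))
    ci_lo = pooled - 1.96 * pooled_se
    ci_hi = pooled + 1.96 * pooled_se
    p = float(2.0 * stats.norm.sf(abs(pooled) / pooled_se))
    return MetaResult(
        pooled_effect=pooled, se=pooled_se, ci_lo=ci_lo, ci_hi=ci_hi, p=p,
        Q=float(Q), df=int(df), p_Q=float(p_Q), tau2=float(tau2),
        model=chosen, k=k, effect_type=effect_type,
    )


def forest_table(
    estimates: list[EffectEstimate], meta: MetaResult
) -> pd.DataFrame:
    """Machine-readable forest plot: one row per cohort plus a pooled footer."""
    w = np.array([1.0 / (est.se**2 + meta.tau2) for est in estimates])
    weight_pct = 100.0 * w / w.sum()
    z975 = 1.96
    rows = [
        {
            "cohort_id": est.cohort_id,
            "n": est.n,
            "log_hr": est.effect,
            "se": est.se,
            "hr": float(np.exp(est.effect)),
            "ci_lo": float(np.exp(est.effect - z975 * est.se)),
            "ci_hi": float(np.exp(est.effect + z975 * est.se)),
            "weight_pct": float(pct),
        }
        for est, pct in zip(estimates, weight_pct)
    ]
    hr, lo, hi = meta.as_hazard_ratio()
    rows.append(
        {
            "cohort_id": f"POOLED({meta.model},Q={meta.Q:.4g},p_Q={meta.p_Q:.4g})",
            "n": int(sum(est.n for est in estimates)),
            "log_hr": meta.pooled_effect,
            "se": meta.se,
            "hr": hr,
            "ci_lo": lo,
            "ci_hi": hi,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
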