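"""Correlation estimation, correlation meta-analysis, and pooled ANOVA.

Per-cohort Pearson correlations (e.g. between a marker gene and the
proliferation score) are carried to the Fisher-z scale, where their sampling
variance is 1/(n-3), and pooled with the same inverse-variance /
heterogeneity-gated machinery as the survival effects.  Categorical
prognostic variables are analyzed by one-way ANOVA on samples pooled across
cohorts after per-cohort baseline centering.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CohortCollection, ExpressionDataset
from .subtyping import baseline_normalize
from .survival_meta import EffectEstimate, MetaResult, meta_effect

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


class PearsonResult(NamedTuple):
    estimate: EffectEstimate
    r: float
    p: float


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


def pearson_with_p(
    x, y, cohort_id: str = "", stratum: str = "all"
) -> PearsonResult:
    """Pearson correlation with its two-sided p and Fisher-z effect.

    The effect is ``atanh(r)`` with standard error ``1/sqrt(n-3)``; at
    ``|r| = 1`` the z-effect is computed on a value nudged just inside the
    open interval and the p-value is the smallest positive float.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AssociationError("x and y must be aligned")
    n = x.size
    if n < 4:
        raise AssociationError(f"at least 4 observations required, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise AssociationError("constant input vector")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        p = float(np.nextafter(0, 1))
        z = float(np.arctanh(np.sign(r) * (1.0 - 1e-15)))
    else:
        p = float(p)
        z = float(np.arctanh(r))
    est = EffectEstimate(
        cohort_id=cohort_id, effect=z, se=1.0 / np.sqrt(n - 3), n=n,
        effect_type="fisher_z", stratum=stratum,
    )
    return PearsonResult(estimate=est, r=r, p=p)


def meta_correlation(
    estimates: list[EffectEstimate], model: str = "auto"
) -> MetaResult:
    """Pool Fisher-z correlation estimates across cohorts.

    Same fixed/random machinery as the survival meta-analysis; report the
    pooled correlation via ``MetaResult.as_correlation()``.
    """
    if not estimates:
        raise AssociationError("meta-analysis requires at least one estimate")
    bad = {e.effect_type for e in estimates} - {"fisher_z"}
    if bad:
        raise AssociationError(f"non-correlation effect types present: {sorted(bad)}")
    return meta_effect(estimates, model=model)


def pooled_anova(
    collection: CohortCollection,
    gene: str,
    variable: str,
    baseline_level: str,
) -> AnovaResult:
    """One-way ANOVA of a gene across levels of a prognostic variable.

    Values are pooled across cohorts after per-cohort baseline centering
    (platform offsets cancel).  Each level must contribute at least 2 pooled
    samples and at least 2 levels must remain.
    """
    pooled = baseline_normalize(collection, variable, baseline_level, gene)
    counts = pooled.groupby("group").size()
    small = counts[counts < 2]
    if len(small):
        raise AssociationError(
            f"level(s) with fewer than 2 pooled samples: {dict(small)}"
        )
    levels = list(counts.index)
    if len(levels) < 2:
        raise AssociationError(f"at least 2 levels required, got {levels}")
    groups = [pooled.loc[pooled["group"] == lv, "value"].to_numpy() for lv in levels]
    F, p = stats.f_oneway(*groups)
    df_between = len(levels) - 1
    df_within = len(pooled) - len(levels)
    return AnovaResult(F=float(F), df_between=df_between,
                       df_within=df_within, p=float(p))


def transcriptome_correlates(
    dataset: ExpressionDataset,
    target_gene: str,
    threshold: float = 0.25,
    signed: bool = False,
) -> pd.DataFrame:
    """Screen every other gene for correlation with a target gene.

    Returns a DataFrame (gene, r) with genes passing ``|r| >= threshold``
    (default) or ``r >= threshold`` when ``signed``, sorted by ``|r|``
    descending.  The target itself is excluded.
    """
    if target_gene not in dataset.genes:
        raise AssociationError(f"target gene {target_gene!r} not present")
    X = dataset.values.to_numpy(dtype=float)
    y = dataset.gene_values(target_gene).to_numpy(dtype=float)
    if y.std() == 0:
        raise AssociationError(f"target gene {target_gene!r} is constant")
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (x_norm * np.sqrt((yc**2).sum()))
    table = pd.DataFrame({"gene": dataset.genes, "r": r})
    table = table[table["gene"] != target_gene]
    table = table.dropna(subset=["r"])
    keep = table["r"] >= threshold if signed else table["r"].abs() >= threshold
    table = table[keep]
    table = table.reindex(table["r"].abs().sort_values(ascending=False).index)
    return table.reset_index(drop=True)
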