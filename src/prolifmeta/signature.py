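"""Proliferation signature derivation and per-sample scoring.

The signature is derived in three steps: (1) a regularized (empirical-Bayes
style) two-sample t-test between the low- and high-serum conditions, in which
each gene's variance is shrunk toward a background estimate pooled over genes
of similar mean expression; (2) Benjamini-Hochberg selection at a configured
FDR; (3) intersection of the significant serum-responsive genes with a
cell-cycle gene set, each surviving gene weighted by its serum-response log
fold change.  Samples are then scored with a weight-normalized sum of
centered expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionDataset
from .syndata import TwoGroupExperiment

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    """Gene labels with signed log-fold-change weights.

    Positive weight = up with proliferation (high-serum minus low-serum
    orientation).
    """

    genes: tuple[str, ...]
    weights: tuple[float, ...]
    name: str = "proliferation"

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise SignatureError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise SignatureError("signature gene labels must be unique")
        if len(self.weights) != len(self.genes):
            raise SignatureError("genes and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if not np.isfinite(w).all():
            raise SignatureError("weights must be finite")
        if (w == 0).any():
            raise SignatureError("zero weights are not allowed")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.genes, name="gene"),
                         name="weight", dtype=float)

    def to_tsv(self, path) -> None:
        self.as_series().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, name: str = "proliferation") -> "GeneSignature":
        s = pd.read_csv(path, sep="\t", index_col=0)["weight"]
        return cls(genes=tuple(s.index.astype(str)),
                   weights=tuple(float(v) for v in s), name=name)


def _rolling_background_variance(
    means: np.ndarray, variances: np.ndarray, window: int
) -> np.ndarray:
    """Mean sample variance over the ``window`` genes nearest in rank of mean
    expression (centered window, truncated at the edges)."""
    order = np.argsort(means, kind="stable")
    v_sorted = pd.Series(variances[order])
    bg_sorted = v_sorted.rolling(window, center=True, min_periods=1).mean().to_numpy()
    bg = np.empty_like(bg_sorted)
    bg[order] = bg_sorted
    return bg


def regularized_two_sample_t(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    nu0: float = 10.0,
    window: int = 101,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Regularized two-sample t-test per gene (Cyber-T style).

    Per gene and group, the background variance ``sigma0^2`` is the mean
    sample variance over the ``window`` genes nearest in rank of mean
    expression within that group; the regularized variance is::

        s~^2 = (nu0 * sigma0^2 + (n - 1) * s^2) / (nu0 + n - 2)

    and the statistic is the Welch-style combination
    ``t = (mean_b - mean_a) / sqrt(s~_a^2/n_a + s~_b^2/n_b)`` with p-values
    from a t distribution on ``nu0 + n_a + n_b - 2`` degrees of freedom.
    ``log_fc = mean_b - mean_a``, with b the high-serum group by default.

    With ``nu0 = 0`` the shrinkage target drops out and each group's
    regularized variance is ``(n-1)/(n-2) * s^2`` (the Bayesian df
    convention), so the statistic equals the ordinary equal-variance
    two-sample t times ``sqrt((n-2)/(n-1))`` when group sizes are equal.
    """
    group_labels = group_labels.loc[matrix.columns]
    levels = sorted(set(group_labels))
    if len(levels) != 2:
        raise SignatureError(f"exactly two groups required, got {levels}")
    if group_a is None or group_b is None:
        if set(levels) == {"low_serum", "high_serum"}:
            group_a, group_b = "low_serum", "high_serum"
        else:
            group_a, group_b = levels
    for level in (group_a, group_b):
        if (group_labels == level).sum() < 2:
            raise SignatureError(
                f"group {level!r} has {(group_labels == level).sum()} arrays; "
                "at least 2 required"
            )
    if window % 2 == 0 or window < 1:
        raise SignatureError(f"window must be a positive odd count, got {window}")
    if window > matrix.shape[0]:
        raise SignatureError("window exceeds the number of genes")

    out = {}
    n = {}
    for key, level in (("a", group_a), ("b", group_b)):
        cols = group_labels.index[group_labels == level]
        sub = matrix[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        sigma0 = _rolling_background_variance(m, s2, window)
        n_g = sub.shape[1]
        reg = (nu0 * sigma0 + (n_g - 1) * s2) / (nu0 + n_g - 2)
        out[key] = (m, reg)
        n[key] = n_g

    mean_a, var_a = out["a"]
    mean_b, var_b = out["b"]
    denom2 = var_a / n["a"] + var_b / n["b"]
    if (denom2 <= 0).any():
        raise SignatureError(
            "zero regularized variance (constant data with nu0 = 0?)"
        )
    log_fc = mean_b - mean_a
    t = log_fc / np.sqrt(denom2)
    df = nu0 + n["a"] + n["b"] - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log_fc": log_fc,
            "t_stat": t,
            "p_value": p,
        },
        index=matrix.index,
    )


def benjamini_hochberg(
    p_values, q: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Returns (significant flags, monotone adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise SignatureError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise SignatureError(f"FDR level q must be in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def serum_differential_expression(
    experiment: TwoGroupExperiment,
    nu0: float = 10.0,
    window: int = 101,
    q: float = 0.10,
) -> pd.DataFrame:
    """Run the regularized t-test on a serum experiment and apply BH at ``q``."""
    de = regularized_two_sample_t(
        experiment.matrix, experiment.group_labels, nu0=nu0, window=window,
        group_a="low_serum", group_b="high_serum",
    )
    reject, p_adj = benjamini_hochberg(de["p_value"].to_numpy(), q=q)
    de = de.assign(fdr_adjusted_p=p_adj, significant=reject)
    return de


def build_proliferation_signature(
    cycle_gene_set,
    de_result: pd.DataFrame,
    q: float = 0.10,
    name: str = "proliferation",
) -> GeneSignature:
    """Intersect significant serum-responsive genes with a cell-cycle gene set.

    Each retained gene is weighted by its serum-response log fold change.
    """
    if "significant" not in de_result.columns:
        reject, p_adj = benjamini_hochberg(de_result["p_value"].to_numpy(), q=q)
        de_result = de_result.assign(fdr_adjusted_p=p_adj, significant=reject)
    significant = de_result.index[de_result["significant"]]
    cycle = set(cycle_gene_set)
    selected = [g for g in significant if g in cycle]
    # drop genes with exactly zero fold change (cannot carry a signed weight)
    selected = [g for g in selected if de_result.loc[g, "log_fc"] != 0]
    if not selected:
        raise SignatureError(
            "empty intersection of significant serum-responsive genes and the "
            "cell-cycle set; review the FDR level, gene sets, or experiment size"
        )
    weights = [float(de_result.loc[g, "log_fc"]) for g in selected]
    return GeneSignature(genes=tuple(selected), weights=tuple(weights), name=name)


def score_samples(
    dataset: ExpressionDataset,
    signature: GeneSignature,
    standardize: bool = False,
) -> pd.Series:
    """Weighted proliferation score per sample.

    Signature genes present in the cohort are centered per gene (cohort mean
    subtracted; optionally scaled to unit SD when ``standardize``), and the
    score is ``sum_g w_g * x~_gj / sum_g |w_g|``.  Missing signature genes are
    counted and logged; at least one must be present.
    """
    w = signature.as_series()
    present = w.index.intersection(dataset.genes)
    n_missing = len(w) - len(present)
    if len(present) == 0:
        raise SignatureError(
            f"no signature genes present in cohort {dataset.cohort_id}"
        )
    if n_missing:
        logger.warning(
            "cohort %s: %d of %d signature genes missing",
            dataset.cohort_id, n_missing, len(w),
        )
    x = dataset.values.loc[present]
    centered = x.sub(x.mean(axis=1), axis=0)
    if standardize:
        sd = x.std(axis=1, ddof=1).replace(0.0, np.nan)
        centered = centered.div(sd, axis=0).fillna(0.0)
    wp = w.loc[present]
    score = centered.mul(wp, axis=0).sum(axis=0) / wp.abs().sum()
    score.name = signature.name
    return score
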