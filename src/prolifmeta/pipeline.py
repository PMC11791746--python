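"""End-to-end orchestration: simulate/load -> signature -> score -> subtype
-> associate -> survival meta-analysis -> evaluate.

A single :class:`PipelineConfig` drives the whole analysis.  Strata are
declarative clinical filters ("all", "er=positive", "er=positive&her2=negative",
"subtype=Basal", ...), applied per cohort before estimation; strata with fewer
than ``min_stratum_n`` samples in a cohort drop that cohort from the stratum
with a logged reason.  All outputs are plain TSV/JSON and are byte-identical
across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import CohortCollection, ExpressionDataset, read_collection
from .evaluation import compare_signatures
from .signature import (
    GeneSignature,
    build_proliferation_signature,
    score_samples,
    serum_differential_expression,
)
from .subtyping import approximate_her2_status, skip_her2_approximation
from .survival_meta import (
    EffectEstimate,
    forest_table,
    meta_effect,
    per_dataset_gene_hr,
)
from .association import meta_correlation, pearson_with_p
from .syndata import (
    ERBB2_ANALOG,
    SimulationConfig,
    cycle_gene_set,
    simulate_cohort_collection,
    simulate_serum_experiment,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the full analysis run."""

    mode: str = "simulate"                   # "simulate" or "load"
    simulation: SimulationConfig | None = None
    manifest: str | None = None              # cohort bundle manifest (load mode)
    signature_source: str = "derive"         # "derive" or "file"
    signature_file: str | None = None
    target_genes: tuple[str, ...] = ("PGRMC1", "TMEM97", "TK1", "LDLR")
    strata: tuple[str, ...] = (
        "all",
        "er=positive",
        "er=negative",
        "her2=negative",
        "er=positive&her2=negative",
    )
    horizon_months: float = 60.0
    fdr_q: float = 0.10
    her2_mode: str = "auto"                  # annotated | approximate | auto
    nu0: float = 10.0
    window: int = 101
    serum_n_per_group: int = 10
    serum_n_de: int = 300
    serum_log_fc_scale: float = 1.0
    cycle_set_extra: int = 150
    min_stratum_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.manifest is not None:
            raise PipelineError("exactly one input mode: manifest set in simulate mode")
        if self.mode == "load" and self.manifest is None:
            raise PipelineError("load mode requires a manifest path")
        if self.signature_source not in ("derive", "file"):
            raise PipelineError(f"unknown signature_source {self.signature_source!r}")
        if self.signature_source == "file" and self.signature_file is None:
            raise PipelineError("signature_source='file' requires signature_file")
        if self.horizon_months <= 0:
            raise PipelineError("horizon_months must be > 0")
        if not 0 < self.fdr_q < 1:
            raise PipelineError("fdr_q must be in (0, 1)")
        if self.her2_mode not in ("annotated", "approximate", "auto"):
            raise PipelineError(f"unknown her2_mode {self.her2_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("target_genes", "strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def parse_stratum(stratum: str) -> dict[str, str]:
    """Parse "er=positive&her2=negative" into {"er": "positive", ...}."""
    if stratum in ("all", ""):
        return {}
    out: dict[str, str] = {}
    for clause in stratum.split("&"):
        key, sep, value = clause.partition("=")
        if not sep or not key.strip() or not value.strip():
            raise PipelineError(f"malformed stratum clause {clause!r}")
        out[key.strip()] = value.strip()
    return out


@dataclass
class PipelineState:
    """Shared intermediate products of one pipeline run."""

    config: PipelineConfig
    collection: CohortCollection
    signature: GeneSignature
    scores: dict[str, pd.Series]                 # cohort_id -> per-sample score
    her2: dict[str, pd.Series]                   # cohort_id -> resolved HER2 labels
    skipped: list[dict] = field(default_factory=list)

    def log_skip(self, stage: str, cohort_id: str, stratum: str, reason: str) -> None:
        entry = {"stage": stage, "cohort_id": cohort_id,
                 "stratum": stratum, "reason": reason}
        self.skipped.append(entry)
        logger.info("skip [%s] cohort=%s stratum=%s: %s",
                    stage, cohort_id, stratum, reason)


def _resolve_her2(config: PipelineConfig, cohort: ExpressionDataset) -> pd.Series:
    annotated = cohort.clinical["her2"].astype(str)
    has_annotation = annotated.isin(["positive", "negative"]).any()
    mode = config.her2_mode
    if mode == "auto":
        mode = "annotated" if has_annotation else "approximate"
    if mode == "annotated":
        return annotated
    if skip_her2_approximation(cohort) or ERBB2_ANALOG not in cohort.genes:
        logger.info("cohort %s: HER2 approximation skipped", cohort.cohort_id)
        return pd.Series("unknown", index=cohort.samples)
    call = approximate_her2_status(cohort.gene_values(ERBB2_ANALOG))
    return call.status


def prepare(config: PipelineConfig) -> PipelineState:
    """Build the shared state: cohorts, signature, scores, HER2 labels."""
    if config.mode == "simulate":
        sim = config.simulation or SimulationConfig(seed=config.seed)
        collection = simulate_cohort_collection(sim)
    else:
        collection = read_collection(config.manifest)

    if config.signature_source == "file":
        signature = GeneSignature.from_tsv(config.signature_file)
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        experiment = simulate_serum_experiment(
            sim,
            n_per_group=config.serum_n_per_group,
            n_de=config.serum_n_de,
            log_fc_scale=config.serum_log_fc_scale,
        )
        de = serum_differential_expression(
            experiment, nu0=config.nu0, window=config.window, q=config.fdr_q
        )
        signature = build_proliferation_signature(
            cycle_gene_set(sim, n_extra=config.cycle_set_extra), de, q=config.fdr_q
        )

    scores = {c.cohort_id: score_samples(c, signature) for c in collection}
    her2 = {c.cohort_id: _resolve_her2(config, c) for c in collection}
    return PipelineState(config=config, collection=collection,
                         signature=signature, scores=scores, her2=her2)


def _stratum_samples(
    state: PipelineState, cohort: ExpressionDataset, stratum: str
) -> pd.Index:
    filters = parse_stratum(stratum)
    mask = pd.Series(True, index=cohort.samples)
    for key, value in filters.items():
        if key == "her2":
            labels = state.her2[cohort.cohort_id].astype(str)
        elif key in cohort.clinical.columns:
            labels = cohort.clinical[key].astype(str)
        else:
            raise PipelineError(f"unknown stratum variable {key!r}")
        mask &= labels == value
    return cohort.samples[mask.to_numpy()]


def run_association_analysis(
    config_or_state: PipelineConfig | PipelineState,
) -> pd.DataFrame:
    """Per gene x stratum meta-analyzed score-gene correlations.

    One row per (gene, stratum) with the pooled correlation, its CI, p,
    Cochran's Q and the model used; strata empty in all cohorts yield an NA
    row with the reason.
    """
    state = (config_or_state if isinstance(config_or_state, PipelineState)
             else prepare(config_or_state))
    config = state.config
    rows = []
    for gene in config.target_genes:
        for stratum in config.strata:
            estimates: list[EffectEstimate] = []
            for cohort in state.collection:
                if gene not in cohort.genes:
                    state.log_skip("association", cohort.cohort_id, stratum,
                                   f"gene {gene} absent")
                    continue
                samples = _stratum_samples(state, cohort, stratum)
                if len(samples) < config.min_stratum_n:
                    state.log_skip("association", cohort.cohort_id, stratum,
                                   f"n={len(samples)} below minimum")
                    continue
                x = cohort.gene_values(gene).loc[samples].to_numpy(dtype=float)
                y = state.scores[cohort.cohort_id].loc[samples].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    state.log_skip("association", cohort.cohort_id, stratum,
                                   "constant gene or score")
                    continue
                res = pearson_with_p(x, y, cohort_id=cohort.cohort_id,
                                     stratum=stratum)
                estimates.append(res.estimate)
            base = {"gene": gene, "stratum": stratum, "k": len(estimates)}
            if not estimates:
                rows.append({**base, "pooled_r": np.nan, "ci_lo": np.nan,
                             "ci_hi": np.nan, "p": np.nan, "Q": np.nan,
                             "p_Q": np.nan, "model": "NA",
                             "reason": "stratum empty in all cohorts"})
                continue
            meta = meta_correlation(estimates)
            r, lo, hi = meta.as_correlation()
            rows.append({**base, "pooled_r": r, "ci_lo": lo, "ci_hi": hi,
                         "p": meta.p, "Q": meta.Q, "p_Q": meta.p_Q,
                         "model": meta.model, "reason": ""})
    return pd.DataFrame(rows)


def run_survival_analysis(
    config_or_state: PipelineConfig | PipelineState,
) -> pd.DataFrame:
    """Pooled per-SD hazard ratios per gene x stratum, unadjusted and
    proliferation-score-adjusted."""
    state = (config_or_state if isinstance(config_or_state, PipelineState)
             else prepare(config_or_state))
    config = state.config
    rows = []
    for gene in config.target_genes:
        for stratum in config.strata:
            sub_cohorts = []
            for cohort in state.collection:
                samples = _stratum_samples(state, cohort, stratum)
                if len(samples) < config.min_stratum_n:
                    state.log_skip("survival", cohort.cohort_id, stratum,
                                   f"n={len(samples)} below minimum")
                    continue
                sub_cohorts.append(cohort.subset_samples(samples))
            if not sub_cohorts:
                for adjusted in (False, True):
                    rows.append({"gene": gene, "stratum": stratum,
                                 "adjusted": adjusted, "k": 0, "hr": np.nan,
                                 "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                                 "Q": np.nan, "p_Q": np.nan, "model": "NA",
                                 "reason": "stratum empty in all cohorts"})
                continue
            sub = CohortCollection(sub_cohorts)
            for adjusted in (False, True):
                adjust = state.scores if adjusted else None
                try:
                    ests = per_dataset_gene_hr(
                        sub, gene, adjust_scores=adjust,
                        horizon_months=config.horizon_months, stratum=stratum,
                    )
                except Exception as err:  # gene absent everywhere, etc.
                    rows.append({"gene": gene, "stratum": stratum,
                                 "adjusted": adjusted, "k": 0, "hr": np.nan,
                                 "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                                 "Q": np.nan, "p_Q": np.nan, "model": "NA",
                                 "reason": str(err)})
                    continue
                if not ests:
                    rows.append({"gene": gene, "stratum": stratum,
                                 "adjusted": adjusted, "k": 0, "hr": np.nan,
                                 "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                                 "Q": np.nan, "p_Q": np.nan, "model": "NA",
                                 "reason": "no cohort could be fit"})
                    continue
                meta = meta_effect(ests)
                hr, lo, hi = meta.as_hazard_ratio()
                rows.append({"gene": gene, "stratum": stratum,
                             "adjusted": adjusted, "k": meta.k, "hr": hr,
                             "ci_lo": lo, "ci_hi": hi, "p": meta.p,
                             "Q": meta.Q, "p_Q": meta.p_Q, "model": meta.model,
                             "reason": ""})
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full analysis and write all reports under ``out_dir``.

    Outputs: association_table.tsv, survival_table.tsv, per-gene forest
    tables (all-samples stratum, unadjusted), signature.tsv,
    c_index_table.tsv, skipped.tsv and run_manifest.json.  Deterministic:
    same config + seed give byte-identical trees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state = prepare(config)

    association = run_association_analysis(state)
    survival = run_survival_analysis(state)

    written: dict[str, Path] = {}
    state.signature.to_tsv(out_dir / "signature.tsv")
    written["signature"] = out_dir / "signature.tsv"
    _write_tsv(association, out_dir / "association_table.tsv")
    written["association"] = out_dir / "association_table.tsv"
    _write_tsv(survival, out_dir / "survival_table.tsv")
    written["survival"] = out_dir / "survival_table.tsv"

    for gene in config.target_genes:
        try:
            ests = per_dataset_gene_hr(
                state.collection, gene, horizon_months=config.horizon_months
            )
        except Exception:
            continue
        if not ests:
            continue
        meta = meta_effect(ests)
        path = out_dir / f"forest_{gene}.tsv"
        _write_tsv(forest_table(ests, meta), path)
        written[f"forest_{gene}"] = path

    score_sets = {state.signature.name: state.scores}
    try:
        cidx = compare_signatures(state.collection, score_sets,
                                  horizon_months=config.horizon_months)
        _write_tsv(cidx, out_dir / "c_index_table.tsv")
        written["c_index"] = out_dir / "c_index_table.tsv"
    except Exception as err:
        logger.warning("C-index evaluation skipped: %s", err)

    skipped = pd.DataFrame(
        state.skipped, columns=["stage", "cohort_id", "stratum", "reason"]
    )
    _write_tsv(skipped, out_dir / "skipped.tsv")
    written["skipped"] = out_dir / "skipped.tsv"

    cfg_text = repr(config)
    manifest = {
        "package": "prolifmeta",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_text,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_cohorts": len(state.collection),
        "signature_size": len(state.signature.genes),
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["run_manifest"] = manifest_path
    return written
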