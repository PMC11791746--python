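"""Synthetic multi-cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes about real breast cancer expression cohorts:

* a latent per-sample proliferation level ``P ~ Normal(0, 1)`` drives a block
  of cell-cycle genes and, with gene-specific loadings, a handful of marker
  genes (PGRMC1/TMEM97/TK1/LDLR analogs);
* each cohort carries additive per-gene platform offsets (cross-platform
  location differences that per-cohort centering must remove);
* an ERBB2 analog receives a large additive shift in a minority of samples
  (the HER2+ outlier mixture that the COPA-style caller must detect);
* survival is exponential with hazard ``h0 * exp(gamma * P + theta * x_m)``
  so that, with ``theta = 0``, any marker gene's survival association exists
  *only* through its loading on P — the mediation structure the
  proliferation-adjusted Cox models are meant to expose;
* a separate two-condition "serum response" experiment plants differentially
  expressed genes (the proliferation block among them) from which the
  signature stage can re-derive the planted gene set.

Expression model per cohort d, gene g, sample j::

    x_gj = mu_g + a_g^(d) + beta_g * P_j + eps_gj
    a_g^(d) ~ Normal(0, platform_sd^2),  eps ~ Normal(0, noise_sd^2)

with ``beta_g = proliferation_loading_scale`` for proliferation genes,
``marker_loadings[g]`` for marker analogs, else 0.  Survival time
``T ~ Exponential(h0 * exp(gamma*P + theta*(x_m - mean)))`` in months,
censored at ``C ~ Uniform(0, censoring_max)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    CLINICAL_COLUMNS,
    CohortCollection,
    ExpressionDataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

ERBB2_ANALOG = "ERBB2"

#: default marker loadings, chosen so that with the default noise_sd = 0.5 the
#: per-gene correlation with the latent proliferation level spans the weak to
#: strong range observed for such markers in tumor cohorts
#: (r = beta / sqrt(beta^2 + noise_sd^2): ~0.27, ~0.51, ~0.69, ~0.16).
DEFAULT_MARKER_LOADINGS: dict[str, float] = {
    "PGRMC1": 0.14,
    "TMEM97": 0.30,
    "TK1": 0.47,
    "LDLR": 0.08,
}


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification for the synthetic cohort collection.

    Defaults encode the study conditions exercised throughout the test
    suite: 10 cohorts of 200 samples, 1,000 genes of which 150 form the
    proliferation block, unit proliferation loadings, residual SD 0.5 log2
    units, 15% HER2+ with a +2 log2 ERBB2 shift (4 residual SDs), log-hazard
    0.4 per SD of latent proliferation, and uniform censoring over 120
    months so the 60-month horizon restriction is exercised.
    """

    n_cohorts: int = 10
    samples_per_cohort: int | Sequence[int] = 200
    n_genes: int = 1000
    n_proliferation_genes: int = 150
    proliferation_loading_scale: float = 1.0
    platform_sd: float = 0.5
    noise_sd: float = 0.5
    her2_fraction: float = 0.15
    her2_shift: float = 2.0
    marker_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LOADINGS)
    )
    baseline_hazard: float = 0.01
    log_hazard_per_sd: float = 0.4
    direct_marker_log_hazard: float = 0.0
    direct_marker: str | None = None
    censoring_max: float = 120.0
    er_positive_fraction: float = 0.7
    #: when nonzero, ER- samples get latent P shifted upward by this amount
    #: (couples hormone-receptor-negative status to higher proliferation).
    er_negative_proliferation_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> SimulationConfigError:
            return SimulationConfigError(f"invalid {name}: {why}")

        for name in ("n_cohorts", "n_genes", "n_proliferation_genes"):
            if int(getattr(self, name)) < 1:
                raise bad(name, "must be >= 1")
        for n in self.cohort_sizes():
            if n < 1:
                raise bad("samples_per_cohort", "all cohort sizes must be >= 1")
        for name in ("platform_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        for name in ("her2_fraction", "er_positive_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise bad(name, "must be a probability in [0, 1]")
        if self.baseline_hazard <= 0:
            raise bad("baseline_hazard", "must be > 0")
        if self.censoring_max <= 0:
            raise bad("censoring_max", "must be > 0")
        labels = self.gene_labels()
        missing = [g for g in self.marker_loadings if g not in set(labels)]
        if missing:
            raise bad(
                "marker_loadings",
                f"labels {missing} do not fit among n_genes={self.n_genes} genes",
            )
        if self.direct_marker is not None and self.direct_marker not in set(labels):
            raise bad("direct_marker", f"{self.direct_marker!r} not a gene label")

    def cohort_sizes(self) -> list[int]:
        if isinstance(self.samples_per_cohort, (int, np.integer)):
            return [int(self.samples_per_cohort)] * self.n_cohorts
        sizes = [int(n) for n in self.samples_per_cohort]
        if len(sizes) != self.n_cohorts:
            raise SimulationConfigError(
                "invalid samples_per_cohort: list length must equal n_cohorts"
            )
        return sizes

    # ---- gene universe layout -------------------------------------------
    def marker_genes(self) -> list[str]:
        return list(self.marker_loadings)

    def proliferation_genes(self) -> list[str]:
        return [f"CCG{i + 1:04d}" for i in range(self.n_proliferation_genes)]

    def filler_genes(self) -> list[str]:
        n_named = len(self.marker_loadings) + 1 + self.n_proliferation_genes
        return [f"G{i + 1:05d}" for i in range(max(0, self.n_genes - n_named))]

    def gene_labels(self) -> list[str]:
        labels = (
            self.marker_genes()
            + [ERBB2_ANALOG]
            + self.proliferation_genes()
            + self.filler_genes()
        )
        if len(labels) > self.n_genes:
            raise SimulationConfigError(
                "invalid n_genes: too small for marker + ERBB2 + proliferation genes"
            )
        return labels

    def loadings(self) -> pd.Series:
        beta = pd.Series(0.0, index=pd.Index(self.gene_labels(), name="gene"))
        beta[self.proliferation_genes()] = self.proliferation_loading_scale
        for g, b in self.marker_loadings.items():
            beta[g] = b
        return beta


@dataclass
class CohortGroundTruth:
    """Per-cohort latent variables recorded by the generator."""

    latent: pd.Series            # P_j, the latent proliferation level
    her2_true: pd.Series         # planted HER2 labels ("positive"/"negative")
    loadings: pd.Series          # beta_g
    baseline_mean: pd.Series     # mu_g (shared across cohorts)
    platform_offset: pd.Series   # a_g^(d)


@dataclass
class TwoGroupExperiment:
    """Two-condition serum-response experiment with planted DE genes."""

    matrix: pd.DataFrame                 # genes x arrays, log2 values
    group_labels: pd.Series              # per array: low_serum / high_serum
    true_de_genes: set[str]
    true_log_fc: dict[str, float]        # high minus low serum, log2 units

    def __post_init__(self) -> None:
        groups = set(self.group_labels)
        if groups != {"low_serum", "high_serum"}:
            raise SimulationConfigError(
                f"group_labels must be low_serum/high_serum, got {sorted(groups)}"
            )
        missing = self.true_de_genes - set(self.matrix.index)
        if missing:
            raise SimulationConfigError(
                f"true DE genes absent from the matrix: {sorted(missing)}"
            )


def _baseline_means(config: SimulationConfig) -> pd.Series:
    """Per-gene baseline log2 means, shared across cohorts (seeded substream)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6D65616E]))
    labels = config.gene_labels()
    mu = rng.normal(8.0, 1.5, size=len(labels))
    return pd.Series(mu, index=pd.Index(labels, name="gene"))


def simulate_cohort_collection(config: SimulationConfig) -> CohortCollection:
    """Generate ``config.n_cohorts`` cohorts under the documented model.

    Each returned :class:`ExpressionDataset` carries a
    :class:`CohortGroundTruth` in its ``truth`` field.  The same seed yields
    byte-identical output.
    """
    labels = pd.Index(config.gene_labels(), name="gene")
    beta = config.loadings()
    mu = _baseline_means(config)
    root = np.random.SeedSequence([config.seed, 0x636F686F])
    children = root.spawn(config.n_cohorts)
    sizes = config.cohort_sizes()
    cohorts = []
    for d, (size, child) in enumerate(zip(sizes, children)):
        rng = np.random.default_rng(child)
        cohort_id = f"SYN{d + 1:02d}"
        samples = pd.Index(
            [f"{cohort_id}_S{j + 1:04d}" for j in range(size)], name="sample_id"
        )

        er_pos = rng.random(size) < config.er_positive_fraction
        P = rng.normal(0.0, 1.0, size=size)
        if config.er_negative_proliferation_shift:
            P = P + config.er_negative_proliferation_shift * (~er_pos)
        her2_pos = rng.random(size) < config.her2_fraction

        offsets = rng.normal(0.0, config.platform_sd, size=len(labels))
        eps = rng.normal(0.0, config.noise_sd, size=(len(labels), size))
        x = (
            mu.to_numpy()[:, None]
            + offsets[:, None]
            + np.outer(beta.to_numpy(), P)
            + eps
        )
        values = pd.DataFrame(x, index=labels, columns=samples)
        values.loc[ERBB2_ANALOG] += config.her2_shift * her2_pos

        # survival: exponential hazard on latent proliferation, optionally with
        # a direct effect of one marker's (centered) expression
        log_rate = np.log(config.baseline_hazard) + config.log_hazard_per_sd * P
        if config.direct_marker is not None and config.direct_marker_log_hazard:
            xm = values.loc[config.direct_marker].to_numpy()
            log_rate = log_rate + config.direct_marker_log_hazard * (xm - xm.mean())
        T = rng.exponential(scale=1.0, size=size) / np.exp(log_rate)
        C = rng.uniform(0.0, config.censoring_max, size=size)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)

        pr_pos = np.where(er_pos, rng.random(size) < 0.8, rng.random(size) < 0.15)
        grade = rng.choice([1, 2, 3], size=size, p=[0.2, 0.45, 0.35])
        node = np.where(rng.random(size) < 0.4, "positive", "negative")
        size_class = rng.choice(["T1", "T2", "T3"], size=size, p=[0.4, 0.45, 0.15])
        treated = np.where(rng.random(size) < 0.5, "yes", "no")
        subtype = np.where(
            her2_pos, "Her2",
            np.where(~er_pos, "Basal", np.where(P > 0, "LumB", "LumA")),
        )

        clinical = pd.DataFrame(
            {
                "er": np.where(er_pos, "positive", "negative"),
                "pr": np.where(pr_pos, "positive", "negative"),
                "her2": np.where(her2_pos, "positive", "negative"),
                "grade": grade.astype(str),
                "node": node,
                "size": size_class,
                "subtype": subtype,
                "time_months": np.round(time, 6),
                "event": event,
                "endpoint": "RFS",
                "treated": treated,
            },
            index=samples,
        )[list(CLINICAL_COLUMNS)]

        truth = CohortGroundTruth(
            latent=pd.Series(P, index=samples, name="latent_proliferation"),
            her2_true=pd.Series(
                np.where(her2_pos, "positive", "negative"), index=samples
            ),
            loadings=beta,
            baseline_mean=mu,
            platform_offset=pd.Series(offsets, index=labels),
        )
        cohorts.append(
            ExpressionDataset(
                cohort_id=cohort_id,
                values=values,
                clinical=clinical,
                platform=f"synthetic-platform-{d % 3 + 1}",
                endpoint="RFS",
                truth=truth,
            )
        )
    return CohortCollection(cohorts)


def cycle_gene_set(config: SimulationConfig, n_extra: int = 150) -> list[str]:
    """A cell-cycle gene set analog: the proliferation block plus ``n_extra``
    cycle-regulated-but-not-serum-responsive decoys drawn from the end of the
    filler block (guaranteed disjoint from serum DE genes chosen from the
    front)."""
    filler = config.filler_genes()
    if n_extra > len(filler):
        raise SimulationConfigError(
            f"invalid n_extra: only {len(filler)} filler genes available"
        )
    decoys = filler[len(filler) - n_extra:]
    return config.proliferation_genes() + decoys


def simulate_serum_experiment(
    config: SimulationConfig,
    n_per_group: int = 10,
    n_de: int = 300,
    log_fc_scale: float = 1.0,
) -> TwoGroupExperiment:
    """Simulate a low- vs high-serum experiment with planted DE genes.

    The proliferation block is planted as up-regulated in high serum (so the
    derived weights are sign-correct for a proliferation score); additional DE
    genes up to ``n_de`` are taken from the front of the filler block with
    random sign.  Residual SD is ``config.noise_sd``.
    """
    if n_per_group < 2:
        raise SimulationConfigError("invalid n_per_group: must be >= 2")
    if n_de > config.n_genes:
        raise SimulationConfigError(
            f"invalid n_de: {n_de} exceeds n_genes={config.n_genes}"
        )
    labels = pd.Index(config.gene_labels(), name="gene")
    prolif = config.proliferation_genes()
    filler = config.filler_genes()
    n_from_prolif = min(n_de, len(prolif))
    n_from_filler = n_de - n_from_prolif
    if n_from_filler > len(filler):
        raise SimulationConfigError(
            "invalid n_de: not enough non-marker genes to plant"
        )
    de_genes = prolif[:n_from_prolif] + filler[:n_from_filler]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x73657275]))
    mu = _baseline_means(config)
    signs = pd.Series(0.0, index=labels)
    signs[prolif[:n_from_prolif]] = 1.0
    if n_from_filler:
        signs[filler[:n_from_filler]] = rng.choice(
            [-1.0, 1.0], size=n_from_filler
        )
    true_log_fc = signs * log_fc_scale

    arrays = pd.Index(
        [f"low_{i + 1:02d}" for i in range(n_per_group)]
        + [f"high_{i + 1:02d}" for i in range(n_per_group)],
        name="array",
    )
    group = pd.Series(
        ["low_serum"] * n_per_group + ["high_serum"] * n_per_group, index=arrays
    )
    high = (group == "high_serum").to_numpy().astype(float)
    x = (
        mu.to_numpy()[:, None]
        + np.outer(true_log_fc.to_numpy(), high)
        + rng.normal(0.0, config.noise_sd, size=(len(labels), len(arrays)))
    )
    matrix = pd.DataFrame(x, index=labels, columns=arrays)
    return TwoGroupExperiment(
        matrix=matrix,
        group_labels=group,
        true_de_genes=set(de_genes),
        true_log_fc={g: float(true_log_fc[g]) for g in de_genes},
    )


def write_fixture_bundle(
    collection: CohortCollection, directory: str | Path
) -> dict[str, Path]:
    """Write one expression + one clinical TSV per cohort plus a manifest.

    Round-trips losslessly through :func:`prolifmeta.dataio.read_collection`.
    Returns a mapping of logical names to written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_lines = [f"n_cohorts={len(collection)}"]
    written: dict[str, Path] = {}
    for i, cohort in enumerate(collection):
        paths = write_dataset(cohort, directory)
        manifest_lines += [
            f"cohort.{i}.id={cohort.cohort_id}",
            f"cohort.{i}.expression={paths['expression'].name}",
            f"cohort.{i}.clinical={paths['clinical'].name}",
            f"cohort.{i}.platform={cohort.platform}",
            f"cohort.{i}.endpoint={cohort.endpoint}",
        ]
        written[f"{cohort.cohort_id}.expression"] = paths["expression"]
        written[f"{cohort.cohort_id}.clinical"] = paths["clinical"]
    manifest = directory / "manifest.txt"
    manifest.write_text("\n".join(manifest_lines) + "\n")
    written["manifest"] = manifest
    return written


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down configuration for quick end-to-end runs."""
    defaults = dict(
        n_cohorts=4,
        samples_per_cohort=60,
        n_genes=300,
        n_proliferation_genes=40,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
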