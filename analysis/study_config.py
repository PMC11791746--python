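"""Shared study conditions for the numbered analysis drivers.

One cohort collection of 10 synthetic cohorts x 200 samples (1,000 genes,
150-gene proliferation block, marker loadings spanning weak to strong) and
one serum-response experiment (10 arrays per condition, 300 planted DE genes
of which 150 are cycle-regulated).  Every driver derives its inputs from
these conditions and the single study seed.
"""

from prolifmeta.pipeline import PipelineConfig
from prolifmeta.syndata import SimulationConfig

STUDY_SEED = 1234

SIMULATION = SimulationConfig(seed=STUDY_SEED)

PIPELINE = PipelineConfig(
    simulation=SIMULATION,
    target_genes=("PGRMC1", "TMEM97", "TK1", "LDLR"),
    strata=(
        "all",
        "er=positive",
        "er=negative",
        "her2=positive",
        "her2=negative",
        "er=positive&her2=negative",
        "er=negative&her2=negative",
        "node=positive",
        "node=negative",
    ),
    seed=STUDY_SEED,
)
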