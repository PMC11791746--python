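"""Score every cohort with the derived signature and meta-analyze
marker-score correlations per stratum.

Produces the machine-readable analog of a marker-vs-proliferation
association table: one row per (gene, stratum) with the pooled Fisher-z
back-transformed correlation, its 95% CI, p-value, and Cochran's Q model
choice.  Writes results/association_table.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import PIPELINE  # noqa: E402

from prolifmeta.pipeline import prepare, run_association_analysis  # noqa: E402

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    state = prepare(PIPELINE)
    table = run_association_analysis(state)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "association_table.tsv", sep="\t", index=False,
                 float_format="%.4g")

    overall = table[table.stratum == "all"].set_index("gene")
    print("pooled correlation with the proliferation score (all samples):")
    for gene, row in overall.iterrows():
        print(f"  {gene:8s} r = {row.pooled_r:+.3f} "
              f"[{row.ci_lo:+.3f}, {row.ci_hi:+.3f}]  p = {row.p:.2e} "
              f"({row.model}, k = {row.k})")
    n_skipped = len(state.skipped)
    print(f"\nfull stratified table ({len(table)} rows) -> "
          f"{out / 'association_table.tsv'}; {n_skipped} cohort/stratum "
          "combinations skipped (logged)")


if __name__ == "__main__":
    main()
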