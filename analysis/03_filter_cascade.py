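"""Run the six-stage filtering cascade on the simulated study.

Applies sharing, control-panel and known-variant exclusion, consequence
filtering, and the score+gene stage to the default-scale synthetic study,
writes the SNV and INDEL funnels (study-table layout) to results/, and
reports whether every implanted causal variant survived to the final stage.
"""

from __future__ import annotations

from pathlib import Path

from famexome.cascade import CascadeConfig, run_cascade
from famexome.synth import SyntheticConfig, gen_family_cohorts

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = gen_family_cohorts(SyntheticConfig(seed=1))
    cfg = CascadeConfig(gene_allowlist=study.gene_allowlist)
    result = run_cascade(study.cohorts, study.control_sites, study.known_sites, cfg)

    RESULTS.mkdir(exist_ok=True)
    result.funnel_snv.to_frame().to_csv(RESULTS / "funnel_snv.tsv", sep="\t")
    result.funnel_indel.to_frame().to_csv(RESULTS / "funnel_indel.tsv", sep="\t")

    print("SNV funnel (per-family values, then summary rows):")
    print(result.funnel_snv.to_frame().to_string())
    print("\nINDEL funnel:")
    print(result.funnel_indel.to_frame().to_string())

    recovered = sum(
        study.implants[fam].key in {v.key for v in result.survivors[fam]}
        for fam in study.implants
    )
    n_survivors = sum(len(v) for v in result.survivors.values())
    print(
        f"\n{n_survivors} surviving candidate variants across "
        f"{len(result.survivors)} families; implanted causal variants "
        f"recovered in {recovered}/{len(study.implants)} families."
    )


if __name__ == "__main__":
    main()
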