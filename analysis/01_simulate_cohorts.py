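#!/usr/bin/env python
"""Generate the synthetic study inputs: GWAS summary statistics for a
continuous blood-pressure exposure and three pregnancy outcomes over
drug-target gene regions, plus per-region LD matrices.

One beta-blocker-like target (single ADRB1 region) and one calcium-channel-
blocker-like target (three pooled regions) are simulated with known true
effects chosen to match published-scale magnitudes: log-odds per mmHg of
0.13 for pre-eclampsia (OR 0.27 per 10 mmHg reduction), -0.07 for
gestational diabetes (OR 2.01), and 0.027 birthweight categories per mmHg
(-0.27 per 10 mmHg reduction).  Writes delimited sumstats, LD matrices, a
region table and the generating truth under results/synthetic_data/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from targetmr import GeneRegion, SyntheticConfig, load_gene_regions, simulate_study
from targetmr.simulate import OutcomeSpec, region_ld
from targetmr.sumstats import write_gwas_table

OUT = ROOT / "results" / "synthetic_data"

SEED = 20_240_901

#: Regions carrying simulated signal (coordinates from the packaged table).
SIGNAL_GENES = {
    "beta_blocker": ["ADRB1"],
    "calcium_channel_blocker": ["CACNA1C", "CACNB1", "CACNG1"],
}

OUTCOME_SPECS = [
    OutcomeSpec("preeclampsia", theta=0.13, outcome_type="case_control",
                case_fraction=0.034, n=141_068),
    OutcomeSpec("gdm", theta=-0.07, outcome_type="case_control",
                case_fraction=0.056, n=138_100),
    OutcomeSpec("birthweight", theta=0.027, outcome_type="continuous", n=155_202),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    packaged = {r.gene: r for regions in load_gene_regions().values() for r in regions}

    exposure = []
    outcomes = {s.name: [] for s in OUTCOME_SPECS}
    truth_out = {}
    region_rows = []
    for t_idx, (drug_class, genes) in enumerate(SIGNAL_GENES.items()):
        for g_idx, gene in enumerate(genes):
            region = packaged[gene]
            cfg = SyntheticConfig(
                seed=SEED + 100 * t_idx + g_idx,
                region=region,
                m_snps=30,
                ld_decay=0.9,
                causal_index=(5, 22),
                causal_beta=0.6,
                n_exposure=757_601,
            )
            e, outs, truth = simulate_study(cfg, OUTCOME_SPECS)
            exposure.extend(e)
            for s in OUTCOME_SPECS:
                outcomes[s.name].extend(outs[s.name])
            region_ld(cfg).write(OUT / f"ld_{gene}.tsv")
            region_rows.append((gene, drug_class, region))
            truth_out[gene] = {
                "drug_class": drug_class,
                "theta": truth["theta"],
                "causal_variant_ids": [truth["variant_ids"][i] for i in cfg.causal_indices],
                "causal_beta_mmHg": list(cfg.causal_betas),
            }
            print(f"{drug_class}/{gene}: {len(e)} variants simulated "
                  f"({sum(1 for r in e if r.pval < 5e-8)} genome-wide significant)")

    write_gwas_table(exposure, OUT / "sbp.tsv")
    for name, recs in outcomes.items():
        write_gwas_table(recs, OUT / f"{name}.tsv")
    with open(OUT / "regions.tsv", "w", newline="\n") as fh:
        fh.write("gene\tdrug_class\tchrom\tstart\tend\n")
        for gene, drug_class, r in region_rows:
            fh.write(f"{gene}\t{drug_class}\t{r.chrom}\t{r.start}\t{r.end}\n")
    with open(OUT / "truth.json", "w", newline="\n") as fh:
        json.dump({"seed": SEED, "targets": truth_out}, fh, indent=2)
        fh.write("\n")
    print(f"\nwrote exposure table ({len(exposure)} rows), "
          f"{len(outcomes)} outcome tables, {len(region_rows)} LD matrices -> {OUT}")


if __name__ == "__main__":
    main()
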