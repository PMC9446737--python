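"""Locus plots: per-region -log10(p) against position for two traits."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .instruments import GeneRegion
from .sumstats import SummaryRecord


def locus_table(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    region: GeneRegion,
) -> pd.DataFrame:
    """Underlying long-format table of -log10(p) per trait over the region."""
    rows = []
    for label, records in (("exposure", exposure), ("outcome", outcome)):
        for r in records:
            if region.contains(r.chrom, r.pos):
                rows.append(
                    {
                        "trait": label,
                        "variant_id": r.variant_id,
                        "pos": r.pos,
                        "neglog10_p": -np.log10(r.pval),
                    }
                )
    return pd.DataFrame(rows).sort_values(["trait", "pos"], ignore_index=True)


def locus_plot(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    region: GeneRegion,
    path,
    labels: tuple[str, str] = ("exposure", "outcome"),
    table_path=None,
) -> pd.DataFrame:
    """Two-panel -log10(p) scatter over the region; writes the image and,
    optionally, the underlying table.  Returns the table."""
    table = locus_table(exposure, outcome, region)
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    for ax, trait, label in zip(axes, ("exposure", "outcome"), labels):
        sub = table[table["trait"] == trait]
        ax.scatter(sub["pos"] / 1e6, sub["neglog10_p"], s=12, color="#1f4e79")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.set_title(label, fontsize=10)
        ax.axvspan(region.start / 1e6, region.end / 1e6, alpha=0.12, color="orange")
    axes[-1].set_xlabel(f"chr{region.chrom} position (Mb)")
    fig.suptitle(f"{region.gene} locus", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False, lineterminator="\n")
    return table
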