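"""Instrument selection for drug-target gene regions and instrument strength.

Variants proxying pharmacological perturbation of a target are taken from the
gene region (plus a symmetric flank, default 10 kb) at genome-wide
significance (p < 5e-8), then clumped greedily by p-value to pairwise
r² < 0.1 so the retained set is near-independent.  Strength is summarised by
the per-SNP variance explained R² = F/(N-2+F) with F = (beta/se)², the joint
R² (sum of per-SNP R²) and the joint F-statistic
F = ((n-k-1)/k) * R²/(1-R²); F > 10 is the conventional weak-instrument rule
of thumb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError
from .sumstats import SummaryRecord, _norm_chrom

GENOME_WIDE_P = 5e-8
DEFAULT_R2_THRESHOLD = 0.1
DEFAULT_FLANK = 10_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene's coordinates (1-based inclusive, GRCh37) with a flank."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene}: end < start")
        if self.flank < 0:
            raise ValueError(f"{self.gene}: flank must be non-negative")

    @property
    def window(self) -> tuple[int, int]:
        """Inclusive [start - flank, end + flank] extraction window."""
        return (self.start - self.flank, self.end + self.flank)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return _norm_chrom(chrom) == _norm_chrom(self.chrom) and lo <= pos <= hi


@dataclass
class LDMatrix:
    """Pairwise r² over an ordered set of variants (symmetric, unit diagonal)."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = tuple(str(v) for v in self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match variant_ids")
        if m and not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if m and not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if m and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-8):
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(tuple(variant_ids), self.r2[np.ix_(idx, idx)])

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))

    def write(self, path, *, delimiter: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep=delimiter, lineterminator="\n", float_format="%.6g"
        )

    @staticmethod
    def block_diagonal(blocks: Sequence["LDMatrix"]) -> "LDMatrix":
        """Combine region LD blocks assuming zero cross-block LD (regions on
        different chromosomes or far apart)."""
        ids: list[str] = []
        for b in blocks:
            ids.extend(b.variant_ids)
        m = len(ids)
        r2 = np.zeros((m, m))
        off = 0
        for b in blocks:
            k = len(b.variant_ids)
            r2[off : off + k, off : off + k] = b.r2
            off += k
        np.fill_diagonal(r2, 1.0)
        return LDMatrix(tuple(ids), r2)


@dataclass
class InstrumentSet:
    """Post-selection variants for one target with strength summaries."""

    target: str
    variants: list[SummaryRecord]
    ld: LDMatrix
    per_snp_r2: list[float]
    joint_r2: float
    f_statistic: float
    n: int
    weak: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


def extract_region(
    records: Sequence[SummaryRecord],
    region: GeneRegion,
    p_threshold: float = GENOME_WIDE_P,
) -> list[SummaryRecord]:
    """Variants inside the flanked region below the p-value threshold
    (strict inequality), ordered by position.  An empty result is valid."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    hits = [r for r in records if region.contains(r.chrom, r.pos) and r.pval < p_threshold]
    return sorted(hits, key=lambda r: r.pos)


def greedy_clump(
    candidates: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[SummaryRecord]:
    """p-value-ranked greedy clumping to pairwise r² below the threshold.

    Iteratively retains the most significant remaining candidate (ties broken
    by position, then id) and discards every remaining candidate in LD
    (r² >= threshold) with it, so the result's pairwise r² are all below the
    threshold.  Returned sorted by position.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    for c in candidates:
        if c.variant_id not in ld:
            raise KeyError(f"candidate {c.variant_id!r} absent from LD matrix")
    remaining = sorted(candidates, key=lambda r: (r.pval, r.pos, r.variant_id))
    retained: list[SummaryRecord] = []
    while remaining:
        top = remaining.pop(0)
        retained.append(top)
        remaining = [
            r for r in remaining if ld.r2_between(top.variant_id, r.variant_id) < r2_threshold
        ]
    return sorted(retained, key=lambda r: r.pos)


def per_snp_r2(beta: float, se: float, n: int) -> float:
    """Variance explained by one SNP: R² = F/(N-2+F), F = (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError("n must exceed 2")
    f = (beta / se) ** 2
    return f / (n - 2 + f)


def joint_strength(per_snp_r2_values: Sequence[float], n: int, k: int | None = None) -> tuple[float, float]:
    """Joint R² (sum of per-SNP R²) and F = ((n-k-1)/k) * R²/(1-R²)."""
    r2s = list(per_snp_r2_values)
    if k is None:
        k = len(r2s)
    if k < 1 or len(r2s) != k:
        raise ValueError("k must equal the number of per-SNP R² values and be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    joint = float(np.sum(r2s))
    if joint >= 1.0:
        raise ValueError("joint R² must be below 1")
    f = ((n - k - 1) / k) * joint / (1.0 - joint)
    return joint, f


def build_instrument_set(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    region: GeneRegion | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    target: str | None = None,
    weak_f_threshold: float = 10.0,
) -> InstrumentSet:
    """Select and summarise instruments for one target.

    ``region=None`` selects genome-wide: all significant hits are clumped
    with no positional restriction.  Raises
    :class:`~targetmr.errors.NoInstrumentsError` when nothing survives.
    """
    name = target or (region.gene if region is not None else "genome_wide")
    if region is not None:
        candidates = extract_region(records, region, p_threshold)
    else:
        if not (0.0 < p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        candidates = sorted(
            (r for r in records if r.pval < p_threshold), key=lambda r: (r.chrom, r.pos)
        )
    retained = greedy_clump(candidates, ld, r2_threshold)
    if not retained:
        raise NoInstrumentsError(f"no instruments for target {name!r}")
    n = int(max(r.n for r in retained))
    r2s = [per_snp_r2(r.beta, r.se, r.n) for r in retained]
    joint, f = joint_strength(r2s, n)
    return InstrumentSet(
        target=name,
        variants=retained,
        ld=ld.submatrix([r.variant_id for r in retained]),
        per_snp_r2=r2s,
        joint_r2=joint,
        f_statistic=f,
        n=n,
        weak=f < weak_f_threshold,
        meta={
            "p_threshold": p_threshold,
            "r2_threshold": r2_threshold,
            "n_candidates": len(candidates),
        },
    )


def load_gene_regions(path=None, flank: int = DEFAULT_FLANK) -> dict[str, list[GeneRegion]]:
    """Load a gene-region table grouped by drug class.

    With no path, the packaged default region table of beta-blocker and
    calcium-channel-blocker target genes is used.  Columns: gene,
    [drug_class,] chrom, start, end[, flank].
    """
    if path is None:
        with resources.as_file(resources.files("targetmr.data") / "gene_regions.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    out: dict[str, list[GeneRegion]] = {}
    for _, row in df.iterrows():
        region = GeneRegion(
            gene=str(row["gene"]),
            chrom=_norm_chrom(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            flank=int(row["flank"]) if "flank" in df.columns and pd.notna(row.get("flank")) else flank,
        )
        cls = str(row["drug_class"]) if "drug_class" in df.columns else "default"
        out.setdefault(cls, []).append(region)
    return out
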