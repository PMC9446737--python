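"""GWAS summary-statistics ingestion, validation and two-sample harmonization.

A summary-statistics table carries, per biallelic SNP, the marginal effect of
the effect allele on a trait (``beta``), its standard error, p-value, effect
allele frequency and sample size.  Two-sample Mendelian randomization needs
the exposure and outcome effects expressed for the *same* effect allele at
every variant; :func:`harmonize_pair` performs that alignment, resolving
swapped alleles, opposite-strand reports, and palindromic (A/T, G/C)
ambiguity via an allele-frequency window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateVariantError, SchemaError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default mapping from field name to column header in delimited input.
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval", "n")


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association statistics for one trait.

    ``beta`` is per unit of the trait (mmHg for blood pressure, log-odds for
    binary outcomes); ``pos`` is 1-based on GRCh37.  ``eaf`` may be None for
    non-palindromic variants, whose alignment is resolvable from alleles
    alone.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be single A/C/G/T bases")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: pval must lie in (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf must lie in [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """A/T or G/C variants: strand is not resolvable from alleles alone."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class TraitMeta:
    """Trait-level metadata: name, measurement type and case/control counts."""

    trait_name: str
    trait_type: str  # "continuous" | "case_control"
    n_cases: int | None = None
    n_controls: int | None = None
    unit_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if not (self.n_cases and self.n_controls and self.n_cases > 0 and self.n_controls > 0):
                raise ValueError("case_control traits require positive n_cases and n_controls")

    @property
    def case_fraction(self) -> float | None:
        if self.trait_type != "case_control":
            return None
        return self.n_cases / (self.n_cases + self.n_controls)


class HarmonizedRecord(NamedTuple):
    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None


@dataclass
class HarmonizedPair:
    """Exposure/outcome betas aligned to a common effect allele per variant."""

    records: list[HarmonizedRecord]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([r.beta_exposure for r in self.records], dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([r.se_exposure for r in self.records], dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([r.beta_outcome for r in self.records], dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([r.se_outcome for r in self.records], dtype=float)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @classmethod
    def from_arrays(
        cls,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        variant_ids: Sequence[str] | None = None,
    ) -> "HarmonizedPair":
        """Build a pair directly from aligned effect arrays (simulation use)."""
        bx = np.asarray(beta_exposure, dtype=float)
        if variant_ids is None:
            variant_ids = [f"snp{i + 1}" for i in range(bx.size)]
        recs = [
            HarmonizedRecord(str(v), float(a), float(b), float(c), float(d), None)
            for v, a, b, c, d in zip(variant_ids, bx, se_exposure, beta_outcome, se_outcome)
        ]
        return cls(records=recs)

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedPair":
        keep = set(variant_ids)
        return HarmonizedPair(
            records=[r for r in self.records if r.variant_id in keep],
            dropped=list(self.dropped),
        )


class GwasReadResult(NamedTuple):
    records: list[SummaryRecord]
    rejections: list[tuple[int, str]]  # (0-based row index in file body, reason)


def read_gwas_table(
    path,
    column_map: dict[str, str] | None = None,
    meta: TraitMeta | None = None,
    *,
    delimiter: str | None = None,
) -> GwasReadResult:
    """Read a delimited summary-statistics table into validated records.

    Tab- or comma-delimited text with a header row; gzip input is accepted
    transparently.  Rows that cannot be coerced into a valid
    :class:`SummaryRecord` (non-numeric beta/se, indel or multi-allelic
    alleles, out-of-range p or eaf, ...) are excluded and reported in
    ``rejections`` with a reason; a missing mandatory column raises
    :class:`~targetmr.errors.SchemaError` naming the column.

    ``meta`` is accepted so call sites can carry trait metadata alongside the
    table; it does not alter parsing.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)

    for fieldname in _MANDATORY:
        if cmap[fieldname] not in df.columns:
            raise SchemaError(f"missing mandatory column {cmap[fieldname]!r} (maps to {fieldname!r})")
    has_eaf = cmap["eaf"] in df.columns

    records: list[SummaryRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            eaf_raw = row_d.get(cmap["eaf"]) if has_eaf else None
            eaf = None
            if eaf_raw is not None and str(eaf_raw).strip() not in ("", "NA", "nan", "None", "."):
                eaf = float(eaf_raw)
                if math.isnan(eaf):
                    eaf = None
            rec = SummaryRecord(
                variant_id=str(row_d[cmap["variant_id"]]).strip(),
                chrom=_norm_chrom(row_d[cmap["chrom"]]),
                pos=int(float(row_d[cmap["pos"]])),
                effect_allele=str(row_d[cmap["effect_allele"]]).strip().upper(),
                other_allele=str(row_d[cmap["other_allele"]]).strip().upper(),
                beta=_require_finite(row_d[cmap["beta"]], "beta"),
                se=_require_finite(row_d[cmap["se"]], "se"),
                pval=_require_finite(row_d[cmap["pval"]], "pval"),
                n=int(float(row_d[cmap["n"]])),
                eaf=eaf,
            )
        except (TypeError, ValueError) as exc:
            rejections.append((i, str(exc)))
            continue
        records.append(rec)
    return GwasReadResult(records, rejections)


def _require_finite(value, name: str) -> float:
    x = float(value)
    if not math.isfinite(x):
        raise ValueError(f"non-finite {name}")
    return x


def _norm_chrom(value) -> str:
    c = str(value).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.lower() in ("x", "y", "mt") else c


def write_gwas_table(records: Sequence[SummaryRecord], path, *, delimiter: str = "\t") -> None:
    """Write records in the same dialect the reader consumes (fixed column
    order, POSIX newlines); round-trips all retained fields."""
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf if r.eaf is not None else "NA" for r in records],
            "beta": [repr(r.beta) for r in records],
            "se": [repr(r.se) for r in records],
            "pval": [repr(r.pval) for r in records],
            "n": [r.n for r in records],
        }
    )
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def _index_by_id(records: Sequence[SummaryRecord], label: str) -> dict[str, SummaryRecord]:
    out: dict[str, SummaryRecord] = {}
    for r in records:
        if r.variant_id in out:
            raise DuplicateVariantError(f"duplicate variant_id {r.variant_id!r} in {label} records")
        out[r.variant_id] = r
    return out


def harmonize_pair(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect allele, variant by variant.

    Retains the id intersection.  Swapped outcome alleles flip the outcome
    beta's sign (and complement its eaf); opposite-strand reports (allele
    complements) are aligned the same way.  Palindromic variants are retained
    only when both effect-allele frequencies are present, both fall outside
    ``0.5 ± palindrome_eaf_window``, and they sit on the same side of 0.5
    after alignment — otherwise they are dropped with reason
    ``"palindromic_ambiguous"``.  Irreconcilable alleles drop with
    ``"allele_mismatch"``.
    """
    w = float(palindrome_eaf_window)
    exp_by_id = _index_by_id(exposure, "exposure")
    out_by_id = _index_by_id(outcome, "outcome")

    records: list[HarmonizedRecord] = []
    dropped: list[tuple[str, str]] = []
    for vid, e in exp_by_id.items():
        o = out_by_id.get(vid)
        if o is None:
            continue  # no pair existed; not a drop
        ea, oa = e.effect_allele, e.other_allele
        pair = (o.effect_allele, o.other_allele)
        comp_pair = (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele])

        if e.is_palindromic:
            # Strand cannot be resolved from alleles; require informative,
            # concordant allele frequencies on both sides.
            if pair == (ea, oa):
                flip = False
            elif pair == (oa, ea):
                flip = True
            else:
                dropped.append((vid, "allele_mismatch"))
                continue
            eaf_o = o.eaf if not flip else (None if o.eaf is None else 1.0 - o.eaf)
            if (
                e.eaf is None
                or eaf_o is None
                or abs(e.eaf - 0.5) <= w
                or abs(eaf_o - 0.5) <= w
                or (e.eaf - 0.5) * (eaf_o - 0.5) < 0
            ):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
        else:
            if pair == (ea, oa) or comp_pair == (ea, oa):
                flip = False
            elif pair == (oa, ea) or comp_pair == (oa, ea):
                flip = True
            else:
                dropped.append((vid, "allele_mismatch"))
                continue

        beta_o = -o.beta if flip else o.beta
        records.append(
            HarmonizedRecord(vid, e.beta, e.se, beta_o, o.se, e.eaf)
        )
    return HarmonizedPair(records=records, dropped=dropped)
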