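"""Synthetic GWAS summary statistics with known ground truth.

Generates per-variant marginal effect estimates for an exposure and one or
more outcomes under a two-sample design: a sparse vector of causal effects
is propagated through an AR(1) linkage-disequilibrium correlation structure
(corr(i, j) = ld_decay^|i-j|) to marginal effects, and independent sampling
noise with covariance sigma² * C / n is added per trait.  Effects are on the
standardized-genotype scale, so the per-variant standard error is
sigma / sqrt(n) for continuous traits and 1 / sqrt(n * cf * (1 - cf)) on the
log-odds scale for case-control traits with case fraction cf.

The defaults emulate the study conditions of a blood-pressure drug-target
analysis: a large continuous exposure GWAS (n ≈ 500k–760k, trait SD in
mmHg), rarer binary pregnancy outcomes (case fractions of a few percent),
cis regions of tens of variants with strong local LD, and causal effects a
few tenths of a mmHg per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import GeneRegion, LDMatrix
from .sumstats import SummaryRecord

#: Non-palindromic allele pairs used for simulated variants (palindromic
#: A/T and G/C pairs are constructed explicitly in harmonization tests).
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"))

DEFAULT_REGION = GeneRegion("ADRB1", "10", 115_803_625, 115_806_663)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one exposure/outcome summary-statistics pair.

    ``causal_beta`` is in exposure units (mmHg per allele on the
    standardized-genotype scale); ``theta`` is the true causal effect of the
    exposure on the outcome (log-odds or outcome units per mmHg); per-variant
    direct (pleiotropic) outcome effects are drawn
    N(directional_pleiotropy, pleiotropy_sd²) and mapped through LD.
    """

    seed: int = 0
    n_exposure: int = 500_000
    n_outcome: int = 100_000
    region: GeneRegion = DEFAULT_REGION
    m_snps: int = 50
    ld_decay: float = 0.9
    causal_index: int | tuple[int, ...] = 25
    causal_beta: float | tuple[float, ...] = 0.5
    theta: float = 0.05
    pleiotropy_sd: float = 0.0
    directional_pleiotropy: float = 0.0
    outcome_type: str = "case_control"
    case_fraction: float = 0.034
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_sd: float = 19.0  # trait SD in exposure units (mmHg for SBP)
    outcome_sd: float = 1.0  # trait SD for continuous outcomes

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must lie in [0, 1)")
        for i in self.causal_indices:
            if not (0 <= i < self.m_snps):
                raise ValueError("causal indices must lie in [0, m_snps)")
        if self.outcome_type not in ("continuous", "case_control"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "case_control" and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")

    @property
    def causal_indices(self) -> tuple[int, ...]:
        ci = self.causal_index
        return (ci,) if isinstance(ci, (int, np.integer)) else tuple(ci)

    @property
    def causal_betas(self) -> tuple[float, ...]:
        cb = self.causal_beta
        if isinstance(cb, (int, float, np.floating)):
            return (float(cb),) * len(self.causal_indices)
        if len(cb) != len(self.causal_indices):
            raise ValueError("causal_beta list must match causal_index list")
        return tuple(float(b) for b in cb)

    @property
    def se_exposure(self) -> float:
        return self.exposure_sd / np.sqrt(self.n_exposure)

    @property
    def se_outcome(self) -> float:
        if self.outcome_type == "case_control":
            cf = self.case_fraction
            return 1.0 / np.sqrt(self.n_outcome * cf * (1.0 - cf))
        return self.outcome_sd / np.sqrt(self.n_outcome)


def _ar1_corr(m: int, decay: float) -> np.ndarray:
    idx = np.arange(m)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld(m_snps: int, ld_decay: float, seed: int | None = None) -> LDMatrix:
    """AR(1) LD: corr(i, j) = ld_decay^|i-j|, r² its square.

    Deterministic given (m_snps, ld_decay); the seed parameter is accepted
    for interface symmetry with the stochastic generators.
    """
    if not (0.0 <= ld_decay < 1.0):
        raise ValueError("ld_decay must lie in [0, 1)")
    corr = _ar1_corr(m_snps, ld_decay)
    ids = tuple(_variant_ids(m_snps))
    return LDMatrix(ids, corr**2)


def _variant_ids(m: int) -> list[str]:
    return [f"rs{900000 + i}" for i in range(m)]


def _region_variant_ids(region: GeneRegion, pos: np.ndarray) -> list[str]:
    # chrom:pos identifiers are unique across regions, so multi-region
    # studies can pool instruments without id collisions
    return [f"{region.chrom}:{int(p)}" for p in pos]


def region_ld(config: SyntheticConfig) -> LDMatrix:
    """The r² matrix of a simulated region, keyed by the same chrom:pos
    variant ids :func:`simulate_pair` and friends emit for ``config``."""
    pos = _positions(config.region, config.m_snps)
    ids = _region_variant_ids(config.region, pos)
    corr = _ar1_corr(config.m_snps, config.ld_decay)
    return LDMatrix(tuple(ids), corr**2)


def _positions(region: GeneRegion, m: int) -> np.ndarray:
    lo, hi = region.start, region.end
    if hi - lo + 1 >= m:
        pos = np.linspace(lo, hi, m).round().astype(int)
        # enforce strict monotonicity after rounding
        for i in range(1, m):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        return pos
    return lo + np.arange(m)


def _records(
    ids: Sequence[str],
    region: GeneRegion,
    pos: np.ndarray,
    alleles: Sequence[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: float,
    n: int,
) -> list[SummaryRecord]:
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return [
        SummaryRecord(
            variant_id=str(ids[j]),
            chrom=region.chrom,
            pos=int(pos[j]),
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(beta[j]),
            se=float(se),
            pval=float(pval[j]),
            n=int(n),
            eaf=float(eaf[j]),
        )
        for j in range(len(ids))
    ]


def _chol(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))


def simulate_pair(config: SyntheticConfig) -> tuple[list[SummaryRecord], list[SummaryRecord], dict]:
    """One exposure/outcome pair of summary-statistics with ground truth.

    Exposure marginal effects are C @ gamma for the sparse causal vector
    gamma; outcome marginals are theta times the exposure marginals plus
    LD-mapped direct effects.  Noise draws for the two traits are
    independent (two-sample design).  Deterministic under ``seed``.
    """
    exposure, outcomes, truth = simulate_study(config, None)
    return exposure, outcomes["outcome"], truth


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome trait layered on a shared exposure draw."""

    name: str
    theta: float
    outcome_type: str = "case_control"
    n: int = 100_000
    case_fraction: float = 0.05
    outcome_sd: float = 1.0
    pleiotropy_sd: float = 0.0
    directional_pleiotropy: float = 0.0


def simulate_study(
    config: SyntheticConfig,
    outcomes: Sequence[OutcomeSpec] | Sequence[tuple] | None = None,
) -> tuple[list[SummaryRecord], dict[str, list[SummaryRecord]], dict]:
    """Simulate one exposure GWAS and any number of outcome GWASs over the
    same region, sharing the exposure draw (as in a study analysing several
    outcomes against one exposure).

    With ``outcomes=None`` (or the sentinel used by :func:`simulate_pair`) a
    single outcome is built from the config's own outcome fields.
    """
    m = config.m_snps
    rng = np.random.default_rng(config.seed)
    corr = _ar1_corr(m, config.ld_decay)
    chol = _chol(corr)
    pos = _positions(config.region, m)
    ids = _region_variant_ids(config.region, pos)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    alleles = [_ALLELE_PAIRS[i] for i in allele_idx]
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    gamma = np.zeros(m)
    for i, b in zip(config.causal_indices, config.causal_betas):
        gamma[i] = b
    bx_true = corr @ gamma
    se_x = config.se_exposure
    bx_hat = bx_true + se_x * (chol @ rng.standard_normal(m))
    exposure = _records(ids, config.region, pos, alleles, eaf, bx_hat, se_x, config.n_exposure)

    if outcomes is None or (len(outcomes) == 1 and not isinstance(outcomes[0], OutcomeSpec)):
        specs = [
            OutcomeSpec(
                name=outcomes[0][0] if outcomes else "outcome",
                theta=config.theta,
                outcome_type=config.outcome_type,
                n=config.n_outcome,
                case_fraction=config.case_fraction,
                outcome_sd=config.outcome_sd,
                pleiotropy_sd=config.pleiotropy_sd,
                directional_pleiotropy=config.directional_pleiotropy,
            )
        ]
    else:
        specs = list(outcomes)

    out_records: dict[str, list[SummaryRecord]] = {}
    truth: dict = {
        "theta": {},
        "beta_exposure_true": bx_true,
        "se_exposure": se_x,
        "gamma": gamma,
        "causal_index": config.causal_indices,
        "eta": {},
        "beta_outcome_true": {},
        "se_outcome": {},
        "variant_ids": ids,
    }
    for spec in specs:
        eta = np.zeros(m)
        if spec.pleiotropy_sd > 0 or spec.directional_pleiotropy != 0:
            eta = rng.normal(spec.directional_pleiotropy, spec.pleiotropy_sd, size=m)
        by_true = spec.theta * bx_true + corr @ eta
        cfg_out = replace(
            config,
            outcome_type=spec.outcome_type,
            n_outcome=spec.n,
            case_fraction=spec.case_fraction if spec.outcome_type == "case_control" else 0.5,
            outcome_sd=spec.outcome_sd,
        )
        se_y = cfg_out.se_outcome
        by_hat = by_true + se_y * (chol @ rng.standard_normal(m))
        out_records[spec.name] = _records(
            ids, config.region, pos, alleles, eaf, by_hat, se_y, spec.n
        )
        truth["theta"][spec.name] = spec.theta
        truth["eta"][spec.name] = eta
        truth["beta_outcome_true"][spec.name] = by_true
        truth["se_outcome"][spec.name] = se_y
    return exposure, out_records, truth


def simulate_coloc_scenario(
    shared: bool,
    config: SyntheticConfig,
    z_causal: float = 8.0,
) -> tuple[list[SummaryRecord], list[SummaryRecord], dict]:
    """A region pair contrasting shared versus distinct causal variants.

    ``shared=True`` drives both traits from one causal variant;
    ``shared=False`` uses two causal variants whose mutual r² must be below
    0.05 (indices from ``config.causal_index`` when it lists two, else
    placed at m/5 and 4m/5).  Causal effect sizes are set so the causal
    variant's expected marginal z-score is ``z_causal`` for each trait;
    ``z_causal=0`` gives a null region for both traits.
    """
    m = config.m_snps
    rng = np.random.default_rng(config.seed)
    corr = _ar1_corr(m, config.ld_decay)
    chol = _chol(corr)
    pos = _positions(config.region, m)
    ids = _region_variant_ids(config.region, pos)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    alleles = [_ALLELE_PAIRS[i] for i in allele_idx]
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    ci = config.causal_indices
    if shared:
        i1 = i2 = ci[0]
    elif len(ci) >= 2:
        i1, i2 = ci[0], ci[1]
    else:
        i1, i2 = m // 5, (4 * m) // 5
    if not shared and corr[i1, i2] ** 2 >= 0.05:
        raise ValueError("distinct-causal scenario requires causal r^2 < 0.05")

    se_x = config.se_exposure
    se_y = config.se_outcome
    bx_true = corr[:, i1] * (z_causal * se_x)
    by_true = corr[:, i2] * (z_causal * se_y)
    bx_hat = bx_true + se_x * (chol @ rng.standard_normal(m))
    by_hat = by_true + se_y * (chol @ rng.standard_normal(m))

    exposure = _records(ids, config.region, pos, alleles, eaf, bx_hat, se_x, config.n_exposure)
    outcome = _records(ids, config.region, pos, alleles, eaf, by_hat, se_y, config.n_outcome)
    truth = {
        "shared": shared,
        "causal_index_exposure": i1,
        "causal_index_outcome": i2,
        "z_causal": z_causal,
        "beta_exposure_true": bx_true,
        "beta_outcome_true": by_true,
        "se_exposure": se_x,
        "se_outcome": se_y,
    }
    return exposure, outcome, truth
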