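"""Single-causal-variant Bayesian colocalization via approximate Bayes factors.

For two traits measured over the same region, the method asks whether the
association signals are driven by one shared causal variant (hypothesis H4)
or by distinct variants (H3), assuming at most one causal variant per trait:

  H0 no causal variant for either trait; H1/H2 a causal variant for trait
  1/2 only; H3 distinct causal variants; H4 a shared causal variant.

Per-variant evidence is the Wakefield approximate Bayes factor computed from
the estimated effect, its standard error and a normal effect-size prior
(SD 0.15 for continuous traits, 0.2 on the log-odds scale for case-control
traits).  Hypothesis posteriors combine the per-variant Bayes factors with
per-variant priors p1, p2 (single-trait causal) and p12 (shared causal); all
arithmetic is in log space with stable log-sum-exp so extreme z-scores do
not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import NoOverlapError
from .instruments import GeneRegion
from .sumstats import SummaryRecord, TraitMeta, harmonize_pair

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocConfig:
    """Priors for colocalization.

    p1/p2: per-variant prior probability of being causal for trait 1/2 only
    (default 1e-4); p12: prior of being causal for both (default 1e-5);
    prior_sd_quant / prior_sd_cc: effect-size prior SDs for continuous and
    case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("per-variant priors must sum below 1")
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ValueError("prior SDs must be positive")

    def prior_sd(self, trait_type: str) -> float:
        return self.prior_sd_cc if trait_type == "case_control" else self.prior_sd_quant


@dataclass
class ColocResult:
    """Posterior probabilities of H0..H4 with the per-variant log-ABFs."""

    pp: np.ndarray  # length 5, sums to 1
    log_abf_1: np.ndarray
    log_abf_2: np.ndarray
    n_snps: int
    config: ColocConfig
    variant_ids: list[str] = field(default_factory=list)

    @property
    def pp_by_hypothesis(self) -> dict[str, float]:
        return dict(zip(HYPOTHESES, map(float, self.pp)))

    @property
    def shared_variant(self) -> bool:
        """Decision flag: posterior for a shared causal variant above 0.5."""
        return float(self.pp[4]) > 0.5


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor of association versus the null.

    With z = beta/se, V = se² and prior variance W = prior_sd²,
    log ABF = 0.5*log(1 - r) + r*z²/2 where r = W/(V + W).  Depends on the
    data only through z and the ratio r, so jointly rescaling betas, SEs and
    the prior SD leaves it unchanged.  Vectorized over arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (se**2 + prior_sd**2)
    out = 0.5 * np.log1p(-r) + 0.5 * r * z2
    return out if out.ndim else float(out)


def coloc_posteriors(
    abf1: Sequence[float],
    abf2: Sequence[float],
    config: ColocConfig | None = None,
    variant_ids: Sequence[str] | None = None,
) -> ColocResult:
    """Combine per-variant log-ABFs for two traits into hypothesis posteriors.

    In log space: the H1/H2 terms sum the single-trait Bayes factors, the H4
    term sums the per-variant products, and the H3 term is the off-diagonal
    double sum, computed by subtracting the diagonal from the full product
    (factoring out the largest term for stability).  Posteriors are the
    softmax of the prior-weighted terms against the H0 baseline.
    """
    cfg = config or ColocConfig()
    a1 = np.asarray(abf1, dtype=float)
    a2 = np.asarray(abf2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("abf1 and abf2 must be equal-length 1-D sequences")
    n = a1.size
    if n < 1:
        raise ValueError("at least one variant is required")

    l1 = logsumexp(a1)
    l2 = logsumexp(a2)
    l4 = logsumexp(a1 + a2)
    if n == 1:
        l3 = -np.inf
    else:
        # sum_{i != j} exp(a1_i + a2_j) = exp(l1 + l2) - exp(l4)
        d = l4 - (l1 + l2)
        l3 = l1 + l2 + np.log1p(-np.exp(d)) if d < 0 else -np.inf

    terms = np.array(
        [
            0.0,
            l1 + np.log(cfg.p1),
            l2 + np.log(cfg.p2),
            l3 + np.log(cfg.p1) + np.log(cfg.p2),
            l4 + np.log(cfg.p12),
        ]
    )
    pp = np.exp(terms - logsumexp(terms))
    pp /= pp.sum()
    return ColocResult(
        pp=pp,
        log_abf_1=a1,
        log_abf_2=a2,
        n_snps=n,
        config=cfg,
        variant_ids=list(variant_ids) if variant_ids is not None else [],
    )


def coloc_region(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    meta: tuple[TraitMeta, TraitMeta],
    region: GeneRegion,
    config: ColocConfig | None = None,
) -> ColocResult:
    """Colocalize two traits over a gene region.

    All region variants present for both traits enter (no significance
    filter); the pair is harmonized to a common effect allele and per-variant
    log-ABFs use the trait-appropriate effect-size prior SD.
    """
    cfg = config or ColocConfig()
    exp_region = [r for r in exposure if region.contains(r.chrom, r.pos)]
    out_region = [r for r in outcome if region.contains(r.chrom, r.pos)]
    pair = harmonize_pair(exp_region, out_region)
    if pair.k == 0:
        raise NoOverlapError(f"no common variants in region {region.gene}")
    sd1 = cfg.prior_sd(meta[0].trait_type)
    sd2 = cfg.prior_sd(meta[1].trait_type)
    abf1 = wakefield_log_abf(pair.beta_exposure, pair.se_exposure, sd1)
    abf2 = wakefield_log_abf(pair.beta_outcome, pair.se_outcome, sd2)
    return coloc_posteriors(abf1, abf2, cfg, variant_ids=pair.variant_ids)


def prior_sensitivity(
    abf1: Sequence[float],
    abf2: Sequence[float],
    config: ColocConfig,
    p12_grid: Sequence[float],
) -> list[tuple[float, ColocResult]]:
    """Recompute posteriors over a grid of shared-causal priors p12.

    ABFs are reused unchanged (they do not depend on p12); the posterior for
    H4 is non-decreasing in p12.
    """
    for g in p12_grid:
        if not (0.0 < g <= min(config.p1, config.p2)):
            raise ValueError("p12 grid values must lie in (0, min(p1, p2)]")
    return [
        (float(g), coloc_posteriors(abf1, abf2, replace(config, p12=float(g))))
        for g in p12_grid
    ]


def coloc_enumeration_oracle(
    abf1: Sequence[float], abf2: Sequence[float], config: ColocConfig | None = None
) -> np.ndarray:
    """Posteriors by exhaustive enumeration of per-variant causal
    configurations — an independent brute-force check, O((n+1)²), intended
    for small n.

    Configuration (i, j) places the causal variant for trait 1 at i and for
    trait 2 at j (0 = none).  Prior weight: 1 for (0,0), p1 or p2 for a
    single causal variant, p12 on the diagonal i = j, p1*p2 off-diagonal;
    likelihood ratio ABF1_i * ABF2_j.
    """
    cfg = config or ColocConfig()
    a1 = np.concatenate([[0.0], np.asarray(abf1, dtype=float)])
    a2 = np.concatenate([[0.0], np.asarray(abf2, dtype=float)])
    n = a1.size - 1
    mass = np.zeros(5)
    for i in range(n + 1):
        for j in range(n + 1):
            logw = a1[i] + a2[j]
            if i == 0 and j == 0:
                h = 0
            elif j == 0:
                h, logw = 1, logw + np.log(cfg.p1)
            elif i == 0:
                h, logw = 2, logw + np.log(cfg.p2)
            elif i == j:
                h, logw = 4, logw + np.log(cfg.p12)
            else:
                h, logw = 3, logw + np.log(cfg.p1) + np.log(cfg.p2)
            mass[h] += np.exp(logw - np.max(a1) - np.max(a2))
    return mass / mass.sum()
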