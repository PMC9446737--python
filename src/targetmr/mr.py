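"""Two-sample Mendelian randomization estimators and effect scaling.

The causal effect of a genetically-proxied exposure on an outcome is
estimated from harmonized per-variant effects.  With a single instrument the
Wald ratio applies; with several, the inverse-variance weighted (IVW)
estimator — weighted regression of outcome betas on exposure betas through
the origin — with a multiplicative dispersion scale floored at 1 so the
standard error never drops below the fixed-effect value ("underdispersion
correction").  Robustness to pleiotropy is probed with MR-Egger (intercept =
directional pleiotropy test), the weighted median (consistent when >= 50% of
weight is valid), and MR-PRESSO (simulation-based global heterogeneity test
with per-variant outlier removal).

Estimates are rescaled for reporting — e.g. per 10 mmHg *reduction* in
systolic blood pressure (scale factor -10) — and exponentiated to odds
ratios for binary outcomes; multiple outcomes are handled with a Bonferroni
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .sumstats import HarmonizedPair

#: 95% normal quantile used for all reported confidence intervals.
Z95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """One estimator's output on the outcome-per-exposure-unit scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    phi: float | None = None  # multiplicative dispersion (>= 1 where floored)
    q_stat: float | None = None  # Cochran-type heterogeneity statistic

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be > 0")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class PressoResult:
    global_p: float
    outliers: list[str]
    corrected: MREstimate
    raw: MREstimate
    outlier_pvals: dict[str, float]


@dataclass(frozen=True)
class ScaledReport:
    """An estimate rescaled for presentation (default: per 10-unit reduction)."""

    estimate: MREstimate
    scale_factor: float
    trait_type: str
    effect_label: str
    value: float  # OR for binary outcomes, scaled beta for continuous
    ci: tuple[float, float]
    pval: float
    significant: bool
    alpha_bonferroni: float


def _normal_p(beta: float, se: float) -> float:
    if beta == 0.0:
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate: beta_outcome / beta_exposure, with
    the first-order delta-method SE se_outcome / |beta_exposure|."""
    if pair.k != 1:
        raise ValueError("wald_ratio requires exactly one harmonized variant")
    r = pair.records[0]
    if r.beta_exposure == 0.0:
        raise ValueError("wald_ratio undefined for beta_exposure = 0")
    beta = r.beta_outcome / r.beta_exposure
    se = r.se_outcome / abs(r.beta_exposure)
    return MREstimate(
        method="wald",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta, se),
        k=1,
    )


def ivw(pair: HarmonizedPair, underdispersion_floor: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate with underdispersion-corrected SE.

    Weighted regression of outcome on exposure betas through the origin with
    weights 1/se_outcome²; the dispersion scale phi = Q/(k-1) multiplies the
    squared SE and is floored at 1 (the fixed-effect SE) when
    ``underdispersion_floor`` is set.
    """
    k = pair.k
    if k < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio for a single variant")
    bx, by, sy = pair.beta_exposure, pair.beta_outcome, pair.se_outcome
    w = 1.0 / sy**2
    s_xx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / s_xx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    phi = q / (k - 1)
    if underdispersion_floor:
        phi = max(1.0, phi)
    se = float(np.sqrt(phi / s_xx))
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta, se),
        k=k,
        phi=phi,
        q_stat=q,
    )


def estimate_effect(pair: HarmonizedPair, underdispersion_floor: bool = True) -> MREstimate:
    """Primary estimator dispatch: Wald ratio when only one variant is
    available, IVW otherwise."""
    if pair.k == 1:
        return wald_ratio(pair)
    return ivw(pair, underdispersion_floor=underdispersion_floor)


def mr_egger(pair: HarmonizedPair, t_reference: bool = True) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Each record is oriented so beta_exposure >= 0 (flipping both betas
    together, an allele relabelling); outcome betas are regressed on exposure
    betas with an intercept, weights 1/se_outcome².  The intercept estimates
    directional pleiotropy and its p-value is the pleiotropy test.  SEs carry
    a dispersion scale phi = Q/(k-2) floored at 1; p-values use a t reference
    with k-2 df (configurable to normal).
    """
    k = pair.k
    if k < 3:
        raise ValueError("egger requires >=3 instruments")
    sign = np.where(pair.beta_exposure < 0, -1.0, 1.0)
    bx = sign * pair.beta_exposure
    by = sign * pair.beta_outcome
    w = 1.0 / pair.se_outcome**2

    sw = float(np.sum(w))
    sx = float(np.sum(w * bx))
    sxx = float(np.sum(w * bx * bx))
    sy = float(np.sum(w * by))
    sxy = float(np.sum(w * bx * by))
    det = sw * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate design: exposure betas carry no spread")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det

    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - 2))
    var_slope = phi * sw / det
    var_int = phi * sxx / det
    df = k - 2

    def _p(b: float, s: float) -> float:
        if b == 0.0:
            return 1.0
        if t_reference:
            return float(2.0 * stats.t.sf(abs(b) / s, df))
        return _normal_p(b, s)

    def _mk(method: str, b: float, s: float) -> MREstimate:
        s = float(np.sqrt(s))
        return MREstimate(
            method=method,
            beta=float(b),
            se=s,
            ci_low=float(b) - Z95 * s,
            ci_high=float(b) + Z95 * s,
            pval=_p(b, s),
            k=k,
            phi=phi,
            q_stat=q,
        )

    return _mk("egger_slope", slope, var_slope), _mk("egger_intercept", intercept, var_int)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median(pair: HarmonizedPair, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Ratios are weighted by the inverse variance of the first-order
    delta-method ratio SE; the estimate interpolates the cumulative weight
    at 0.5.  The SE comes from a parametric bootstrap: exposure and outcome
    betas are redrawn from their normal sampling distributions ``n_boot``
    times under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    keep = [r for r in pair.records if r.beta_exposure != 0.0]
    if len(keep) < len(pair.records):
        warnings.warn("excluding variant(s) with beta_exposure = 0 from weighted median")
    k = len(keep)
    if k < 3:
        raise ValueError("weighted median requires >=3 usable instruments")
    bx = np.array([r.beta_exposure for r in keep])
    sx = np.array([r.se_exposure for r in keep])
    by = np.array([r.beta_outcome for r in keep])
    sy = np.array([r.se_outcome for r in keep])

    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    w = 1.0 / se_ratio**2
    beta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_b[i]
        ok = bxi != 0.0
        ri = by_b[i, ok] / bxi[ok]
        wi = (np.abs(bxi[ok]) / sy[ok]) ** 2
        boot[i] = _weighted_median(ri, wi)
    se = float(np.std(boot, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_normal_p(beta, se),
        k=k,
    )


def mr_presso(
    pair: HarmonizedPair,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_p: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier detection, corrected IVW.

    The observed statistic is the weighted residual sum of squares of each
    outcome beta around its leave-one-out IVW prediction.  Its null
    distribution comes from ``n_sim`` parametric draws of the outcome betas
    around those predictions (exposure betas held fixed), with the
    leave-one-out fit recomputed per draw so observed and simulated
    statistics are exchangeable.  Per-variant outlier p-values are the tail
    fractions of each variant's contribution, Bonferroni-compared with
    ``outlier_p / k``; the corrected estimate is IVW on the non-outliers.
    """
    k = pair.k
    if k < 4:
        raise ValueError("mr_presso requires >=4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    bx, by, sy = pair.beta_exposure, pair.beta_outcome, pair.se_outcome
    ids = pair.variant_ids
    w = 1.0 / sy**2

    s_xx = np.sum(w * bx**2)
    s_xy = np.sum(w * bx * by)
    beta_loo = (s_xy - w * bx * by) / (s_xx - w * bx**2)  # per-variant leave-one-out IVW
    t_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(t_obs))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    s_xy_sim = by_sim @ (w * bx)
    beta_loo_sim = (s_xy_sim[:, None] - w * bx * by_sim) / (s_xx - w * bx**2)
    t_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = t_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_out = (1 + np.sum(t_sim >= t_obs, axis=0)) / (1 + n_sim)
    outlier_pvals = {ids[i]: float(p_out[i]) for i in range(k)}
    flagged = [ids[i] for i in range(k) if p_out[i] < outlier_p / k]

    raw = ivw(pair)
    keep = [v for v in ids if v not in flagged]
    if not keep:
        raise RuntimeError("no variants remain after outlier removal")
    corrected_pair = pair.subset(keep)
    corrected = estimate_effect(corrected_pair)
    corrected = replace(corrected, method="presso_corrected")
    raw = replace(raw, method="presso_raw")
    return PressoResult(
        global_p=global_p,
        outliers=flagged,
        corrected=corrected,
        raw=raw,
        outlier_pvals=outlier_pvals,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tested outcomes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def scale_report(
    est: MREstimate,
    scale_factor: float,
    trait_type: str,
    alpha_bonferroni: float = 0.05,
    exposure_label: str = "10 mmHg SBP reduction",
) -> ScaledReport:
    """Rescale an estimate for presentation.

    ``scale_factor`` multiplies the per-unit beta (default convention: -10,
    i.e. per 10-unit *reduction* in the exposure, which flips the effect
    direction).  Case-control outcomes are exponentiated to an odds ratio
    with CI endpoints exp(scaled beta -/+ 1.96 * scaled se); the p-value is
    scale-invariant.
    """
    if scale_factor == 0:
        raise ValueError("scale_factor must be nonzero")
    if trait_type not in ("continuous", "case_control"):
        raise ValueError(f"unknown trait_type {trait_type!r}")
    sb = scale_factor * est.beta
    ss = abs(scale_factor) * est.se
    if trait_type == "case_control":
        lo, hi = float(np.exp(sb - Z95 * ss)), float(np.exp(sb + Z95 * ss))
        value = float(np.exp(sb))
        label = f"OR per {exposure_label}"
    else:
        lo, hi = sb - Z95 * ss, sb + Z95 * ss
        value = sb
        label = f"beta per {exposure_label}"
    return ScaledReport(
        estimate=est,
        scale_factor=scale_factor,
        trait_type=trait_type,
        effect_label=label,
        value=value,
        ci=(min(lo, hi), max(lo, hi)),
        pval=est.pval,
        significant=est.pval < alpha_bonferroni,
        alpha_bonferroni=alpha_bonferroni,
    )
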