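"""Full-analysis orchestration: config → instruments → MR → coloc bundle.

One run covers one or more drug-target definitions (a set of gene regions
pooled into a single instrument set, or genome-wide selection) against one
or more outcome GWASs.  Per outcome it harmonizes, applies the primary
estimator (Wald ratio when a single instrument survives, IVW otherwise),
adds robust estimators where the instrument count permits (Egger and
weighted median need k >= 3, MR-PRESSO k >= 4 — skipped with a logged
reason otherwise), rescales the effect for reporting with a Bonferroni flag
at alpha / (number of outcomes), and optionally colocalizes each region.
Bundles are plain JSON-serializable dicts with a provenance block, so
identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ColocConfig, coloc_region, prior_sensitivity, wakefield_log_abf
from .errors import NoInstrumentsError
from .instruments import (
    DEFAULT_R2_THRESHOLD,
    GENOME_WIDE_P,
    GeneRegion,
    InstrumentSet,
    LDMatrix,
    build_instrument_set,
    extract_region,
    greedy_clump,
    joint_strength,
    per_snp_r2,
)
from .mr import (
    bonferroni_threshold,
    estimate_effect,
    mr_egger,
    mr_presso,
    scale_report,
    weighted_median,
)
from .sumstats import SummaryRecord, TraitMeta, harmonize_pair, read_gwas_table

log = logging.getLogger("targetmr")


@dataclass
class OutcomeInput:
    name: str
    records: list[SummaryRecord]
    meta: TraitMeta


@dataclass
class RunConfig:
    """Everything one analysis run needs, with the field defaults of the
    study design (p < 5e-8, r² < 0.1, ±10 kb flank, effects per 10-unit
    reduction, alpha 0.05 Bonferroni-split across outcomes)."""

    exposure: list[SummaryRecord]
    exposure_meta: TraitMeta
    outcomes: list[OutcomeInput]
    targets: dict[str, list[GeneRegion]]  # target name -> pooled regions
    ld: dict[str, LDMatrix]  # gene name (or "genome_wide") -> LD
    genome_wide: bool = False
    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    scale_factor: float = -10.0
    alpha: float = 0.05
    run_coloc: bool = True
    coloc_config: ColocConfig = field(default_factory=ColocConfig)
    p12_grid: tuple[float, ...] = ()
    palindrome_eaf_window: float = 0.08
    seed: int = 0
    weighted_median_boot: int = 1000
    presso_sim: int = 1000

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("at least one outcome is required")
        for regions in self.targets.values():
            for region in regions:
                if region.gene not in self.ld:
                    raise ValueError(f"no LD source for region {region.gene}")

    @property
    def alpha_bonferroni(self) -> float:
        return bonferroni_threshold(self.alpha, len(self.outcomes))


def _estimate_to_dict(est) -> dict:
    return {k: v for k, v in dataclasses.asdict(est).items()}


def select_instruments(config: RunConfig, target: str) -> InstrumentSet:
    """Pooled instrument selection for one target.

    Candidates from every region of the target are clumped jointly against a
    block-diagonal LD matrix (cross-region LD taken as zero — regions sit on
    different chromosomes or far apart), so the pooled set obeys the same
    pairwise r² threshold as each per-region set.
    """
    if target == "genome_wide":
        return build_instrument_set(
            config.exposure,
            config.ld["genome_wide"],
            region=None,
            p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold,
            target=target,
        )
    regions = config.targets[target]
    candidates: list[SummaryRecord] = []
    blocks: list[LDMatrix] = []
    for region in regions:
        hits = extract_region(config.exposure, region, config.p_threshold)
        log.info("%s/%s: %d significant region variants", target, region.gene, len(hits))
        candidates.extend(hits)
        blocks.append(config.ld[region.gene])
    pooled_ld = LDMatrix.block_diagonal(blocks) if len(blocks) > 1 else blocks[0]
    retained = greedy_clump(candidates, pooled_ld, config.r2_threshold)
    if not retained:
        raise NoInstrumentsError(f"no instruments for target {target!r}")
    n = int(max(r.n for r in retained))
    r2s = [per_snp_r2(r.beta, r.se, r.n) for r in retained]
    joint, f = joint_strength(r2s, n)
    return InstrumentSet(
        target=target,
        variants=retained,
        ld=pooled_ld.submatrix([r.variant_id for r in retained]),
        per_snp_r2=r2s,
        joint_r2=joint,
        f_statistic=f,
        n=n,
        weak=f < 10.0,
        meta={"n_candidates": len(candidates), "n_regions": len(regions)},
    )


def run_target(config: RunConfig, target: str) -> dict:
    """Run the full analysis for one target; returns a JSON-ready bundle."""
    instruments = select_instruments(config, target)
    bundle: dict = {
        "target": target,
        "instruments": {
            "k": instruments.k,
            "variants": instruments.variant_ids,
            "joint_r2": instruments.joint_r2,
            "f_statistic": instruments.f_statistic,
            "n": instruments.n,
            "weak": instruments.weak,
            "per_snp_r2": instruments.per_snp_r2,
        },
        "outcomes": [],
        "coloc": [],
    }
    for outcome in config.outcomes:
        pair = harmonize_pair(
            instruments.variants, outcome.records, config.palindrome_eaf_window
        )
        entry: dict = {
            "outcome": outcome.name,
            "k_used": pair.k,
            "dropped": list(map(list, pair.dropped)),
            "estimates": {},
            "skipped": {},
        }
        if pair.k == 0:
            entry["skipped"]["all"] = "no harmonized variants"
            bundle["outcomes"].append(entry)
            continue
        primary = estimate_effect(pair)
        report = scale_report(
            primary,
            config.scale_factor,
            outcome.meta.trait_type,
            config.alpha_bonferroni,
        )
        entry["estimates"][primary.method] = _estimate_to_dict(primary)
        entry["scaled"] = {
            "effect_label": report.effect_label,
            "value": report.value,
            "ci": list(report.ci),
            "pval": report.pval,
            "significant": report.significant,
            "alpha_bonferroni": report.alpha_bonferroni,
        }
        if pair.k >= 3:
            slope, intercept = mr_egger(pair)
            entry["estimates"]["egger_slope"] = _estimate_to_dict(slope)
            entry["estimates"]["egger_intercept"] = _estimate_to_dict(intercept)
            wm = weighted_median(pair, n_boot=config.weighted_median_boot, seed=config.seed)
            entry["estimates"]["weighted_median"] = _estimate_to_dict(wm)
        else:
            reason = f"k={pair.k} < 3"
            entry["skipped"]["egger"] = reason
            entry["skipped"]["weighted_median"] = reason
            log.info("%s/%s: skipping egger/weighted_median (%s)", target, outcome.name, reason)
        if pair.k >= 4:
            presso = mr_presso(pair, n_sim=config.presso_sim, seed=config.seed)
            entry["estimates"]["presso_raw"] = _estimate_to_dict(presso.raw)
            entry["estimates"]["presso_corrected"] = _estimate_to_dict(presso.corrected)
            entry["presso"] = {"global_p": presso.global_p, "outliers": presso.outliers}
        else:
            entry["skipped"]["presso"] = f"k={pair.k} < 4"
            log.info("%s/%s: skipping MR-PRESSO (k=%d < 4)", target, outcome.name, pair.k)
        bundle["outcomes"].append(entry)

    if config.run_coloc and target != "genome_wide":
        for region in config.targets[target]:
            for outcome in config.outcomes:
                try:
                    res = coloc_region(
                        config.exposure,
                        outcome.records,
                        (config.exposure_meta, outcome.meta),
                        region,
                        config.coloc_config,
                    )
                except Exception as exc:  # no overlap etc.: recorded, run continues
                    bundle["coloc"].append(
                        {"gene": region.gene, "outcome": outcome.name, "error": str(exc)}
                    )
                    continue
                entry = {
                    "gene": region.gene,
                    "outcome": outcome.name,
                    "n_snps": res.n_snps,
                    "pp": res.pp_by_hypothesis,
                    "shared_variant": res.shared_variant,
                }
                if config.p12_grid:
                    sens = prior_sensitivity(
                        res.log_abf_1, res.log_abf_2, config.coloc_config, config.p12_grid
                    )
                    entry["prior_sensitivity"] = [
                        {"p12": p12, "pp": r.pp_by_hypothesis} for p12, r in sens
                    ]
                bundle["coloc"].append(entry)
    bundle["provenance"] = _provenance(config)
    return bundle


def run(config: RunConfig) -> dict:
    """Run every configured target (plus genome-wide selection if enabled)."""
    targets = list(config.targets)
    if config.genome_wide:
        targets.append("genome_wide")
    bundles = {}
    for target in targets:
        try:
            bundles[target] = run_target(config, target)
        except NoInstrumentsError as exc:
            log.warning("%s", exc)
            bundles[target] = {
                "target": target,
                "error": "no instruments",
                "detail": str(exc),
                "provenance": _provenance(config),
            }
    return bundles


def _provenance(config: RunConfig) -> dict:
    digest_src = json.dumps(
        {
            "p_threshold": config.p_threshold,
            "r2_threshold": config.r2_threshold,
            "scale_factor": config.scale_factor,
            "alpha": config.alpha,
            "outcomes": [o.name for o in config.outcomes],
            "targets": {
                t: [(r.gene, r.chrom, r.start, r.end, r.flank) for r in rs]
                for t, rs in config.targets.items()
            },
            "coloc": dataclasses.asdict(config.coloc_config),
            "p12_grid": list(config.p12_grid),
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return {
        "software": f"targetmr {__version__}",
        "config_hash": hashlib.sha256(digest_src.encode()).hexdigest()[:16],
        "seed": config.seed,
    }


def results_table(bundles: dict) -> pd.DataFrame:
    """Flatten run bundles into one row per (target, outcome, method)."""
    rows = []
    for target, bundle in bundles.items():
        if "error" in bundle:
            rows.append({"target": target, "outcome": "", "method": "", "note": bundle["error"]})
            continue
        for entry in bundle["outcomes"]:
            for method, est in entry.get("estimates", {}).items():
                row = {
                    "target": target,
                    "outcome": entry["outcome"],
                    "method": method,
                    "k": est["k"],
                    "beta": est["beta"],
                    "se": est["se"],
                    "ci_low": est["ci_low"],
                    "ci_high": est["ci_high"],
                    "pval": est["pval"],
                }
                if method in ("ivw", "wald") and "scaled" in entry:
                    row["scaled_value"] = entry["scaled"]["value"]
                    row["scaled_ci_low"] = entry["scaled"]["ci"][0]
                    row["scaled_ci_high"] = entry["scaled"]["ci"][1]
                    row["effect_label"] = entry["scaled"]["effect_label"]
                    row["significant"] = entry["scaled"]["significant"]
                rows.append(row)
    return pd.DataFrame(rows)


def coloc_table(bundles: dict) -> pd.DataFrame:
    rows = []
    for target, bundle in bundles.items():
        for entry in bundle.get("coloc", []):
            if "error" in entry:
                rows.append({"target": target, "gene": entry["gene"],
                             "outcome": entry["outcome"], "note": entry["error"]})
                continue
            row = {"target": target, "gene": entry["gene"], "outcome": entry["outcome"],
                   "n_snps": entry["n_snps"], "shared_variant": entry["shared_variant"]}
            row.update({h: p for h, p in entry["pp"].items()})
            rows.append(row)
    return pd.DataFrame(rows)


def write_bundles(bundles: dict, out_json, results_tsv=None, coloc_tsv=None) -> None:
    with open(out_json, "w", newline="\n") as fh:
        json.dump(bundles, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    if results_tsv is not None:
        results_table(bundles).to_csv(results_tsv, sep="\t", index=False, lineterminator="\n")
    if coloc_tsv is not None:
        df = coloc_table(bundles)
        if not df.empty:
            df.to_csv(coloc_tsv, sep="\t", index=False, lineterminator="\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_run_config_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML file of file paths and options.

    Expected keys: exposure {path, trait_name, trait_type, [column_map]},
    outcomes [{name, path, trait_type, n_cases, n_controls}], targets
    {name: regions_path or list}, ld {gene: path}, plus any scalar RunConfig
    field (p_threshold, r2_threshold, scale_factor, alpha, seed, ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    exp_meta = TraitMeta(
        trait_name=raw["exposure"].get("trait_name", "exposure"),
        trait_type=raw["exposure"].get("trait_type", "continuous"),
        n_cases=raw["exposure"].get("n_cases"),
        n_controls=raw["exposure"].get("n_controls"),
        unit_label=raw["exposure"].get("unit_label", ""),
    )
    exposure, _ = read_gwas_table(
        raw["exposure"]["path"], raw["exposure"].get("column_map"), exp_meta
    )
    outcomes = []
    for o in raw["outcomes"]:
        meta = TraitMeta(
            trait_name=o["name"],
            trait_type=o.get("trait_type", "case_control"),
            n_cases=o.get("n_cases"),
            n_controls=o.get("n_controls"),
            unit_label=o.get("unit_label", ""),
        )
        recs, _ = read_gwas_table(o["path"], o.get("column_map"), meta)
        outcomes.append(OutcomeInput(o["name"], recs, meta))
    targets: dict[str, list[GeneRegion]] = {}
    for name, spec in raw["targets"].items():
        regions = [
            GeneRegion(r["gene"], str(r["chrom"]), int(r["start"]), int(r["end"]),
                       int(r.get("flank", 10_000)))
            for r in spec
        ]
        targets[name] = regions
    ld = {gene: LDMatrix.read(p) for gene, p in raw["ld"].items()}
    scalars = {
        k: raw[k]
        for k in (
            "genome_wide", "p_threshold", "r2_threshold", "scale_factor", "alpha",
            "run_coloc", "palindrome_eaf_window", "seed",
            "weighted_median_boot", "presso_sim",
        )
        if k in raw
    }
    if "p12_grid" in raw:
        scalars["p12_grid"] = tuple(float(x) for x in raw["p12_grid"])
    if "coloc" in raw:
        scalars["coloc_config"] = ColocConfig(**raw["coloc"])
    return RunConfig(
        exposure=exposure,
        exposure_meta=exp_meta,
        outcomes=outcomes,
        targets=targets,
        ld=ld,
        **scalars,
    )
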