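"""End-to-end analysis orchestration and report generation.

Runs the full survey-style analysis over a directory of per-locus FASTA
alignments plus a population map: pooled and per-population diversity
tables, LD pair tables and per-locus summaries, LD-decay fits with
threshold-crossing distances, composite-likelihood recombination
estimates, Hudson F_ST, and the resampling experiment.  Outputs are TSV
files plus a JSON manifest carrying the configuration, its hash, seeds
and package version, so identical configurations produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ldcore import LDPairSet, build_ld_pairs, prune_linked_snps
from .lddecay import fit_dprime_decay, fit_hill_weir
from .popstats import global_fst, summarize_locus, summarize_population, summary_table
from .resample import joint_draws, latitude_trend_table, resample_statistics
from .rho import build_lookup, estimate_rho, rho_over_theta
from .seqio import (
    LocusAlignment,
    PopulationMap,
    classify_sites,
    read_locus_alignment,
    read_population_map,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "load_inputs"]


@dataclass
class RunConfig:
    """Validated configuration for a full analysis run."""

    input_dir: str
    output_dir: str
    missing_policy: str = "complete_deletion"
    ld_missing_policy: str = "pairwise_available"
    correction_scope: str = "global"
    decay_threshold: float = 0.2
    map_scales_cm_per_mb: tuple[float, ...] = (1.0,)
    prune_r2: float = 0.2
    resample_k: int = 8
    resample_B: int = 100
    dense_population_min_n: int = 11
    rho_grid_max_per_kb: float = 100.0
    rho_grid_points: int = 15
    rho_lookup_sims: int = 300
    rho_lookup_max_n: int = 100  # larger samples are projected onto the table
    rho_lookup_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.missing_policy not in ("complete_deletion", "pairwise_available"):
            raise ValueError(f"unknown missing policy {self.missing_policy}")
        if self.correction_scope not in ("global", "per_locus"):
            raise ValueError(f"unknown correction scope {self.correction_scope}")
        if self.resample_k < 2 or self.resample_B < 1:
            raise ValueError("resample parameters out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "map_scales_cm_per_mb" in data:
            data["map_scales_cm_per_mb"] = tuple(data["map_scales_cm_per_mb"])
        return cls(**data)

    def config_hash(self) -> str:
        # output_dir does not influence results, so it stays out of the hash
        data = dataclasses.asdict(self)
        data.pop("output_dir")
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(input_dir: str | Path) -> tuple[list[LocusAlignment], PopulationMap]:
    """Read every per-locus FASTA and the population map from a directory."""
    input_dir = Path(input_dir)
    fastas = sorted(input_dir.glob("*.fasta")) + sorted(input_dir.glob("*.fa"))
    if not fastas:
        raise FileNotFoundError(f"no FASTA alignments in {input_dir}")
    alignments = [read_locus_alignment(p) for p in fastas]
    popmap = read_population_map(input_dir / "popmap.tsv")
    return alignments, popmap


def _write(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _display_diversity(df: pd.DataFrame) -> pd.DataFrame:
    """Survey-style display table: theta and pi scaled x10^3, 2 sig figs."""
    out = df.copy()
    for col, new in (("theta_w", "theta_w_e3"), ("pi", "pi_e3")):
        out[new] = (out[col] * 1e3).map(
            lambda v: float(f"{v:.2g}") if np.isfinite(v) else np.nan
        )
    keep = [
        "locus_id",
        "population_id",
        "n",
        "L",
        "S",
        "singletons",
        "H",
        "Hd",
        "theta_w_e3",
        "pi_e3",
        "tajimas_d",
        "d_significant",
    ]
    return out[[c for c in keep if c in out.columns]]


def run_full_analysis(
    config: RunConfig,
    alignments: list[LocusAlignment] | None = None,
    popmap: PopulationMap | None = None,
) -> dict:
    """Run every stage and write the report bundle.

    Returns the bundle as a dict of DataFrames plus the manifest.  Any
    stage failure is recorded in the manifest and re-raised after partial
    outputs are flushed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}
    if alignments is None or popmap is None:
        alignments, popmap = load_inputs(config.input_dir)
    site_tables = {
        aln.locus_id: classify_sites(aln, config.missing_policy) for aln in alignments
    }
    dense_pops = [
        pop
        for pop in popmap.population_ids
        if len(popmap.individuals_in(pop)) >= config.dense_population_min_n
    ]
    try:
        # --- diversity -------------------------------------------------------
        pooled = [summarize_locus(a, site_tables[a.locus_id]) for a in alignments]
        per_pop = [
            summarize_population(a, popmap, pop, config.missing_policy)
            for a in alignments
            for pop in dense_pops
        ]
        div = summary_table(pooled + per_pop)
        bundle["diversity"] = div
        _write(div, outdir / "diversity_full.tsv", chash)
        _write(_display_diversity(div), outdir / "diversity_display.tsv", chash)
        manifest["stages"]["diversity"] = "ok"

        # --- LD pairs --------------------------------------------------------
        ld_tables = {
            aln.locus_id: site_tables[aln.locus_id].with_policy(
                config.ld_missing_policy
            )
            for aln in alignments
        }
        pair_set = build_ld_pairs(
            alignments,
            [ld_tables[a.locus_id] for a in alignments],
            correction_scope=config.correction_scope,
        )
        bundle["ld_pairs"] = pair_set
        _write(pair_set.to_frame(), outdir / "ld_pairs.tsv", chash)
        _write(pair_set.locus_summary(), outdir / "ld_locus_summary.tsv", chash)
        retained, removed = prune_linked_snps(pair_set, config.prune_r2)
        _write(
            pd.DataFrame(sorted(removed), columns=["locus_id", "position"]),
            outdir / "pruned_snps.tsv",
            chash,
        )
        manifest["stages"]["ld"] = "ok"
        manifest["ld"] = {
            "n_pairs": pair_set.n_pairs,
            "n_significant": pair_set.n_significant,
            "mean_r2": pair_set.mean_r2,
            "n_pruned": len(removed),
            "correction_scope": pair_set.correction_scope,
        }

        # --- decay fits ------------------------------------------------------
        decay_rows = []
        scopes: list[tuple[str, LDPairSet, float]] = []
        mean_n = float(np.mean([a.n for a in alignments]))
        scopes.append(("pooled", pair_set, mean_n))
        for pop in dense_pops:
            sub_alns = [a.subset(popmap.individuals_in(pop)) for a in alignments]
            sub_alns = [a for a in sub_alns if a.n >= 4]
            sub_sites = [
                classify_sites(a, config.ld_missing_policy) for a in sub_alns
            ]
            pop_pairs = build_ld_pairs(
                sub_alns, sub_sites, correction_scope=config.correction_scope
            )
            if pop_pairs.n_pairs >= 5:
                scopes.append(
                    (pop, pop_pairs, float(np.mean([a.n for a in sub_alns])))
                )
        for scope_name, pairs, n_used in scopes:
            if pairs.n_pairs < 5:
                continue
            hw = fit_hill_weir(pairs, n_used)
            decay_rows.append(
                {
                    "scope": scope_name,
                    "model": hw.model,
                    "parameter": hw.fitted_param,
                    "n_used": hw.n_used,
                    "map_scale_cm_per_mb": np.nan,
                    "n_pairs": hw.n_pairs,
                    "crossing_bp": hw.crossing_bp(config.decay_threshold),
                    "mean_r2": pairs.mean_r2,
                }
            )
            for scale in config.map_scales_cm_per_mb:
                dp = fit_dprime_decay(pairs, scale)
                decay_rows.append(
                    {
                        "scope": scope_name,
                        "model": dp.model,
                        "parameter": dp.fitted_param,
                        "n_used": np.nan,
                        "map_scale_cm_per_mb": scale,
                        "n_pairs": dp.n_pairs,
                        "crossing_bp": dp.crossing_bp(config.decay_threshold),
                        "mean_r2": pairs.mean_r2,
                    }
                )
        decay = pd.DataFrame(decay_rows)
        bundle["decay"] = decay
        _write(decay, outdir / "ld_decay.tsv", chash)
        manifest["stages"]["decay"] = "ok"

        # --- recombination ---------------------------------------------------
        if config.rho_lookup_path:
            from .rho import read_ldhat_lookup

            lookup = read_ldhat_lookup(config.rho_lookup_path)
            lookups = {lookup.n: lookup}
        else:
            lookups = {}
        from .rho import log_grid

        table_grid = log_grid(config.rho_grid_points, config.rho_grid_max_per_kb)
        cand_grid = np.linspace(
            0.0, config.rho_grid_max_per_kb, 2 * config.rho_grid_points + 1
        )
        rho_rows = []
        for aln in alignments:
            sites = ld_tables[aln.locus_id]
            n_key = min(aln.n, config.rho_lookup_max_n)
            if n_key not in lookups:
                lookups[n_key] = build_lookup(
                    n=n_key,
                    rho_grid=table_grid,
                    n_sims_per_cell=config.rho_lookup_sims,
                    seed=config.seed + 7919,
                )
            est = estimate_rho(aln, sites, lookups[n_key], cand_grid)
            pooled_row = next(s for s in pooled if s.locus_id == aln.locus_id)
            rho_rows.append(
                {
                    "locus_id": aln.locus_id,
                    "rho_per_kb": est.rho_per_kb,
                    "rho_locus": est.rho_locus,
                    "rho_per_site": est.rho_per_site,
                    "rho_over_theta": rho_over_theta(est, pooled_row.theta_w),
                    "flat_likelihood": est.flat_likelihood_flag,
                    "n_pairs": est.n_pairs,
                    "computed": est.computed,
                }
            )
        rho_df = pd.DataFrame(rho_rows)
        bundle["rho"] = rho_df
        _write(rho_df, outdir / "rho.tsv", chash)
        manifest["stages"]["rho"] = "ok"

        # --- F_ST ------------------------------------------------------------
        fst_rows = []
        for aln in alignments:
            try:
                res = global_fst(aln, popmap)
                fst_rows.append(
                    {
                        "locus_id": res.locus_id,
                        "fst": res.fst,
                        "n_populations": res.n_populations,
                        "within_diversity": res.within_diversity,
                        "between_diversity": res.between_diversity,
                    }
                )
            except ValueError as exc:
                logger.warning("F_ST skipped for %s: %s", aln.locus_id, exc)
        fst_df = pd.DataFrame(fst_rows)
        bundle["fst"] = fst_df
        _write(fst_df, outdir / "fst.tsv", chash)
        manifest["stages"]["fst"] = "ok"

        # --- resampling ------------------------------------------------------
        rs_rows = []
        rs_summaries = []
        for pop in dense_pops:
            draws = joint_draws(
                popmap, pop, config.resample_k, config.resample_B, config.seed
            )
            for aln in alignments:
                rs = resample_statistics(
                    aln, popmap, pop, k=config.resample_k, B=config.resample_B,
                    seed=config.seed, draws=draws,
                )
                rs_summaries.append(rs)
                rs_rows.append(rs.as_row())
        rs_df = pd.DataFrame(rs_rows)
        bundle["resample"] = rs_df
        _write(rs_df, outdir / "resample.tsv", chash)
        trend = latitude_trend_table(alignments, popmap, rs_summaries)
        bundle["latitude_trend"] = trend
        _write(trend, outdir / "latitude_trend.tsv", chash)
        manifest["stages"]["resample"] = "ok"
    except Exception as exc:
        manifest["stages"]["error"] = repr(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return bundle
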