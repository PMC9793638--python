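"""Replicate orchestration: burn-in, scenario replicates, estimation, reports.

:func:`run_pipeline` reproduces the shape of the study's comparison tables for
one configured scenario: per-estimator mean F, variance of F, correlation with
F_IBD and ΔID (averaged over replicates), power to detect inbreeding
depression, min/max of individual coefficients, and bootstrap/paired-t
comparisons of each estimator's ΔID with the F_IBD-based one.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import depression, estimators
from .breeding import SchemeConfig, run_scenario
from .io import RunConfig, config_hash
from .sim_core import burn_in, load_population, save_population

__all__ = ["run_pipeline", "replicate_tables", "get_ancestral"]

logger = logging.getLogger("inbredsim")


def get_ancestral(config: RunConfig):
    """Burn in the large initial population, using the cache when enabled."""
    genome, effects = config.genome_and_effects()
    key = None
    if config.cache_dir:
        key = Path(config.cache_dir) / (
            f"ancestral_{config_hash(config)[:8]}_"
            f"{config.ancestral_n}x{config.burn_in_generations}_{config.seed}.npz"
        )
        if key.exists():
            logger.info("loading cached ancestral population %s", key)
            return load_population(key)
    seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    state = burn_in(genome, config.ancestral_n, config.burn_in_generations,
                    effects, rng=np.random.default_rng(seed))
    if key is not None:
        key.parent.mkdir(parents=True, exist_ok=True)
        save_population(key, state)
    return state


def replicate_tables(result, maf_thresholds=(), roh_params=None) -> pd.DataFrame:
    """Per-individual F table of one replicate, all measures and provenances."""
    x = result.genotypes
    roh = None
    if roh_params is not None:
        roh = {
            "chrom": result.marker_chrom,
            "pos": result.marker_pos,
            "genome_length_bp": result.line.genome.total_length_bp,
            "params": roh_params,
        }
    book = result.line.book
    table = estimators.f_table(
        x,
        p_base=result.p_base,
        tracer=result.line.T,
        pedigree=(book.ids, book.sires, book.dams, result.line.ids),
        roh=roh,
    )
    for thr in maf_thresholds:
        cur = estimators.segregating(x)
        xc = x[:, cur]
        p_cur = estimators.allele_frequencies(xc).p
        keep = estimators.apply_maf_filter(p_cur, thr)
        for m in estimators.METHODS:
            table[f"{m}_current_maf{thr:g}"] = estimators.compute_freq_F(
                xc[:, keep], p_cur[keep], m)
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured scenario end to end and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ancestral = get_ancestral(config)
    scheme = SchemeConfig(
        scheme=config.scheme, n=config.n, t=config.t,
        natural_selection=config.natural_selection,
        tracer_spacing_bp=config.tracer_spacing_bp,
    )
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replicates + 1)[1:]
    summaries = []
    manifest = []
    roh_params = config.roh_params if config.roh else None
    for i, seed in enumerate(rep_seeds):
        rng = np.random.default_rng(seed)
        result = run_scenario(scheme, ancestral, rng)
        table = replicate_tables(result, config.maf_thresholds, roh_params)
        summaries.append(depression.summarize_replicate(table, result.fitness))
        manifest.append({
            "replicate": i,
            "seed_entropy": int(np.asarray(seed.entropy).ravel()[0]) if seed.entropy is not None else -1,
            "spawn_key": "/".join(map(str, seed.spawn_key)),
            "n_markers": int(result.genotypes.shape[1]),
            "base_h2": result.base_h2,
        })
        if (i + 1) % max(1, config.replicates // 10) == 0:
            logger.info("replicate %d/%d done", i + 1, config.replicates)
    agg = depression.aggregate_replicates(
        summaries, rng=np.random.SeedSequence((config.seed, 0xB007)).generate_state(1)[0])

    chash = config_hash(config)
    summary = agg["summary"].copy()
    summary.insert(0, "config_hash", chash)
    summary.insert(1, "master_seed", config.seed)
    summary.to_csv(outdir / "summary.csv")
    agg["power"].rename("power_pct").to_csv(outdir / "power.csv")
    summary[["min", "max"]].to_csv(outdir / "minmax.csv")
    if "delta_id_vs_ibd" in agg:
        agg["delta_id_vs_ibd"].to_csv(outdir / "delta_id_vs_ibd.csv")
    pd.DataFrame(manifest).to_csv(outdir / "replicate_manifest.csv", index=False)
    agg["config_hash"] = chash
    return agg
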