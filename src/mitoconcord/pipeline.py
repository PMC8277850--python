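"""End-to-end orchestration: simulate -> filter -> stats -> ancestry ->
association -> sweep -> cline -> spatial -> mito.

Each stage reads only the outputs of earlier stages, uses a seed derived
from the master seed by a fixed per-stage offset, and records its
parameters and outputs in a manifest.  The stage set is toggleable; the
result object carries the structured outputs plus a ``signatures`` summary
of the qualitative mitonuclear-selection signature (block F_ST peak,
association hit inside the block, pi depletion and r2 elevation with
disjoint bootstrap CIs, positive beta cline CI, significant site-level
mitonuclear and climate partial Mantel associations).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import ancestry, cline, mito_genome, mitoassoc, popgen, simdata, spatial, sweep
from .simdata import (BLOCK_END, BLOCK_START, CHR5, FLANK_END, FLANK_START,
                      SimConfig, SimResult, simulate_dataset)
from .variant_io import FilterSpec, apply_variant_filters

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (documented counter scheme)
STAGE_SEED_OFFSETS = {
    "simulate": 0, "sweep": 101, "spatial": 202, "ld": 303,
}

DEFAULT_STAGES = ("simulate", "filter", "popgen", "ancestry", "mitoassoc",
                  "sweep", "cline", "spatial", "mito")


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles, parameters and the master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = DEFAULT_STAGES
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    panel_threshold: float = 0.6
    h_source: str = "panel"   # "panel" (off-block markers) or "pca" (EV1 min-max)
    k_axes: int = 3
    assoc_cutoff: float = 1e-6
    window: int = 1000
    boot_iters: int = 10_000
    n_perm: int = 10_000
    max_ld_pairs: int = 2000
    seed: int = 0
    outdir: str | None = None

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


@dataclass
class PipelineResult:
    config: RunConfig
    sim: SimResult | None = None
    filtered: object = None
    filter_counts: dict | None = None
    fst_parental: popgen.FstResult | None = None
    pca: popgen.PCAResult | None = None
    panel: ancestry.MarkerPanel | None = None
    triangle: ancestry.TriangleScores | None = None
    theta_block: np.ndarray | None = None
    mitonuclear_site: pd.Series | None = None
    scan: mitoassoc.AssocScan | None = None
    pi_contrast: sweep.BlockContrast | None = None
    ld_contrast: sweep.BlockContrast | None = None
    cline_fit: cline.ClineFit | None = None
    cline_labels: list[str] | None = None
    mantel_mito: spatial.MantelResult | None = None
    mantel_climate: spatial.MantelResult | None = None
    climate_pcs: spatial.ClimatePCA | None = None
    rank_tests: dict | None = None
    mito_clades: dict[str, int] | None = None
    mito_fixed: tuple | None = None
    signatures: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in dependency order; returns all results.

    Stage failures abort with the stage name; the manifest accumulated so
    far is flushed to ``<outdir>/manifest.json`` when an output directory
    is configured.
    """
    res = PipelineResult(config=config)
    manifest: dict = {"seed": config.seed, "stages": {}}
    res.manifest = manifest

    def record(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    try:
        for stage in config.stages:
            t0 = time.time()
            if stage == "simulate":
                sim_cfg = SimConfig(**{**asdict_shallow(config.sim),
                                       "seed": config.stage_seed("simulate")})
                res.sim = simulate_dataset(sim_cfg)
                if config.outdir:
                    paths = simdata.write_dataset(res.sim, config.outdir)
                    record(stage, t0, outputs={k: _checksum(p) for k, p in paths.items()},
                           s_mismatch=sim_cfg.s_mismatch)
                else:
                    record(stage, t0, s_mismatch=sim_cfg.s_mismatch)
            elif stage == "filter":
                res.filtered, res.filter_counts = apply_variant_filters(
                    res.sim.genotypes, config.filter_spec)
                record(stage, t0, counts=res.filter_counts)
            elif stage == "popgen":
                _stage_popgen(res)
                record(stage, t0, weighted_fst=res.fst_parental.weighted)
            elif stage == "ancestry":
                _stage_ancestry(res)
                record(stage, t0, panel_size=int(res.panel.site_idx.size))
            elif stage == "mitoassoc":
                _stage_mitoassoc(res)
                record(stage, t0, lam=res.scan.lam,
                       n_hits=int(np.nansum(res.scan.significant)))
            elif stage == "sweep":
                _stage_sweep(res)
                record(stage, t0, pi_disjoint=res.pi_contrast.disjoint,
                       ld_disjoint=res.ld_contrast.disjoint)
            elif stage == "cline":
                _stage_cline(res)
                record(stage, t0, alpha=res.cline_fit.alpha, beta=res.cline_fit.beta)
            elif stage == "spatial":
                _stage_spatial(res)
                record(stage, t0, mantel_mito_p=res.mantel_mito.p,
                       mantel_climate_p=res.mantel_climate.p)
            elif stage == "mito":
                _stage_mito(res)
                record(stage, t0, n_fixed=len(res.mito_fixed[0]))
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        if config.outdir:
            _flush_manifest(manifest, config.outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    res.signatures = _signatures(res)
    manifest["signatures"] = {k: bool(v) for k, v in res.signatures.items()}
    if config.outdir:
        _flush_manifest(manifest, config.outdir)
    return res


def asdict_shallow(cfg: SimConfig) -> dict:
    d = dict(cfg.__dict__)
    return d


def _flush_manifest(manifest: dict, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _groups(res: PipelineResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = res.sim.samples["group"].to_numpy()
    return g == "parentA", g == "parentB", g == "admixed"


def _stage_popgen(res: PipelineResult) -> None:
    gm = res.filtered
    ga, gb, _ = _groups(res)
    res.fst_parental = popgen.wc_fst_scan(gm.dosage[ga], gm.dosage[gb],
                                          pops=("parentA", "parentB"))
    res.pca = popgen.genotype_pca(gm.dosage, k=10, orient_groups=(ga, gb))


def _stage_ancestry(res: PipelineResult) -> None:
    gm = res.filtered
    ga, gb, _ = _groups(res)
    freq_a = np.nansum(gm.dosage[ga], axis=0) / (2 * np.isfinite(gm.dosage[ga]).sum(axis=0))
    freq_b = np.nansum(gm.dosage[gb], axis=0) / (2 * np.isfinite(gm.dosage[gb]).sum(axis=0))
    res.panel = ancestry.select_informative_markers(
        res.fst_parental, gm.chrom, gm.pos, freq_a, freq_b,
        threshold=res.config.panel_threshold)
    res.triangle = ancestry.triangle_scores(gm.dosage, res.panel)
    block = ancestry.BlockSpec(CHR5, BLOCK_START, BLOCK_END)
    res.theta_block, _ = ancestry.block_ancestry(
        gm.dosage, gm.chrom, gm.pos, block, panel=res.panel)
    mt = res.sim.samples["mt_clade"].to_numpy(dtype=float)
    _, res.mitonuclear_site = ancestry.mitonuclear_ancestry(
        mt, res.theta_block, site=res.sim.samples["site"].to_numpy())


def _stage_mitoassoc(res: PipelineResult) -> None:
    gm = res.filtered
    _, _, adm = _groups(res)
    mt = res.sim.samples["mt_clade"].to_numpy(dtype=float)[adm]
    raw = mitoassoc.structure_adjusted_scan(
        gm.dosage[adm], gm.chrom, gm.pos, mt, k_axes=res.config.k_axes)
    res.scan = mitoassoc.genomic_control(raw, cutoff=res.config.assoc_cutoff)


def _focal_deme(res: PipelineResult) -> str:
    """Admixed site with the clearest mtDNA majority (observable choice)."""
    tab = res.sim.samples
    adm = tab[tab["group"] == "admixed"]
    skew = (adm.groupby("site")["mt_clade"].mean() - 0.5).abs()
    return skew.sort_values(ascending=False, kind="stable").index[0]


def _stage_sweep(res: PipelineResult) -> None:
    cfg = res.config
    gm_all = res.sim.all_sites
    tab = res.sim.samples
    block = ancestry.BlockSpec(CHR5, BLOCK_START, BLOCK_END)
    rng = np.random.default_rng(cfg.stage_seed("sweep"))

    focal = _focal_deme(res)
    focal_idx = np.where(tab["site"].to_numpy() == focal)[0]
    wins = popgen.pi_windows(gm_all.dosage, gm_all.chrom, gm_all.pos,
                             window=cfg.window, sample_idx=focal_idx)
    vb, vc = sweep.region_values(block, windows=wins,
                                 flank=(FLANK_START, FLANK_END), comparison="flank")
    res.pi_contrast = sweep.bootstrap_block_contrast(
        vb, vc, statistic="pi", iters=cfg.boot_iters, seed=rng)

    gm = res.filtered
    adm = tab["group"].to_numpy() == "admixed"
    on5 = (gm.chrom == CHR5) & (gm.pos >= FLANK_START) & (gm.pos <= FLANK_END)
    ld = popgen.ld_r2_matrix(gm.dosage[adm], gm.chrom, gm.pos,
                             site_idx=np.where(on5)[0],
                             max_pairs=cfg.max_ld_pairs,
                             rng=np.random.default_rng(cfg.stage_seed("ld")))
    lb, lc = sweep.region_values(block, ld=ld,
                                 flank=(FLANK_START, FLANK_END), comparison="flank")
    res.ld_contrast = sweep.bootstrap_block_contrast(
        lb, lc, statistic="r2", iters=cfg.boot_iters, seed=rng)


def _stage_cline(res: PipelineResult) -> None:
    ga, gb, _ = _groups(res)
    if res.config.h_source == "pca":
        h = ancestry.hybrid_index_from_axis(res.pca.eigenvectors[:, 0],
                                            group_a=ga, group_b=gb)
    else:
        # genome-wide index from panel markers outside the focal block, so
        # the index is not partly the block ancestry it is regressed against
        p = res.panel
        off = ~((p.chrom == CHR5) & (p.pos >= BLOCK_START) & (p.pos <= BLOCK_END))
        sub = ancestry.MarkerPanel(p.site_idx[off], p.chrom[off], p.pos[off],
                                   p.b_is_alt[off], p.threshold)
        h = ancestry.triangle_scores(res.filtered.dosage, sub).ancestry
    res.cline_fit = cline.fit_cline(res.theta_block, h,
                                    cluster=res.sim.samples["site"].to_numpy())
    res.cline_labels = cline.interpret_cline(res.cline_fit)


def _stage_spatial(res: PipelineResult) -> None:
    cfg = res.config
    tab = res.sim.samples
    sites = tab.groupby("site", sort=True).agg(
        lat=("lat", "first"), lon=("lon", "first"))
    order = list(sites.index)
    geo = spatial.geographic_distance_matrix(sites["lat"].to_numpy(),
                                             sites["lon"].to_numpy())
    mt_site = tab.groupby("site")["mt_clade"].mean().reindex(order)
    th = pd.Series(res.theta_block, index=tab.index)
    th_site = th.groupby(tab["site"]).mean().reindex(order)
    mn_site = res.mitonuclear_site.reindex(order)

    rng = np.random.default_rng(cfg.stage_seed("spatial"))
    A = spatial.value_difference_matrix(mt_site.to_numpy())
    B = spatial.value_difference_matrix(th_site.to_numpy())
    res.mantel_mito = spatial.partial_mantel_test(A, B, geo, n_perm=cfg.n_perm,
                                                  seed=rng)

    climate = res.sim.climate.reindex(order)
    res.climate_pcs = spatial.climate_pca(climate)
    pc1 = res.climate_pcs.scores[:, 0]
    C1 = spatial.value_difference_matrix(pc1)
    MN = spatial.value_difference_matrix(mn_site.to_numpy())
    res.mantel_climate = spatial.partial_mantel_test(MN, C1, geo,
                                                     n_perm=cfg.n_perm, seed=rng)

    grp = tab.groupby("site")["group"].first().reindex(order)
    vals = {g: pc1[grp.to_numpy() == g] for g in pd.unique(grp)}
    vals = {g: v for g, v in vals.items() if len(v) >= 2}
    res.rank_tests = spatial.rank_group_tests(vals) if len(vals) >= 2 else None


def _stage_mito(res: PipelineResult) -> None:
    sim = res.sim
    groups = dict(zip(sim.samples["sample"], sim.samples["group"]))
    aln = mito_genome.HaplotypeAlignment(
        sequences=list(sim.mt_sequences), labels=list(sim.mt_labels),
        groups=[groups[l] for l in sim.mt_labels])
    net = mito_genome.build_msn(aln)
    ref = sim.samples.loc[sim.samples["group"] == "parentA", "sample"].iloc[0]
    res.mito_clades = mito_genome.assign_clades(net, reference_label=ref)
    res.mito_fixed = mito_genome.fixed_differences(aln, "parentA", "parentB")


def _signatures(res: PipelineResult) -> dict:
    """Qualitative mitonuclear-selection signature checks."""
    sig: dict = {}
    if res.fst_parental is not None and res.sim is not None:
        block_idx = np.array(res.sim.truth.block_locus_idx)
        # map truth (pre-filter) indices onto the filtered matrix by position
        gm = res.filtered
        pre = res.sim.genotypes
        block_pos = set(zip(pre.chrom[block_idx], pre.pos[block_idx]))
        mask = np.array([(c, p) in block_pos for c, p in zip(gm.chrom, gm.pos)])
        if mask.any():
            sig["fst_block_peak"] = res.fst_parental.weighted_subset(mask) > 0.6
        else:
            sig["fst_block_peak"] = False
        if res.scan is not None:
            hits = np.nan_to_num(res.scan.significant, nan=0).astype(bool)
            sig["assoc_hit_in_block"] = bool((hits & mask).any())
    if res.pi_contrast is not None:
        sig["pi_depletion"] = (res.pi_contrast.disjoint
                               and res.pi_contrast.direction == "depletion")
    if res.ld_contrast is not None:
        sig["ld_elevation"] = (res.ld_contrast.disjoint
                               and res.ld_contrast.direction == "elevation")
    if res.cline_fit is not None:
        sig["beta_positive"] = res.cline_fit.ci_beta[0] > 0
    if res.mantel_mito is not None:
        sig["mantel_mito_significant"] = res.mantel_mito.p < 0.05
    if res.mantel_climate is not None:
        sig["mantel_climate_significant"] = res.mantel_climate.p < 0.05
    return sig
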