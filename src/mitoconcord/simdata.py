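"""Synthetic admixture-scenario generator with ground truth.

Emulates the statistical structure of a two-species hybrid zone: two
parental populations with shallow genome-wide differentiation (background
F_ST ~ 0.02 via Balding-Nichols draws) punctuated by a few near-fixed
"islands" of divergence, one of which is a fully linked candidate block;
divergent maternally inherited mtDNA clades; admixed demes formed by
initial mixing followed by Wright-Fisher random mating with drift,
migration, and optional viability selection against mitonuclear mismatch
(fitness (1 - s)^m where m is the dosage of candidate-block alleles
mismatched to the individual's mtDNA clade); and a site-level climate
gradient (temperature tracks latitude, precipitation tracks coastal
distance) yielding two dominant climate PCs.

The genome is desk-scaled: chr1-chr4 carry unlinked background and island
loci; chr5 spans 300 kb with the candidate block at 100,001-160,000 and a
flanking super-region at 50,001-250,000, with invariant sites appended so
all-sites diversity estimators are exercised.  Ground truth (per-individual
ancestry, island locus indices, block interval, selection regime) is
recorded for parameter-recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, obj_array, write_vcf

__all__ = [
    "DemeConfig",
    "SimConfig",
    "TruthRecord",
    "SimResult",
    "simulate_parental_frequencies",
    "simulate_admixed_cohort",
    "attach_climate_gradient",
    "simulate_dataset",
    "write_dataset",
]

CHR5 = "chr5"
CHR5_LENGTH = 300_000
BLOCK_START, BLOCK_END = 100_001, 160_000
FLANK_START, FLANK_END = 50_001, 250_000


@dataclass
class DemeConfig:
    site: str
    n: int
    init_frac_a: float       # initial fraction of parental-A founders
    lat: float
    lon: float
    mt_clade1_freq: float | None = None  # default 1 - init_frac_a


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions emulated.

    Cohort sizes mirror the field design (tens of individuals per parental
    group split over several sites, seven admixed demes along the contact
    front with founding parental-A fractions grading from 0.8 to 0.2);
    the number of post-contact random-mating generations and the mismatch
    selection coefficient are the scenario knobs.
    """

    n_per_parental: int = 60
    n_parental_sites: int = 6
    # Founding parental-A fractions track a climate-suitability axis that
    # combines latitude and coastal distance (0.3 * normalized latitude +
    # 0.7 * normalized coastal distance over the demes below), so site
    # ancestry follows the climate gradient rather than raw geographic
    # distance — the spatial structure the concordance tests probe.
    # Parental A occupies the coastal south, parental B the inland north.
    admixed_demes: list[DemeConfig] = field(default_factory=lambda: [
        DemeConfig("adm1", 50, 0.95, 47.0, -127.0),
        DemeConfig("adm2", 50, 0.35, 48.0, -122.8),
        DemeConfig("adm3", 50, 0.76, 49.0, -126.2),
        DemeConfig("adm4", 50, 0.34, 50.0, -123.4),
        DemeConfig("adm5", 50, 0.59, 51.0, -125.6),
        DemeConfig("adm6", 50, 0.12, 52.0, -122.2),
        DemeConfig("adm7", 50, 0.39, 53.0, -124.8),
    ])
    n_background_loci: int = 2000
    n_chr5_background: int = 150     # of the background total, placed on chr5
    n_island_loci: int = 25          # off-block divergence islands
    n_block_snps: int = 15
    background_fst: float = 0.02
    island_freqs: tuple[float, float] = (0.01, 0.99)  # ALT freq in (A, B)
    generations: int = 25
    s_mismatch: float = 0.5
    migration_rate: float = 0.05
    missing_rate: float = 0.0
    n_invariant_per_kb: int = 5      # invariant chr5 sites appended for all-sites mode
    # climate model: 13 temperature-like variables follow latitude, 13
    # precipitation-like follow coastal distance (proxied by longitude km)
    temp_slope: float = -0.7         # degrees C per degree latitude
    precip_slope: float = 1.5        # mm per km of coastal distance
    climate_noise_sd: float = 0.05   # relative to each variable's sd
    mt_seq_length: int = 800
    mt_fixed_diffs: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.s_mismatch < 1):
            raise ValueError(f"s_mismatch must be in [0, 1), got {self.s_mismatch}")
        for name in ("background_fst", "migration_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not all(0 <= f <= 1 for f in self.island_freqs):
            raise ValueError(f"island_freqs must be in [0, 1], got {self.island_freqs}")
        for c in ("n_per_parental", "n_background_loci", "n_island_loci",
                  "n_block_snps", "generations"):
            if getattr(self, c) < 1:
                raise ValueError(f"{c} must be >= 1, got {getattr(self, c)}")
        for d in self.admixed_demes:
            if not (0 <= d.init_frac_a <= 1):
                raise ValueError(f"deme {d.site}: init_frac_a must be in [0, 1]")
            if d.n < 1:
                raise ValueError(f"deme {d.site}: n must be >= 1")


@dataclass
class TruthRecord:
    true_ancestry: dict[str, float]      # per-sample B-genome fraction in [0, 1]
    island_locus_idx: list[int]          # columns of the variant matrix (incl. block)
    block_locus_idx: list[int]
    block_interval: tuple[str, int, int]
    s_mismatch: float

    def to_json(self) -> str:
        d = asdict(self)
        d["block_interval"] = list(d["block_interval"])
        return json.dumps(d, indent=1, sort_keys=True)


def simulate_parental_frequencies(config: SimConfig,
                                  rng: np.random.Generator | None = None
                                  ) -> pd.DataFrame:
    """Per-locus parental ALT-allele frequencies and genomic coordinates.

    Background loci: ancestral frequency q ~ U(0.1, 0.9), each parental
    frequency an independent Balding-Nichols Beta draw with F =
    ``background_fst`` (expected Weir-Cockerham F_ST ~ F).  Island and
    block loci are near-fixed for alternative alleles (``island_freqs``).
    The ALT allele is by convention the parental-B allele at island/block
    loci.
    """
    rng = rng or np.random.default_rng(config.seed)
    F = config.background_fst
    nb = config.n_background_loci
    q = rng.uniform(0.1, 0.9, size=nb)
    if F > 0:
        k = (1.0 - F) / F
        pa = rng.beta(q * k, (1 - q) * k)
        pb = rng.beta(q * k, (1 - q) * k)
    else:
        pa = q.copy()
        pb = q.copy()

    fa, fb = config.island_freqs
    ni, nk = config.n_island_loci, config.n_block_snps

    rows = []
    # background loci: chr1-chr4 plus a chr5 contingent in the flank region
    n5 = min(config.n_chr5_background, nb)
    n_other = nb - n5
    per = max(n_other // 4, 1)
    pos_counter = {}
    k_idx = 0
    for c in range(4):
        count = per if c < 3 else n_other - 3 * per
        pos = np.sort(rng.choice(np.arange(1, 10_000_001), size=count, replace=False))
        for p in pos:
            rows.append((f"chr{c + 1}", int(p), pa[k_idx], pb[k_idx], "background"))
            k_idx += 1
    # chr5 background loci stay outside the candidate block: background loci
    # are unlinked, so placing them inside the block would plant unswept
    # variation in a region the scenario treats as a single linked haplotype
    chr5_pool = np.concatenate([np.arange(1, BLOCK_START),
                                np.arange(BLOCK_END + 1, CHR5_LENGTH + 1)])
    pos5 = np.sort(rng.choice(chr5_pool, size=n5, replace=False))
    for p in pos5:
        rows.append((CHR5, int(p), pa[k_idx], pb[k_idx], "background"))
        k_idx += 1
    # islands: spread over chr1-chr4
    ipos = rng.choice(np.arange(1, 10_000_001), size=ni, replace=False)
    for j, p in enumerate(np.sort(ipos)):
        rows.append((f"chr{j % 4 + 1}", int(p), fa, fb, "island"))
    # candidate block on chr5: evenly spaced, fully linked
    bpos = np.linspace(BLOCK_START + 1000, BLOCK_END - 1000, nk).astype(int)
    for p in bpos:
        rows.append((CHR5, int(p), fa, fb, "block"))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "p_alt_a", "p_alt_b", "kind"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # de-duplicate any coincident positions within a chromosome
    df = df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return df


def _draw_parental(freqs: pd.DataFrame, which: str, n: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg draws: (unlinked dosages, block haplotypes)."""
    p = freqs[f"p_alt_{which}"].to_numpy()
    is_block = (freqs["kind"] == "block").to_numpy()
    dos = rng.binomial(2, p[~is_block], size=(n, (~is_block).sum())).astype(float)
    hap = rng.random((n, 2, is_block.sum())) < p[is_block]
    return dos, hap


def cross_parentals(config: SimConfig, freqs: pd.DataFrame, n: int,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """True F1 dosages: each offspring from an A mother and a B father.

    One gamete per parent at unlinked loci; one intact block haplotype from
    each parent.  At loci fixed for alternative alleles in the parents,
    every F1 is heterozygous (ancestry 0.5, heterozygosity 1).
    """
    rng = rng or np.random.default_rng(config.seed)
    is_block = (freqs["kind"] == "block").to_numpy()
    da, ha = _draw_parental(freqs, "a", n, rng)
    db, hb = _draw_parental(freqs, "b", n, rng)
    gam_a = rng.binomial(1, da / 2.0)
    gam_b = rng.binomial(1, db / 2.0)
    block = (ha[np.arange(n), rng.integers(0, 2, n)].astype(int)
             + hb[np.arange(n), rng.integers(0, 2, n)].astype(int))
    dosage = np.empty((n, len(freqs)))
    dosage[:, ~is_block] = gam_a + gam_b
    dosage[:, is_block] = block
    return dosage


class ExtinctionError(RuntimeError):
    """A deme produced no viable offspring under the selection regime."""


def _next_generation(dos, hap, clade, q, config: SimConfig, deme: DemeConfig,
                     freqs: pd.DataFrame, rng: np.random.Generator):
    """One Wright-Fisher round with migration and viability selection."""
    n = dos.shape[0]
    target = deme.n
    s = config.s_mismatch
    out_d, out_h, out_c, out_q = [], [], [], []
    accepted = 0
    attempts = 0
    while accepted < target:
        attempts += 1
        if attempts > 200:
            raise ExtinctionError(
                f"deme {deme.site}: no viable offspring after {attempts} batches"
            )
        batch = max(2 * (target - accepted), 8)
        mothers = rng.integers(0, n, size=batch)
        fathers = rng.integers(0, n, size=batch)
        # unlinked loci: each parent transmits one allele per locus
        ga = rng.binomial(1, dos[mothers] / 2.0)
        gb = rng.binomial(1, dos[fathers] / 2.0)
        d_off = (ga + gb).astype(float)
        # block: one intact haplotype from each parent
        pick_m = rng.integers(0, 2, size=batch)
        pick_f = rng.integers(0, 2, size=batch)
        h_off = np.stack([hap[mothers, pick_m], hap[fathers, pick_f]], axis=1)
        c_off = clade[mothers]
        q_off = (q[mothers] + q[fathers]) / 2.0
        # migration: replace a fraction with fresh parental immigrants
        mig = rng.random(batch) < config.migration_rate
        n_mig = int(mig.sum())
        if n_mig:
            from_a = rng.random(n_mig) < deme.init_frac_a
            for src, msk in (("a", from_a), ("b", ~from_a)):
                k = int(msk.sum())
                if k == 0:
                    continue
                di, hi = _draw_parental(freqs, src, k, rng)
                rows = np.where(mig)[0][msk]
                d_off[rows] = di
                h_off[rows] = hi
                c_off = c_off.copy()
                q_off = q_off.copy()
                c_off[rows] = 0 if src == "a" else 1
                q_off[rows] = 0.0 if src == "a" else 1.0
        # viability: (1 - s)^(mismatched block-allele dosage)
        theta = h_off.mean(axis=(1, 2))  # B-ancestry of the block
        mismatch = np.where(c_off == 1, 2.0 * (1.0 - theta), 2.0 * theta)
        w = (1.0 - s) ** mismatch
        keep = rng.random(batch) < w
        k = int(keep.sum())
        if k == 0:
            continue
        take = min(k, target - accepted)
        sel = np.where(keep)[0][:take]
        out_d.append(d_off[sel])
        out_h.append(h_off[sel])
        out_c.append(c_off[sel])
        out_q.append(q_off[sel])
        accepted += take
    return (np.vstack(out_d), np.concatenate(out_h, axis=0),
            np.concatenate(out_c), np.concatenate(out_q))


def simulate_admixed_cohort(config: SimConfig, freqs: pd.DataFrame,
                            rng: np.random.Generator | None = None
                            ) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Draw parental cohorts and evolve admixed demes; return full dataset.

    Parental individuals are Hardy-Weinberg draws at parental frequencies;
    each admixed deme starts as a mixture of parental founders (fraction
    ``init_frac_a`` from A) and undergoes ``generations`` Wright-Fisher
    rounds with drift, migration and mitonuclear viability selection.
    mtDNA clades are maternally inherited (0 = parental A, 1 = parental B).
    """
    rng = rng or np.random.default_rng(config.seed)
    is_block = (freqs["kind"] == "block").to_numpy()
    n_unlinked = int((~is_block).sum())

    samples, groups, sites, lats, lons, clades_out, true_q = [], [], [], [], [], [], []
    dos_rows, hap_rows = [], []

    # parental cohorts, split over sites along the latitudinal front
    par_sites = {
        "a": [(f"pa{k + 1}", 44.5 + 0.9 * k, -128.0 + 0.2 * (k % 3))
              for k in range(config.n_parental_sites)],
        "b": [(f"pb{k + 1}", 51.0 + 0.9 * k, -121.5 - 0.2 * (k % 3))
              for k in range(config.n_parental_sites)],
    }
    for which, group, clade_val, qv in (("a", "parentA", 0, 0.0), ("b", "parentB", 1, 1.0)):
        d, h = _draw_parental(freqs, which, config.n_per_parental, rng)
        dos_rows.append(d)
        hap_rows.append(h)
        slist = par_sites[which]
        for i in range(config.n_per_parental):
            site, lat, lon = slist[i % len(slist)]
            samples.append(f"{group}_{i + 1:03d}")
            groups.append(group)
            sites.append(site)
            lats.append(lat)
            lons.append(lon)
            clades_out.append(clade_val)
            true_q.append(qv)

    # admixed demes
    for deme in config.admixed_demes:
        n = deme.n
        from_a = rng.random(n) < deme.init_frac_a
        na, nb_ = int(from_a.sum()), n - int(from_a.sum())
        d = np.empty((n, n_unlinked))
        h = np.empty((n, 2, int(is_block.sum())), dtype=bool)
        if na:
            d[from_a], h[from_a] = _draw_parental(freqs, "a", na, rng)
        if nb_:
            d[~from_a], h[~from_a] = _draw_parental(freqs, "b", nb_, rng)
        mt1 = deme.mt_clade1_freq
        if mt1 is None:
            clade = (~from_a).astype(int)
        else:
            clade = (rng.random(n) < mt1).astype(int)
        q = (~from_a).astype(float)
        for _ in range(config.generations):
            d, h, clade, q = _next_generation(d, h, clade, q, config, deme, freqs, rng)
        dos_rows.append(d)
        hap_rows.append(h)
        for i in range(n):
            samples.append(f"{deme.site}_{i + 1:03d}")
            groups.append("admixed")
            sites.append(deme.site)
            lats.append(deme.lat)
            lons.append(deme.lon)
            clades_out.append(int(clade[i]))
            true_q.append(float(q[i]))

    dos_unlinked = np.vstack(dos_rows)
    haps = np.concatenate(hap_rows, axis=0)
    dos_block = haps.sum(axis=1).astype(float)

    # interleave block columns back into genomic order
    n_total = len(freqs)
    dosage = np.empty((dos_unlinked.shape[0], n_total))
    dosage[:, ~is_block] = dos_unlinked
    dosage[:, is_block] = dos_block

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=n_total)]
    alt_base = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4]
                         for r in ref])
    gm = GenotypeMatrix(
        dosage=dosage,
        chrom=freqs["chrom"].to_numpy(),
        pos=freqs["pos"].to_numpy(),
        ref=ref,
        alt=obj_array([(b,) for b in alt_base]),
        samples=samples,
        gq=None,
        is_indel=np.zeros(n_total, dtype=bool),
    )
    table = pd.DataFrame({
        "sample": samples, "group": groups, "site": sites,
        "lat": lats, "lon": lons, "mt_clade": clades_out,
    }).set_index("sample", drop=False)
    island_idx = np.where(freqs["kind"].isin(["island", "block"]))[0].tolist()
    block_idx = np.where(is_block)[0].tolist()
    truth = TruthRecord(
        true_ancestry=dict(zip(samples, true_q)),
        island_locus_idx=island_idx,
        block_locus_idx=block_idx,
        block_interval=(CHR5, BLOCK_START, BLOCK_END),
        s_mismatch=config.s_mismatch,
    )
    return gm, table, truth


TEMP_VARS = [f"temp_{i:02d}" for i in range(1, 14)]
PRECIP_VARS = [f"precip_{i:02d}" for i in range(1, 14)]


def attach_climate_gradient(sites: pd.DataFrame, config: SimConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-site table of 26 climate variables from the spatial gradients.

    Thirteen temperature-like variables are linear in latitude and thirteen
    precipitation-like variables linear in coastal distance (longitude
    converted to km), each with its own slope scale and offset plus
    Gaussian noise, so a correlation PCA yields two dominant axes.
    ``sites`` needs columns site, lat, lon (one row per site).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    lat = sites["lat"].to_numpy(dtype=float)
    lon = sites["lon"].to_numpy(dtype=float)
    coast_km = (lon - lon.min()) * 111.0 * np.cos(np.radians(lat.mean()))
    lat_km = (lat - lat.min()) * 111.0
    # temperature loads mostly on latitude, precipitation mostly on coastal
    # distance, with cross-loadings as in maritime climates: PC1 becomes the
    # shared (suitability) axis, PC2 the latitude-vs-coast contrast
    temp_axis = (0.8 * lat_km + 0.2 * coast_km) / 111.0
    precip_axis = 0.1 * lat_km + 0.9 * coast_km
    data = {}
    for j, name in enumerate(TEMP_VARS):
        scale = 0.5 + 1.5 * (j / max(len(TEMP_VARS) - 1, 1))
        base = scale * config.temp_slope * temp_axis + 10.0 * j
        sd = config.climate_noise_sd * (np.std(base) if np.std(base) > 0 else 1.0)
        data[name] = base + (rng.normal(0, sd, size=len(lat)) if sd > 0 else 0.0)
    for j, name in enumerate(PRECIP_VARS):
        scale = 0.3 + 0.9 * (j / max(len(PRECIP_VARS) - 1, 1))
        base = scale * config.precip_slope * precip_axis + 50.0 * j
        sd = config.climate_noise_sd * (np.std(base) if np.std(base) > 0 else 1.0)
        data[name] = base + (rng.normal(0, sd, size=len(lat)) if sd > 0 else 0.0)
    return pd.DataFrame(data, index=sites["site"].to_numpy())


def _mt_haplotypes(config: SimConfig, clades: np.ndarray, labels: list[str],
                   rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Clade-structured mtDNA haplotypes: two divergent clusters with a few
    shared within-clade variants, so the haplotype network splits cleanly."""
    L = config.mt_seq_length
    bases = "ACGT"
    anc = "".join(rng.choice(list(bases), size=L))
    fixed_pos = rng.choice(L, size=config.mt_fixed_diffs, replace=False)
    clade1 = list(anc)
    for p in fixed_pos:
        clade1[p] = bases[(bases.index(clade1[p]) + 1) % 4]
    clade_seq = {0: anc, 1: "".join(clade1)}
    # 3 haplotype variants per clade (0-2 private mutations each)
    variants: dict[int, list[str]] = {}
    avoid = set(fixed_pos)
    for c in (0, 1):
        vs = [clade_seq[c]]
        for v in range(2):
            s = list(clade_seq[c])
            npriv = v + 1
            pool = [p for p in range(L) if p not in avoid]
            for p in rng.choice(pool, size=npriv, replace=False):
                s[p] = bases[(bases.index(s[p]) + 1) % 4]
            vs.append("".join(s))
        variants[c] = vs
    seqs = []
    for c in clades:
        vi = rng.choice(3, p=[0.6, 0.25, 0.15])
        seqs.append(variants[int(c)][vi])
    return seqs, labels


@dataclass
class SimResult:
    config: SimConfig
    freqs: pd.DataFrame
    genotypes: GenotypeMatrix
    all_sites: GenotypeMatrix
    samples: pd.DataFrame
    truth: TruthRecord
    climate: pd.DataFrame
    mt_sequences: list[str]
    mt_labels: list[str]


def _append_invariant_sites(gm: GenotypeMatrix, config: SimConfig,
                            rng: np.random.Generator) -> GenotypeMatrix:
    """All-sites matrix: variant loci plus invariant (all hom-ref) chr5 sites."""
    n_inv = config.n_invariant_per_kb * (CHR5_LENGTH // 1000)
    taken = set(gm.pos[gm.chrom == CHR5].tolist())
    pool = np.array([p for p in range(1, CHR5_LENGTH + 1) if p not in taken])
    inv_pos = np.sort(rng.choice(pool, size=min(n_inv, len(pool)), replace=False))
    bases = np.array(["A", "C", "G", "T"])
    inv_ref = bases[rng.integers(0, 4, size=len(inv_pos))]
    chrom = np.concatenate([gm.chrom, np.full(len(inv_pos), CHR5)])
    pos = np.concatenate([gm.pos, inv_pos])
    ref = np.concatenate([gm.ref, inv_ref])
    alt = np.concatenate([gm.alt, obj_array([()] * len(inv_pos))])
    dosage = np.hstack([gm.dosage, np.zeros((gm.n_samples, len(inv_pos)))])
    indel = np.concatenate([gm.is_indel, np.zeros(len(inv_pos), dtype=bool)])
    order = np.lexsort((pos, chrom))
    return GenotypeMatrix(
        dosage=dosage[:, order], chrom=chrom[order], pos=pos[order],
        ref=ref[order], alt=alt[order], samples=list(gm.samples),
        gq=None, is_indel=indel[order],
    )


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: frequencies, cohort, climate, mtDNA, all-sites."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_parental_frequencies(config, rng)
    gm, table, truth = simulate_admixed_cohort(config, freqs, rng)
    site_df = table.groupby("site", sort=True).agg(
        lat=("lat", "first"), lon=("lon", "first")).reset_index()
    climate = attach_climate_gradient(site_df, config, rng)
    mt_seqs, mt_labels = _mt_haplotypes(
        config, table["mt_clade"].to_numpy(), list(table["sample"]), rng)
    all_sites = _append_invariant_sites(gm, config, rng)
    return SimResult(config=config, freqs=freqs, genotypes=gm,
                     all_sites=all_sites, samples=table, truth=truth,
                     climate=climate, mt_sequences=mt_seqs, mt_labels=mt_labels)


def write_dataset(result: SimResult, outdir: str) -> dict[str, str]:
    """Write VCFs, sample/climate TSVs, mtDNA FASTA and truth JSON.

    Re-reading the VCFs with :func:`mitoconcord.variant_io.read_genotypes`
    reproduces the dosage matrices exactly; fixed config seed gives
    byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "variants": os.path.join(outdir, "variants.vcf"),
        "all_sites": os.path.join(outdir, "all_sites.vcf"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "climate": os.path.join(outdir, "climate.tsv"),
        "mtdna": os.path.join(outdir, "mtdna.fasta"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(paths["variants"], result.genotypes)
    write_vcf(paths["all_sites"], result.all_sites)
    result.samples.to_csv(paths["samples"], sep="\t", index=False)
    result.climate.rename_axis("site").to_csv(paths["climate"], sep="\t")
    with open(paths["mtdna"], "w") as fh:
        for label, seq in zip(result.mt_labels, result.mt_sequences):
            fh.write(f">{label}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(result.truth.to_json())
    return paths
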