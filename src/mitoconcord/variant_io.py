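"""Genotype and metadata I/O plus variant filtering.

Reads VCF 4.2 (variant-only or all-sites dialects) into an in-memory dosage
matrix via cyvcf2, applies the standard GBS-style site filters (indel
removal, genotype-quality masking, minor-allele-frequency, missingness,
biallelic-only), and reads the per-sample metadata table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "FilterSpec",
    "read_genotypes",
    "apply_variant_filters",
    "read_sample_table",
    "write_vcf",
]


def obj_array(items: list) -> np.ndarray:
    """1-D object array of tuples (plain np.array would make it 2-D)."""
    out = np.empty(len(items), dtype=object)
    out[:] = items
    return out


@dataclass
class GenotypeMatrix:
    """Diploid dosages (0/1/2, NaN = missing) with site and sample metadata.

    ``dosage`` has shape (n_samples, n_sites); ``gq`` the matching genotype
    qualities (NaN where absent).  Positions are 1-based and strictly
    increasing within each chromosome.
    """

    dosage: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray          # object array: tuple of alt alleles per site
    samples: list[str]
    gq: np.ndarray | None = None
    is_indel: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, mask],
            chrom=self.chrom[mask], pos=self.pos[mask],
            ref=self.ref[mask], alt=self.alt[mask],
            samples=list(self.samples),
            gq=None if self.gq is None else self.gq[:, mask],
            is_indel=None if self.is_indel is None else self.is_indel[mask],
        )

    def sample_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass(frozen=True)
class FilterSpec:
    """Site/genotype filter thresholds.

    Defaults follow the GBS filtering criteria: genotypes with GQ <= 20 are
    masked, then indels, non-biallelic sites, sites with > 30% missing
    genotypes, and sites with MAF < 0.05 (inclusive boundary: exactly 0.05
    is kept) are removed.
    """

    min_gq: float = 20.0           # strict: keep GQ > min_gq
    min_maf: float = 0.05          # keep MAF >= min_maf
    max_missing: float = 0.30      # remove missing fraction > max_missing
    biallelic_only: bool = True
    drop_indels: bool = True

    def __post_init__(self):
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError(f"min_maf must be in [0, 0.5], got {self.min_maf}")
        if not (0 <= self.max_missing <= 1):
            raise ValueError(f"max_missing must be in [0, 1], got {self.max_missing}")


def read_genotypes(path: str, all_sites: bool = False) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    GT is decoded to alt-allele dosage ignoring phase; GQ is retained when
    present.  Invariant records (no alt allele) are kept only when
    ``all_sites`` is set.  Non-diploid genotypes raise ``ValueError``.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    dos_rows, gq_rows, chroms, poss, refs, alts, indels = [], [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        invariant = len(rec.ALT) == 0
        if invariant and not all_sites:
            continue
        gts = rec.genotypes  # list of [a1, a2, phased]
        for g in gts:
            if len(g) != 3:
                raise ValueError(
                    f"non-diploid genotype at record {i + 1} ({rec.CHROM}:{rec.POS})"
                )
        d = np.array(rec.gt_types, dtype=float)  # 0,1,2 hom-ref/het/hom-alt; 3 unknown
        d[d == 3] = np.nan
        dos_rows.append(d)
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            gq = np.array(gq, dtype=float).ravel()
            gq[gq < 0] = np.nan
        else:
            gq = np.full(len(samples), np.nan)
        gq_rows.append(gq)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(tuple(rec.ALT))
        indels.append(rec.is_indel)
    vcf.close()
    if not dos_rows:
        raise ValueError(f"no usable records in {path}")
    return GenotypeMatrix(
        dosage=np.vstack(dos_rows).T,
        chrom=np.array(chroms), pos=np.array(poss, dtype=int),
        ref=np.array(refs), alt=obj_array(alts),
        samples=samples,
        gq=np.vstack(gq_rows).T,
        is_indel=np.array(indels, dtype=bool),
    )


def apply_variant_filters(gm: GenotypeMatrix, spec: FilterSpec = FilterSpec()
                          ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply genotype and site filters; return filtered matrix + removal counts.

    Order: GQ masking first (so masked genotypes count toward missingness),
    then site removal by (1) indel, (2) not biallelic, (3) missingness,
    (4) MAF.  Counts report sites removed at each step, applied sequentially.
    """
    dos = gm.dosage.copy()
    counts: dict[str, int] = {}
    if gm.gq is not None:
        mask = np.isfinite(gm.gq) & (gm.gq <= spec.min_gq)
        dos[mask] = np.nan
        counts["genotypes_masked_gq"] = int(mask.sum())

    keep = np.ones(gm.n_sites, dtype=bool)

    if spec.drop_indels and gm.is_indel is not None:
        rm = keep & gm.is_indel
        counts["indel"] = int(rm.sum())
        keep &= ~gm.is_indel
    else:
        counts["indel"] = 0

    if spec.biallelic_only:
        n_alt = np.array([len(a) for a in gm.alt])
        rm = keep & (n_alt != 1)
        counts["not_biallelic"] = int(rm.sum())
        keep &= n_alt == 1
    else:
        counts["not_biallelic"] = 0

    miss_frac = np.mean(~np.isfinite(dos), axis=0)
    rm = keep & (miss_frac > spec.max_missing)
    counts["missingness"] = int(rm.sum())
    keep &= miss_frac <= spec.max_missing

    with np.errstate(invalid="ignore", divide="ignore"):
        n_called = np.isfinite(dos).sum(axis=0)
        p = np.nansum(dos, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1 - p)
    maf_ok = np.where(n_called > 0, maf >= spec.min_maf, False)
    rm = keep & ~maf_ok
    counts["maf"] = int(rm.sum())
    keep &= maf_ok

    counts["kept"] = int(keep.sum())
    if counts["kept"] == 0:
        warnings.warn("no sites survive filtering; returning empty matrix")
    out = replace(gm, dosage=dos).take_sites(keep)
    return out, counts


ALLOWED_GROUPS: tuple[str, ...] = ()  # empty = any label accepted


def read_sample_table(path: str, allowed_groups: list[str] | None = None) -> pd.DataFrame:
    """Read the sample metadata TSV (sample, group, site, lat, lon, mt_clade).

    mt_clade is coerced to {0.0, 1.0, NaN}.  Duplicate sample ids raise;
    unknown group labels raise when ``allowed_groups`` is given.  Samples
    with missing coordinates are flagged (``has_coords`` column) so spatial
    analyses can exclude their sites with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "site": str})
    required = {"sample", "group", "site", "lat", "lon", "mt_clade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if allowed_groups is not None:
        bad = sorted(set(df["group"]) - set(allowed_groups))
        if bad:
            raise ValueError(f"unknown group labels {bad}; allowed: {allowed_groups}")
    df["mt_clade"] = pd.to_numeric(df["mt_clade"], errors="coerce")
    if not df["mt_clade"].dropna().isin([0.0, 1.0]).all():
        raise ValueError("mt_clade values must be 0, 1 or missing")
    df["has_coords"] = df["lat"].notna() & df["lon"].notna()
    if (~df["has_coords"]).any():
        warnings.warn(
            f"{int((~df['has_coords']).sum())} samples lack coordinates; "
            "their sites are excluded from spatial analyses"
        )
    return df.set_index("sample", drop=False)


def match_samples(gm: GenotypeMatrix, table: pd.DataFrame) -> pd.DataFrame:
    """Reorder the sample table to the genotype matrix; error on absentees."""
    absent = [s for s in gm.samples if s not in table.index]
    if absent:
        raise KeyError(f"samples in VCF absent from sample table: {absent}")
    return table.loc[gm.samples]


def write_vcf(path: str, gm: GenotypeMatrix, with_gq: bool = True,
              default_gq: int = 99) -> None:
    """Write a GenotypeMatrix as plain-text VCF 4.2 (GT[:GQ] FORMAT).

    Invariant sites (empty alt tuple) are written with ALT "." so the file
    round-trips through :func:`read_genotypes` in all-sites mode.
    """
    fmt = "GT:GQ" if with_gq else "GT"
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            alt = ",".join(gm.alt[j]) if len(gm.alt[j]) else "."
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                gt = gt_map.get(d, "./.")
                if with_gq:
                    q = default_gq
                    if gm.gq is not None and np.isfinite(gm.gq[i, j]):
                        q = int(gm.gq[i, j])
                    cells.append(f"{gt}:{q}")
                else:
                    cells.append(gt)
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")
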