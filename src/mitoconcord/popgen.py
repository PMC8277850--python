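"""Core differentiation and diversity statistics.

Implements the two-population Weir & Cockerham (1984) F_ST estimator from
genotype counts, windowed nucleotide diversity on all-sites data with the
missing-data-aware (pixy-style) ratio-of-sums estimator, genotype-r2 linkage
disequilibrium, and genotype PCA with per-site mean imputation.

All functions accept a dosage matrix of shape (n_samples, n_sites) with
values in {0, 1, 2} and ``np.nan`` for missing genotypes (see
:class:`mitoconcord.variant_io.GenotypeMatrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FstResult",
    "WindowDiversity",
    "wc_fst_scan",
    "pi_windows",
    "ld_r2_matrix",
    "genotype_pca",
]


@dataclass
class FstResult:
    """Per-site Weir & Cockerham variance components and F_ST ratios.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals.  ``per_site`` is a/(a+b+c) with
    NaN where the denominator is zero (monomorphic sites); ``weighted`` is
    the ratio-of-sums estimate sum(a)/sum(a+b+c).  Negative per-site ratios
    are retained, matching VCFtools semantics.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_site: np.ndarray
    weighted: float
    pops: tuple[str, str]

    def weighted_subset(self, mask: np.ndarray) -> float:
        """Weighted F_ST over an arbitrary site subset (boolean mask)."""
        denom = (self.a + self.b + self.c)[mask]
        ok = np.isfinite(denom)
        if not np.any(ok) or np.nansum(denom[ok]) == 0:
            return float("nan")
        return float(np.nansum(self.a[mask][ok]) / np.nansum(denom[ok]))


def _pop_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped individuals, alt allele freq, observed het freq)."""
    called = np.isfinite(dos)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n)
        h = np.nansum(dos == 1, axis=0) / n
    return n, p, h


def wc_fst_scan(dosage_a: np.ndarray, dosage_b: np.ndarray,
                pops: tuple[str, str] = ("A", "B")) -> FstResult:
    """Weir & Cockerham (1984) two-level F_ST from two populations' dosages.

    Variance components for the two-population, biallelic, diploid case are
    computed per site from sample sizes, allele frequencies and observed
    heterozygote frequencies; sites where either population has fewer than
    two genotyped individuals are returned as NaN.
    """
    r = 2.0
    n1, p1, h1 = _pop_counts(np.asarray(dosage_a, dtype=float))
    n2, p2, h2 = _pop_counts(np.asarray(dosage_b, dtype=float))
    valid = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom != 0, a / denom, np.nan)

    ok = np.isfinite(denom)
    weighted = float(np.sum(a[ok]) / np.sum(denom[ok])) if np.any(ok) and np.sum(denom[ok]) != 0 else float("nan")
    return FstResult(a=a, b=b, c=c, per_site=per_site, weighted=weighted, pops=pops)


@dataclass
class WindowDiversity:
    """Nucleotide diversity in non-overlapping windows.

    ``pi`` is the ratio-of-sums estimate: total allele-pair differences over
    total allele-pair comparisons across genotyped sites in the window.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    pi: float
    n_sites: int  # sites contributing >= 2 genotyped alleles
    n_comparisons: float


def per_site_pi(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pairwise differences, pairwise comparisons) from dosages.

    A site with n genotyped alleles, of which n_alt are alternate, has
    2 * n_ref * n_alt differing pairs out of n * (n - 1) ordered pairs.
    Sites with < 2 genotyped alleles contribute zero to both sums.
    """
    dos = np.asarray(dos, dtype=float)
    called = np.isfinite(dos)
    n_alleles = 2.0 * called.sum(axis=0)
    n_alt = np.nansum(dos, axis=0)
    n_ref = n_alleles - n_alt
    diffs = 2.0 * n_ref * n_alt
    comps = n_alleles * (n_alleles - 1.0)
    usable = n_alleles >= 2
    return np.where(usable, diffs, 0.0), np.where(usable, comps, 0.0)


def pi_windows(dos: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
               window: int = 1000, sample_idx: np.ndarray | None = None,
               is_all_sites: bool = True) -> list[WindowDiversity]:
    """Windowed pi on an all-sites matrix (invariant sites included).

    Windows are anchored at position 1: [1, window], [window+1, 2*window], ...
    Raises ``ValueError`` on variant-only input because the estimator is
    biased without invariant sites.
    """
    if not is_all_sites:
        raise ValueError(
            "pi_windows requires an all-sites matrix (invariant sites included); "
            "re-read the VCF with all_sites=True"
        )
    if sample_idx is not None:
        dos = dos[sample_idx]
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    diffs, comps = per_site_pi(dos)
    out: list[WindowDiversity] = []
    for ch in pd.unique(chrom):
        sel = chrom == ch
        p = pos[sel]
        d = diffs[sel]
        c = comps[sel]
        win_idx = (p - 1) // window
        for w in np.unique(win_idx):
            m = win_idx == w
            csum = float(c[m].sum())
            # ratio of sums: total differences over total comparisons across
            # genotyped sites; invariant sites add comparisons, not differences
            pi = float(d[m].sum() / csum) if csum > 0 else float("nan")
            out.append(WindowDiversity(
                chrom=str(ch), start=int(w) * window + 1, end=(int(w) + 1) * window,
                pi=pi, n_sites=int((c[m] > 0).sum()), n_comparisons=csum,
            ))
    return out


def ld_r2_matrix(dos: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                 site_idx: np.ndarray | None = None,
                 max_pairs: int | None = None,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pairwise genotype r2 (squared Pearson correlation of dosages).

    For each site pair, samples missing at either site are dropped; pairs
    where either site is then monomorphic are skipped.  Returns a DataFrame
    with columns chrom, pos1, pos2, r2, n.  ``max_pairs`` subsamples pairs
    uniformly (seeded via ``rng``) to bound cost on dense regions.
    """
    dos = np.asarray(dos, dtype=float)
    idx = np.arange(dos.shape[1]) if site_idx is None else np.asarray(site_idx)
    pairs = [(i, j) for k, i in enumerate(idx) for j in idx[k + 1:]]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng()
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    rows = []
    for i, j in pairs:
        x, y = dos[:, i], dos[:, j]
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 2:
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        rows.append((str(chrom[i]), int(pos[i]), int(pos[j]), float(r * r), n))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "r2", "n"])


@dataclass
class PCAResult:
    eigenvectors: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray   # (k,) non-increasing
    total_variance: float


def genotype_pca(dos: np.ndarray, k: int = 10, standardize: bool = False,
                 orient_groups: tuple[np.ndarray, np.ndarray] | None = None) -> PCAResult:
    """PCA of centered dosages; missing genotypes mean-imputed per site.

    With ``standardize`` the per-site scaling 1/sqrt(p(1-p)) is applied
    (Patterson-style); default is centered-only.  ``orient_groups`` gives
    boolean masks for parental groups (A, B); EV1 is flipped so that the
    group-A mean is below the group-B mean.
    """
    X = np.array(dos, dtype=float)
    mu = np.nanmean(X, axis=0)
    miss = ~np.isfinite(X)
    X[miss] = np.take(mu, np.nonzero(miss)[1])
    X -= mu
    if standardize:
        p = mu / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        X /= sd
    n = X.shape[0]
    cov = X @ X.T / max(X.shape[1], 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    k = min(k, n)
    ev = vecs[:, :k]
    if orient_groups is not None:
        ga, gb = orient_groups
        if ev[ga, 0].mean() > ev[gb, 0].mean():
            ev = ev.copy()
            ev[:, 0] *= -1
    return PCAResult(eigenvectors=ev, eigenvalues=vals[:k],
                     total_variance=float(vals.sum()))
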