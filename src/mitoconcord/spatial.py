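"""Site-level distance matrices, Mantel tests, climate PCA, rank tests.

Mantel and partial Mantel tests follow the permutation scheme of the vegan
tradition: the observed statistic is the Pearson correlation of the
vectorized upper triangles; the null distribution permutes rows and columns
of the first matrix simultaneously; the one-sided p-value is
(1 + #{r_perm >= r_obs}) / (n_perm + 1).  The partial test correlates the
residuals of A~C and B~C.  Climate PCA operates on the correlation matrix
of standardized site-by-variable climate data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MantelResult",
    "geographic_distance_matrix",
    "value_difference_matrix",
    "mantel_test",
    "partial_mantel_test",
    "climate_pca",
    "rank_group_tests",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool
    control: str | None = None
    tail: str = "greater"


def geographic_distance_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle (haversine) distances in km between sites."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return d


def value_difference_matrix(values: np.ndarray) -> np.ndarray:
    """Absolute-difference distance matrix of a per-site scalar (ancestry, PC score)."""
    v = np.asarray(values, dtype=float)
    return np.abs(v[:, None] - v[None, :])


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _check_square(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all matrices must be square with matching site order")
    if n < 4:
        raise ValueError("Mantel tests need >= 4 sites")
    return n


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float(((x - x.mean()) @ (y - y.mean())) / (len(x) * sx * sy))


def _perm_iter(n: int, n_perm: int, rng: np.random.Generator, exhaustive: bool):
    if exhaustive:
        for perm in _permutations(range(n)):
            yield np.array(perm)
    else:
        for _ in range(n_perm):
            yield rng.permutation(n)


def mantel_test(A: np.ndarray, B: np.ndarray, n_perm: int = 10_000,
                seed: int | np.random.Generator | None = None,
                tail: str = "greater", exhaustive: bool = False) -> MantelResult:
    """Mantel test of matrix association with row/column permutations of A.

    ``exhaustive`` enumerates all n! site permutations instead of sampling
    (only sensible for very small n); the identity permutation then plays
    the role of the observed configuration and p = #{r_perm >= r_obs} / n!.
    """
    n = _check_square(A, B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = _upper(B)
    r_obs = _pearson(_upper(A), b)
    count = 0
    total = 0
    for perm in _perm_iter(n, n_perm, rng, exhaustive):
        r_p = _pearson(_upper(A[np.ix_(perm, perm)]), b)
        total += 1
        if tail == "greater":
            count += r_p >= r_obs - 1e-12
        elif tail == "two-sided":
            count += abs(r_p) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    if exhaustive:
        p = count / total
    else:
        p = (1 + count) / (total + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=total, partial=False, tail=tail)


def _residual_matrix(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Off-diagonal residuals of A on C (linear fit on the upper triangle),
    reflected back into a symmetric matrix so permutations stay consistent."""
    a, c = _upper(A), _upper(C)
    if c.std() == 0:
        beta0, beta1 = a.mean(), 0.0
    else:
        beta1 = np.cov(a, c, bias=True)[0, 1] / c.var()
        beta0 = a.mean() - beta1 * c.mean()
    R = A - (beta0 + beta1 * C)
    np.fill_diagonal(R, 0.0)
    return R


def partial_mantel_test(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                        n_perm: int = 10_000,
                        seed: int | np.random.Generator | None = None,
                        tail: str = "greater", exhaustive: bool = False) -> MantelResult:
    """Partial Mantel test of A vs B controlling the linear effect of C.

    Residualizes A and B on C over the upper triangle, correlates the
    residuals, and permutes rows/columns of the residualized A.
    """
    _check_square(A, B, C)
    RA = _residual_matrix(A, C)
    RB = _residual_matrix(B, C)
    if _upper(RA).std() < 1e-12 or _upper(RB).std() < 1e-12:
        # a matrix fully determined by the control leaves zero residuals:
        # no association beyond C by construction
        return MantelResult(r=0.0, p=1.0, n_perm=0, partial=True,
                            control="C", tail=tail)
    res = mantel_test(RA, RB, n_perm=n_perm, seed=seed, tail=tail, exhaustive=exhaustive)
    return MantelResult(r=res.r, p=res.p, n_perm=res.n_perm, partial=True,
                        control="C", tail=tail)


@dataclass
class ClimatePCA:
    scores: np.ndarray            # (n_sites, k)
    variance_fraction: np.ndarray
    loadings: np.ndarray          # (n_variables, k)
    variables: list[str]


def climate_pca(table: pd.DataFrame) -> ClimatePCA:
    """PCA of the correlation matrix of standardized site-level climate data.

    Zero-variance variables are dropped with a warning; variance fractions
    sum to 1 over all retained components.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("climate PCA needs >= 3 sites")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance climate variables")
    X = X[:, keep]
    names = [c for c, k in zip(table.columns, keep) if k]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n = Z.shape[0]
    corr = Z.T @ Z / (n - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0, None)
    vecs = vecs[:, order]
    frac = vals / vals.sum()
    return ClimatePCA(scores=Z @ vecs, variance_fraction=frac, loadings=vecs,
                      variables=names)


def rank_group_tests(values: dict[str, np.ndarray],
                     exact_pairwise: bool = True) -> dict:
    """Kruskal-Wallis across groups plus BH-adjusted pairwise Wilcoxon rank-sums.

    Uses tie-corrected rank statistics; pairwise Wilcoxon rank-sum (a.k.a.
    Mann-Whitney) p-values are exact for small tie-free samples and
    normal-approximated otherwise, then Benjamini-Hochberg adjusted across
    the pairwise family.
    """
    groups = list(values)
    if len(groups) < 2 or any(len(values[g]) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    kw_stat, kw_p = stats.kruskal(*[values[g] for g in groups])
    pair_labels, pair_p = [], []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            x, y = np.asarray(values[g1]), np.asarray(values[g2])
            has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if (exact_pairwise and not has_ties
                                 and len(x) < 50 and len(y) < 50) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            pair_labels.append((g1, g2))
            pair_p.append(float(res.pvalue))
    adj = multipletests(pair_p, method="fdr_bh")[1] if pair_p else np.array([])
    return {
        "kruskal_stat": float(kw_stat), "kruskal_p": float(kw_p),
        "pairs": pair_labels, "pairwise_p": np.array(pair_p),
        "pairwise_p_adjusted": np.asarray(adj),
    }
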