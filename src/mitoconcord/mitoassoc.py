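"""Structure-corrected association between mtDNA clade and nuclear genotypes.

The scan regresses the top eigenvectors of an identity-by-state kinship
matrix out of both the binary mtDNA clade score and each SNP's dosage
vector, then scores each SNP with n_eff * r^2 of the residual correlation,
treated as a 1-df chi-square.  Residual structure and sample-size effects
are absorbed by genomic control: the inflation factor lambda is the median
raw statistic divided by 0.4549 (the chi-square_1 median), and corrected
statistics are raw / lambda, with p-values from the 1-df upper tail and a
genome-wide significance cutoff of 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...

__all__ = [
    "AssocScan",
    "ibs_kinship",
    "structure_adjusted_scan",
    "genomic_control",
]


@dataclass
class AssocScan:
    chrom: np.ndarray
    pos: np.ndarray
    chi2_raw: np.ndarray
    lam: float | None = None
    chi2_corrected: np.ndarray | None = None
    p: np.ndarray | None = None
    significant: np.ndarray | None = None
    cutoff: float = 1e-6


def ibs_kinship(dos: np.ndarray) -> np.ndarray:
    """Identity-by-state similarity: mean over shared sites of 1 - |di - dj| / 2.

    Diagonal is 1 by definition.  A sample pair with zero shared non-missing
    sites raises, because downstream eigen-decomposition would be undefined.
    """
    dos = np.asarray(dos, dtype=float)
    n = dos.shape[0]
    called = np.isfinite(dos)
    d0 = np.nan_to_num(dos, nan=0.0)
    # sum over shared sites of |di - dj| via expansion is unstable with
    # missingness; loop over pairs in vectorized row blocks instead.
    K = np.empty((n, n))
    for i in range(n):
        shared = called[i] & called
        diff = np.abs(d0[i] - d0)
        diff[~shared] = 0.0
        ns = shared.sum(axis=1).astype(float)
        if (ns == 0).any():
            j = int(np.where(ns == 0)[0][0])
            raise ValueError(f"sample pair ({i}, {j}) shares no genotyped sites")
        K[i] = 1.0 - (diff.sum(axis=1) / ns) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def _residualize(y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual of y on the column space of Q (with intercept included)."""
    X = np.column_stack([np.ones(len(y)), Q]) if Q.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def structure_adjusted_scan(dos: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                            mt_scores: np.ndarray, kinship: np.ndarray | None = None,
                            k_axes: int = 3) -> AssocScan:
    """Per-SNP score statistic for mtDNA-clade association after structure adjustment.

    The top ``k_axes`` eigenvectors of the kinship matrix are regressed out
    of the phenotype and of each dosage vector (restricted to the samples
    genotyped at that SNP); the statistic is n_eff * r^2 with
    n_eff = n - k_axes - 1, referred to chi-square with 1 df.  SNPs whose
    residual variance vanishes are skipped (NaN) and logged.
    """
    dos = np.asarray(dos, dtype=float)
    y = np.asarray(mt_scores, dtype=float)
    n, L = dos.shape
    if k_axes >= n:
        raise ValueError(f"k_axes={k_axes} must be < n samples ({n})")
    if k_axes > 0:
        if kinship is None:
            kinship = ibs_kinship(dos)
        vals, vecs = np.linalg.eigh(kinship)
        Q = vecs[:, np.argsort(vals)[::-1][:k_axes]]
    else:
        Q = np.empty((n, 0))

    chi2 = np.full(L, np.nan)
    for j in range(L):
        ok = np.isfinite(dos[:, j]) & np.isfinite(y)
        m = int(ok.sum())
        if m <= k_axes + 2:
            continue
        ry = _residualize(y[ok], Q[ok])
        rg = _residualize(dos[ok, j], Q[ok])
        sy, sg = ry.std(), rg.std()
        if sy == 0 or sg == 0:
            logger.info("SNP %s:%s skipped: zero residual variance", chrom[j], pos[j])
            continue
        r = float(np.dot(ry, rg) / (len(ry) * sy * sg))
        chi2[j] = (m - k_axes - 1) * r * r
    return AssocScan(chrom=np.asarray(chrom), pos=np.asarray(pos), chi2_raw=chi2)


def genomic_control(scan: AssocScan, cutoff: float = 1e-6) -> AssocScan:
    """Apply genomic control: lambda = median(chi2) / 0.4549, corrected = raw / lambda."""
    raw = scan.chi2_raw
    finite = raw[np.isfinite(raw)]
    if finite.size < 100:
        raise ValueError(f"genomic control needs >= 100 scored SNPs, got {finite.size}")
    med = float(np.median(finite))
    if med == 0:
        raise ValueError("degenerate scan: median chi-square is 0")
    lam = med / CHI2_1_MEDIAN
    corrected = raw / lam
    p = stats.chi2.sf(corrected, df=1)
    return AssocScan(
        chrom=scan.chrom, pos=scan.pos, chi2_raw=raw,
        lam=lam, chi2_corrected=corrected, p=p,
        significant=np.nan_to_num(p, nan=1.0) < cutoff, cutoff=cutoff,
    )
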