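"""Ancestry-informative markers and admixture diagnostics.

A marker panel is the set of SNPs strongly differentiated between the two
parental populations (per-site F_ST above a threshold, 0.6 by default, with
0.3 as the standard robustness check).  Each panel locus is polarized so
that the allele at higher frequency in parental group B scores ancestry 1;
homozygotes then score 0 or 1 and heterozygotes 0.5.  Per-individual means
of these scores give the triangle-plot coordinates (ancestry proportion,
interspecific heterozygosity), the candidate-block ancestry theta, and the
combined mitonuclear ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import FstResult

__all__ = [
    "MarkerPanel",
    "TriangleScores",
    "BlockSpec",
    "select_informative_markers",
    "triangle_scores",
    "block_ancestry",
    "mitonuclear_ancestry",
    "hybrid_index_from_axis",
]


@dataclass
class MarkerPanel:
    site_idx: np.ndarray      # indices into the filtered GenotypeMatrix
    chrom: np.ndarray
    pos: np.ndarray
    b_is_alt: np.ndarray      # True where the ALT allele is the group-B allele
    threshold: float


@dataclass
class TriangleScores:
    """Triangle-plot coordinates per individual.

    ``ancestry`` is the mean per-locus ancestry score over non-missing panel
    loci; ``heterozygosity`` the fraction of those loci that are
    heterozygous.  With complete data het <= 2*min(a, 1-a) exactly.
    Individuals missing every panel locus get NaN and are flagged.
    """

    ancestry: np.ndarray
    heterozygosity: np.ndarray
    n_used: np.ndarray


@dataclass
class BlockSpec:
    chrom: str
    start: int   # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"block end {self.end} < start {self.start}")

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(chrom) == self.chrom) & (pos >= self.start) & (pos <= self.end)


def select_informative_markers(fst: FstResult, chrom: np.ndarray, pos: np.ndarray,
                               freq_a: np.ndarray, freq_b: np.ndarray,
                               threshold: float = 0.6) -> MarkerPanel:
    """Select sites with per-site F_ST strictly above ``threshold``.

    ``freq_a``/``freq_b`` are ALT-allele frequencies in the two parental
    groups; polarity is set from them (B allele = the one commoner in B),
    so ancestry semantics survive ref/alt relabeling.  Frequency ties fall
    back to allele-index order (ALT treated as the B allele) and are logged.
    """
    sel = np.where(np.nan_to_num(fst.per_site, nan=-1.0) > threshold)[0]
    if sel.size == 0:
        warnings.warn(f"no markers exceed F_ST threshold {threshold}; empty panel")
    b_is_alt = freq_b[sel] >= freq_a[sel]
    ties = freq_b[sel] == freq_a[sel]
    if ties.any():
        warnings.warn(f"{int(ties.sum())} panel loci with equal parental "
                      "frequencies polarized by allele index order")
    return MarkerPanel(site_idx=sel, chrom=np.asarray(chrom)[sel],
                       pos=np.asarray(pos)[sel], b_is_alt=b_is_alt,
                       threshold=threshold)


def _ancestry_scores(dos: np.ndarray, b_is_alt: np.ndarray) -> np.ndarray:
    """Per-locus ancestry 0/0.5/1 (NaN where missing) from dosages."""
    scores = dos / 2.0
    return np.where(b_is_alt[None, :], scores, 1.0 - scores)


def triangle_scores(dos: np.ndarray, panel: MarkerPanel) -> TriangleScores:
    """Ancestry proportion and interspecific heterozygosity over the panel."""
    if panel.site_idx.size == 0:
        raise ValueError("empty marker panel")
    sub = dos[:, panel.site_idx].astype(float)
    scores = _ancestry_scores(sub, panel.b_is_alt)
    called = np.isfinite(sub)
    n_used = called.sum(axis=1)
    if (n_used == 0).any():
        warnings.warn(f"{int((n_used == 0).sum())} individuals missing all "
                      "panel loci; scores undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        anc = np.nansum(scores, axis=1) / n_used
        het = np.nansum(sub == 1, axis=1) / n_used
    anc[n_used == 0] = np.nan
    het[n_used == 0] = np.nan
    return TriangleScores(ancestry=anc, heterozygosity=het, n_used=n_used)


def block_ancestry(dos: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                   block: BlockSpec, b_is_alt: np.ndarray | None = None,
                   panel: MarkerPanel | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-locus ancestry (theta) over block member loci.

    Member loci are those inside the block interval; polarity comes either
    from an explicit ``b_is_alt`` vector over those loci or from a panel
    restricted to the block.  Returns (theta, n_used).
    """
    if panel is not None:
        in_block = block.contains(panel.chrom, panel.pos)
        idx = panel.site_idx[in_block]
        pol = panel.b_is_alt[in_block]
    else:
        member = block.contains(chrom, pos)
        idx = np.where(member)[0]
        pol = np.ones(idx.size, dtype=bool) if b_is_alt is None else np.asarray(b_is_alt)
    if idx.size == 0:
        raise ValueError("no loci inside the candidate block")
    sub = dos[:, idx].astype(float)
    scores = _ancestry_scores(sub, pol)
    n_used = np.isfinite(sub).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.nansum(scores, axis=1) / n_used
    theta[n_used == 0] = np.nan
    return theta, n_used


def mitonuclear_ancestry(mt_score: np.ndarray, theta: np.ndarray,
                         site: np.ndarray | None = None
                         ) -> tuple[np.ndarray, pd.Series | None]:
    """Combined mitonuclear ancestry: (mtDNA score + block theta) / 2.

    Individuals missing either component get NaN and are excluded from the
    per-site means (returned when ``site`` labels are supplied).
    """
    mt = np.asarray(mt_score, dtype=float)
    th = np.asarray(theta, dtype=float)
    indiv = (mt + th) / 2.0
    site_means = None
    if site is not None:
        df = pd.DataFrame({"site": np.asarray(site), "mn": indiv})
        site_means = df.dropna().groupby("site")["mn"].mean()
    return indiv, site_means


def hybrid_index_from_axis(ev1: np.ndarray,
                           group_a: np.ndarray | None = None,
                           group_b: np.ndarray | None = None) -> np.ndarray:
    """Min-max transform of the first PCA eigenvector onto [0, 1].

    h = (EV1 - min) / (max - min), oriented so parental group A maps near 0
    and group B near 1 (axis flipped if the group means are inverted).
    """
    ev1 = np.asarray(ev1, dtype=float)
    lo, hi = np.nanmin(ev1), np.nanmax(ev1)
    if hi == lo:
        raise ValueError("degenerate axis: max(EV1) == min(EV1)")
    h = (ev1 - lo) / (hi - lo)
    if group_a is not None and group_b is not None:
        if np.nanmean(h[group_a]) > np.nanmean(h[group_b]):
            h = 1.0 - h
    return h
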