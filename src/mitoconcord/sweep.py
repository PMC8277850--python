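"""Bootstrap contrast of diversity and LD: candidate block vs flanking region.

A selective sweep leaves locally reduced nucleotide diversity and elevated
linkage disequilibrium around the swept haplotype.  The contrast resamples
per-window pi values (or per-pair r2 values) with replacement, compares the
95% bootstrap CIs of the block mean and the comparison-region mean, and
flags disjoint intervals with their direction (depletion or elevation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import BlockSpec
from .popgen import WindowDiversity

__all__ = ["BlockContrast", "bootstrap_block_contrast", "region_values"]


@dataclass
class BlockContrast:
    statistic: str                  # "pi" or "r2"
    block_mean: float
    comparison_mean: float
    block_ci: tuple[float, float]
    comparison_ci: tuple[float, float]
    iterations: int
    disjoint: bool
    direction: str                  # "depletion" | "elevation" | "none"


def _boot_ci(values: np.ndarray, iters: int, rng: np.random.Generator,
             batch: int = 2000) -> tuple[float, float]:
    n = values.size
    means = np.empty(iters)
    for start in range(0, iters, batch):
        k = min(batch, iters - start)
        idx = rng.integers(0, n, size=(k, n))
        means[start:start + k] = values[idx].mean(axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def bootstrap_block_contrast(values_block: np.ndarray, values_comparison: np.ndarray,
                             statistic: str = "pi", iters: int = 10_000,
                             seed: int | np.random.Generator | None = None) -> BlockContrast:
    """Percentile bootstrap CIs of the two set means and the disjoint-CI flag.

    Resampling unit is whatever the inputs are (1-kb windows for pi, site
    pairs for r2).  ``disjoint`` is True when block upper < comparison lower
    (depletion) or block lower > comparison upper (elevation).
    """
    vb = np.asarray(values_block, dtype=float)
    vc = np.asarray(values_comparison, dtype=float)
    vb = vb[np.isfinite(vb)]
    vc = vc[np.isfinite(vc)]
    if vb.size == 0 or vc.size == 0:
        raise ValueError("both value sets must be non-empty")
    if vb.size == 1 or vc.size == 1:
        warnings.warn("value set of size 1: degenerate (zero-width) bootstrap CI")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ci_b = _boot_ci(vb, iters, rng)
    ci_c = _boot_ci(vc, iters, rng)
    if ci_b[1] < ci_c[0]:
        disjoint, direction = True, "depletion"
    elif ci_b[0] > ci_c[1]:
        disjoint, direction = True, "elevation"
    else:
        disjoint, direction = False, "none"
    return BlockContrast(
        statistic=statistic, block_mean=float(vb.mean()), comparison_mean=float(vc.mean()),
        block_ci=ci_b, comparison_ci=ci_c, iterations=iters,
        disjoint=disjoint, direction=direction,
    )


def region_values(block: BlockSpec,
                  windows: list[WindowDiversity] | None = None,
                  ld: pd.DataFrame | None = None,
                  flank: tuple[int, int] | None = None,
                  comparison: str = "flank") -> tuple[np.ndarray, np.ndarray]:
    """Partition pi windows or LD pairs into block vs comparison sets.

    Windows join the block when their midpoint lies inside it; with
    ``comparison="flank"`` the comparison set is windows/pairs inside the
    ``flank`` super-region but outside the block, with ``"rest"`` it is the
    rest of the chromosome.  LD pairs need both sites on one side; pairs
    straddling the boundary are excluded from both sets.
    """
    if (windows is None) == (ld is None):
        raise ValueError("provide exactly one of windows or ld")
    if comparison == "flank" and flank is None:
        raise ValueError("comparison='flank' requires a flank interval")

    if windows is not None:
        mids = np.array([(w.start + w.end) / 2.0 for w in windows])
        chroms = np.array([w.chrom for w in windows])
        vals = np.array([w.pi for w in windows])
        on_chrom = chroms == block.chrom
        in_block = on_chrom & (mids >= block.start) & (mids <= block.end)
        if comparison == "flank":
            in_comp = (on_chrom & (mids >= flank[0]) & (mids <= flank[1]) & ~in_block)
        else:
            in_comp = on_chrom & ~in_block
    else:
        on_chrom = ld["chrom"].to_numpy() == block.chrom
        p1 = ld["pos1"].to_numpy()
        p2 = ld["pos2"].to_numpy()
        vals = ld["r2"].to_numpy()
        b1 = (p1 >= block.start) & (p1 <= block.end)
        b2 = (p2 >= block.start) & (p2 <= block.end)
        in_block = on_chrom & b1 & b2
        if comparison == "flank":
            f1 = (p1 >= flank[0]) & (p1 <= flank[1]) & ~b1
            f2 = (p2 >= flank[0]) & (p2 <= flank[1]) & ~b2
            in_comp = on_chrom & f1 & f2
        else:
            in_comp = on_chrom & ~b1 & ~b2

    if not in_block.any():
        raise ValueError("no values fall inside the candidate block")
    return vals[in_block], vals[in_comp]
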