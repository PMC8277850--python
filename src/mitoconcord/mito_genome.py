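"""mtDNA haplotype analysis and Wright-Fisher drift arithmetic.

Covers: pairwise haplotype distances (Hamming, ambiguity-aware), a
minimum-spanning haplotype network over unique sequences, clade scoring by
removing the deepest network edge, fixed nucleotide differences and d_xy
between clades, fixed amino-acid substitutions under the vertebrate
mitochondrial code, and Wright-Fisher effective-size / lineage-sorting
calculations (diffusion mean absorption time plus a forward binomial
simulator that serves as its independent check).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import parse as seqio_parse

VALID_CHARS = set("ACGTN-")
MISSING_CHARS = set("N-")

__all__ = [
    "HaplotypeAlignment",
    "HaploNetwork",
    "DriftParams",
    "read_alignment",
    "pairwise_differences",
    "build_msn",
    "assign_clades",
    "fixed_differences",
    "translate_and_compare",
    "ne_from_diversity",
    "wf_absorption_time",
    "wf_forward_simulate",
]


@dataclass
class HaplotypeAlignment:
    sequences: list[str]
    labels: list[str]
    groups: list[str] | None = None

    def __post_init__(self):
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lens)}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - VALID_CHARS
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_alignment(fasta_path: str, groups: dict[str, str] | None = None) -> HaplotypeAlignment:
    recs = list(seqio_parse(fasta_path, "fasta"))
    labels = [r.id for r in recs]
    return HaplotypeAlignment(
        sequences=[str(r.seq) for r in recs], labels=labels,
        groups=[groups[l] for l in labels] if groups else None,
    )


def _hamming(s1: str, s2: str) -> int:
    return sum(
        1 for a, b in zip(s1, s2)
        if a != b and a not in MISSING_CHARS and b not in MISSING_CHARS
    )


def pairwise_differences(aln: HaplotypeAlignment) -> np.ndarray:
    """Hamming distances ignoring positions where either sequence has N or a gap."""
    n = len(aln.sequences)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(aln.sequences[i], aln.sequences[j])
    return d


@dataclass
class HaploNetwork:
    """Minimum spanning network over unique haplotypes.

    ``node_members`` maps node index -> sample labels sharing that
    haplotype; ``edges`` are (u, v, mutation count) in the spanning tree.
    """

    haplotypes: list[str]
    node_members: list[list[str]]
    edges: list[tuple[int, int, int]]

    @property
    def node_sizes(self) -> list[int]:
        return [len(m) for m in self.node_members]


def build_msn(aln: HaplotypeAlignment) -> HaploNetwork:
    """Collapse identical sequences and build a minimum spanning tree (Kruskal).

    Edge ties are broken by lexicographic node-pair order (deterministic);
    edge weights are the mutation counts between haplotypes.
    """
    uniq: dict[str, int] = {}
    members: list[list[str]] = []
    haps: list[str] = []
    for seq, label in zip(aln.sequences, aln.labels):
        if seq not in uniq:
            uniq[seq] = len(haps)
            haps.append(seq)
            members.append([])
        members[uniq[seq]].append(label)
    k = len(haps)
    if k == 1:
        return HaploNetwork(haplotypes=haps, node_members=members, edges=[])
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = _hamming(haps[i], haps[j])
    # Kruskal with (weight, u, v) ordering for deterministic tie-breaks
    edges_sorted = sorted((int(d[i, j]), i, j) for i in range(k) for j in range(i + 1, k))
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int, int]] = []
    for w, u, v in edges_sorted:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v, w))
            if len(tree) == k - 1:
                break
    return HaploNetwork(haplotypes=haps, node_members=members, edges=tree)


def assign_clades(net: HaploNetwork, reference_label: str | None = None) -> dict[str, int]:
    """Score samples 0/1 by splitting the network at its deepest edge.

    The maximum-weight spanning-tree edge is removed; the two components
    are the clades.  Polarity: the component containing ``reference_label``
    scores 0 (without a reference, the component holding the first sample in
    network order scores 0).  A tie for the maximum edge raises, demanding a
    manual split rather than a silent arbitrary one.
    """
    if len(net.haplotypes) < 2:
        return {label: 0 for m in net.node_members for label in m}
    weights = [w for _, _, w in net.edges]
    wmax = max(weights)
    if weights.count(wmax) > 1:
        raise ValueError(
            f"tie for maximum network edge (weight {wmax}); "
            "clade split ambiguous — supply a manual split"
        )
    cut = weights.index(wmax)
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(net.haplotypes)))
    g.add_edges_from((u, v) for i, (u, v, _) in enumerate(net.edges) if i != cut)
    comps = list(nx.connected_components(g))
    assert len(comps) == 2
    node_clade: dict[int, int] = {}
    for ci, comp in enumerate(comps):
        for node in comp:
            node_clade[node] = ci
    scores = {label: node_clade[i] for i, m in enumerate(net.node_members) for label in m}
    ref = reference_label if reference_label is not None else net.node_members[0][0]
    if ref not in scores:
        raise KeyError(f"reference sample {ref!r} not in network")
    if scores[ref] == 1:
        scores = {lab: 1 - s for lab, s in scores.items()}
    return scores


def fixed_differences(aln: HaplotypeAlignment, group_a: str, group_b: str
                      ) -> tuple[list[int], float]:
    """Sites fixed between two groups plus mean between-group difference (d_xy).

    A site is fixed when the two groups' observed allele sets (ignoring
    N/gap) are non-empty and disjoint.  d_xy averages the per-pair
    mismatch fraction over comparable sites across all between-group
    sequence pairs.
    """
    if aln.groups is None:
        raise ValueError("alignment has no group labels")
    idx_a = [i for i, g in enumerate(aln.groups) if g == group_a]
    idx_b = [i for i, g in enumerate(aln.groups) if g == group_b]
    if not idx_a or not idx_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    fixed: list[int] = []
    for s in range(aln.length):
        al_a = {aln.sequences[i][s] for i in idx_a} - MISSING_CHARS
        al_b = {aln.sequences[i][s] for i in idx_b} - MISSING_CHARS
        if al_a and al_b and not (al_a & al_b):
            fixed.append(s + 1)  # 1-based
    fracs = []
    for i in idx_a:
        for j in idx_b:
            s1, s2 = aln.sequences[i], aln.sequences[j]
            comp = sum(1 for a, b in zip(s1, s2)
                       if a not in MISSING_CHARS and b not in MISSING_CHARS)
            if comp:
                fracs.append(_hamming(s1, s2) / comp)
    dxy = float(np.mean(fracs)) if fracs else float("nan")
    return fixed, dxy


@dataclass
class CodingRegion:
    gene: str
    start: int  # 1-based inclusive, in frame
    end: int
    strand: int = 1


def _consensus(seqs: list[str]) -> str:
    """Majority consensus; ties and all-missing columns become N."""
    out = []
    for col in zip(*seqs):
        counts = Counter(c for c in col if c not in MISSING_CHARS)
        if not counts:
            out.append("N")
            continue
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out.append("N")
        else:
            out.append(top[0][0])
    return "".join(out)


def translate_and_compare(aln: HaplotypeAlignment, regions: list[CodingRegion],
                          group_a: str, group_b: str) -> list[dict]:
    """Fixed amino-acid substitutions between group consensus sequences.

    Each group's majority consensus is translated per coding region with
    the vertebrate mitochondrial code (NCBI table 2: TGA->W, AGA/AGG->stop,
    ATA->M).  Substitutions are reported as gene, 1-based residue index,
    and from->to letters (e.g. N150D).  Codons containing N in either
    consensus are skipped; an internal stop raises with gene and position.
    """
    if aln.groups is None:
        raise ValueError("alignment has no group labels")
    seq_a = _consensus([s for s, g in zip(aln.sequences, aln.groups) if g == group_a])
    seq_b = _consensus([s for s, g in zip(aln.sequences, aln.groups) if g == group_b])
    if not seq_a or not seq_b:
        raise ValueError("empty consensus")
    subs: list[dict] = []
    for reg in regions:
        sub_a = seq_a[reg.start - 1:reg.end]
        sub_b = seq_b[reg.start - 1:reg.end]
        if len(sub_a) % 3 != 0:
            raise ValueError(f"{reg.gene}: coding length {len(sub_a)} is not a whole codon count")
        if reg.strand == -1:
            sub_a = str(Seq(sub_a).reverse_complement())
            sub_b = str(Seq(sub_b).reverse_complement())
        aa_a = str(Seq(sub_a).translate(table=2))
        aa_b = str(Seq(sub_b).translate(table=2))
        for r, (x, y) in enumerate(zip(aa_a, aa_b), start=1):
            codon_a = sub_a[3 * (r - 1):3 * r]
            codon_b = sub_b[3 * (r - 1):3 * r]
            if "N" in codon_a or "N" in codon_b:
                continue
            internal = r < len(aa_a)
            if internal and (x == "*" or y == "*"):
                raise ValueError(f"internal stop codon in {reg.gene} at residue {r}")
            if x != y:
                subs.append({"gene": reg.gene, "residue": r,
                             "from": x, "to": y, "label": f"{x}{r}{y}"})
    return subs


@dataclass
class DriftParams:
    ne: float
    mu: float
    pi: float
    p: float

    def __post_init__(self):
        if self.ne <= 0 or self.mu <= 0:
            raise ValueError("Ne and mu must be positive")
        if not (0 < self.p < 1):
            raise ValueError("starting frequency p must be in (0, 1)")


def ne_from_diversity(pi: float, mu: float, mode: str = "pi_over_mu") -> float:
    """Effective population size from nucleotide diversity.

    ``pi_over_mu`` returns pi/mu (the convention consistent with the
    downstream lineage-sorting arithmetic here); ``pi_over_4mu`` returns
    the diploid-autosomal pi/(4 mu).
    """
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    if mode == "pi_over_mu":
        return pi / mu
    if mode == "pi_over_4mu":
        return pi / (4.0 * mu)
    raise ValueError(f"unknown mode {mode!r}")


def wf_absorption_time(ne: float, p: float, scaling: str = "diploid"
                       ) -> dict[str, float]:
    """Diffusion-approximation Wright-Fisher absorption times.

    Mean time to loss or fixation from frequency p:
        T(p) = -4 Ne (p ln p + (1-p) ln(1-p))
    and the mean time conditional on loss:
        T_loss(p) = -4 Ne (p / (1-p)) ln p.
    ``scaling="haploid"`` replaces 4 Ne with 2 Ne.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    c = 4.0 * ne if scaling == "diploid" else 2.0 * ne
    if p <= 0 or p >= 1:
        return {"t_absorption": 0.0, "t_loss": 0.0, "note": "boundary start"}
    t = -c * (p * np.log(p) + (1 - p) * np.log(1 - p))
    t_loss = -c * (p / (1 - p)) * np.log(p)
    return {"t_absorption": float(t), "t_loss": float(t_loss)}


def wf_forward_simulate(n: int, p0: float, n_reps: int = 1000,
                        seed: int | np.random.Generator | None = None,
                        max_gens: int = 10_000_000) -> np.ndarray:
    """Forward binomial Wright-Fisher: generations to absorption per replicate.

    A diploid population of n individuals carries 2n allele copies; each
    generation resamples the count Binomial(2n, x/2n) until loss or
    fixation.  Serves as the Monte-Carlo oracle for
    :func:`wf_absorption_time`.
    """
    if n > 10_000:
        raise ValueError("forward simulation is intended for n <= 10,000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_n = 2 * n
    times = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        x = int(round(p0 * two_n))
        t = 0
        while 0 < x < two_n:
            x = rng.binomial(two_n, x / two_n)
            t += 1
            if t >= max_gens:
                raise RuntimeError("absorption not reached within max_gens")
        times[r] = t
    return times
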