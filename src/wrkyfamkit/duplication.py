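"""Tandem clusters, microsynteny blocks and duplication-type classification.

Tandem duplicates are family members lying within a fixed number of gene
ranks of one another on a chromosome (single linkage, default ≤10 genes).
Segmental duplicates are family gene pairs whose flanking windows share a
chain of collinear homologous gene pairs (anchors); block significance is
a hypergeometric tail probability on the anchor count given the
genome-wide homolog density, Bonferroni-scaled by the number of window
pairs examined.  Gene-level duplication classes follow the standard
precedence segmental > tandem > proximal > dispersed, with singletons
having no family homolog at all.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomeAnnotation
from .selection import ng86_kaks

__all__ = [
    "TandemCluster",
    "SyntenyBlock",
    "DuplicationType",
    "find_tandem_clusters",
    "find_synteny_blocks",
    "classify_duplication_types",
    "summarize_block_ks",
    "infer_homology_pairs",
]


@dataclass
class TandemCluster:
    chromosome: str
    genes: list[str]  # ordered by rank
    ranks: list[int]


@dataclass
class SyntenyBlock:
    gene_a: str
    gene_b: str
    anchors: list[tuple[str, str]]
    evalue: float
    mean_ks: float = float("nan")
    sd_ks: float = float("nan")
    ks_defined: bool = False

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class DuplicationType:
    gene_id: str
    duplication_class: str  # singleton|dispersed|proximal|tandem|segmental


def find_tandem_clusters(
    annotation: GenomeAnnotation,
    family_ids: Iterable[str],
    max_gene_distance: int = 10,
) -> list[TandemCluster]:
    """Single-linkage tandem clustering of family genes by rank distance.

    Two family genes on one chromosome join a cluster when their ranks
    (over all annotated genes, strand ignored) differ by at most
    ``max_gene_distance``; clusters of at least two genes are returned,
    sorted by chromosome then rank.
    """
    fam = sorted(set(family_ids))
    for gid in fam:
        if gid not in annotation:
            raise KeyError(f"unknown gene id {gid!r}")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid in fam:
        g = annotation[gid]
        by_chrom.setdefault(g.chromosome, []).append((annotation.rank[gid], gid))
    clusters = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        run: list[tuple[int, str]] = [entries[0]]
        for entry in entries[1:]:
            if entry[0] - run[-1][0] <= max_gene_distance:
                run.append(entry)
            else:
                if len(run) >= 2:
                    clusters.append(
                        TandemCluster(chrom, [g for _, g in run], [r for r, _ in run])
                    )
                run = [entry]
        if len(run) >= 2:
            clusters.append(TandemCluster(chrom, [g for _, g in run], [r for r, _ in run]))
    return clusters


def _longest_monotone_chain(pairs: list[tuple[int, int, str, str]]) -> list[tuple[str, str]]:
    """Longest chain strictly monotone in both ranks; inversions allowed by
    taking the better of the increasing and decreasing orientations."""

    def lis(seq: list[tuple[int, int, str, str]], sign: int) -> list[tuple[str, str]]:
        order = sorted(seq, key=lambda t: (t[0], sign * t[1]))
        # O(n^2) DP is fine at window scale
        n = len(order)
        length = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if order[j][0] < order[i][0] and sign * order[j][1] < sign * order[i][1]:
                    if length[j] + 1 > length[i]:
                        length[i] = length[j] + 1
                        prev[i] = j
        if n == 0:
            return []
        end = max(range(n), key=lambda i: (length[i], -i))
        chain = []
        while end != -1:
            chain.append(order[end])
            end = prev[end]
        chain.reverse()
        return [(a, b) for _, _, a, b in chain]

    up = lis(pairs, +1)
    down = lis(pairs, -1)
    return up if len(up) >= len(down) else down


def find_synteny_blocks(
    annotation: GenomeAnnotation,
    family_pairs: Sequence[tuple[str, str]],
    homology_pairs: Iterable[tuple[str, str]],
    window: int = 50,
    min_pairs: int = 3,
    evalue_cutoff: float = 0.01,
    tandem_gap: int = 2,
) -> list[SyntenyBlock]:
    """Microsynteny detection around candidate family gene pairs.

    For each candidate pair, homologous gene pairs between the two
    ``window``-gene windows centred on the focal genes are collected
    (tandem-duplicated neighbours within ``tandem_gap`` ranks collapsed to
    one representative), the longest rank-monotone chain in either
    orientation is taken as the anchor set, and blocks with at least
    ``min_pairs`` anchors and Bonferroni-scaled hypergeometric E-value at
    or below the cutoff are reported.
    """
    if window < min_pairs:
        raise ValueError("window must be >= min_pairs")
    hom: set[frozenset[str]] = set()
    for a, b in homology_pairs:
        if a != b:
            hom.add(frozenset((a, b)))
    n_genes = len(annotation)
    total_pairs = n_genes * (n_genes - 1) // 2
    density = len(hom) / total_pairs if total_pairs else 0.0
    half = window // 2
    n_tests = max(len(family_pairs), 1)

    def window_genes(gid: str) -> list[tuple[int, str]]:
        g = annotation[gid]
        chrom_genes = annotation.chromosomes[g.chromosome]
        r = annotation.rank[gid]
        lo, hi = max(0, r - half), min(len(chrom_genes), r + half + 1)
        return [(i, chrom_genes[i].gene_id) for i in range(lo, hi)]

    def collapse(win: list[tuple[int, str]]) -> list[tuple[int, str]]:
        """Collapse runs of homologous near-neighbours to one representative."""
        kept: list[tuple[int, str]] = []
        for r, gid in win:
            if kept and r - kept[-1][0] <= tandem_gap:
                prev = kept[-1][1]
                if frozenset((prev, gid)) in hom:
                    continue
            kept.append((r, gid))
        return kept

    blocks = []
    for ga, gb in family_pairs:
        if ga not in annotation or gb not in annotation:
            raise KeyError(f"unknown gene in family pair ({ga!r}, {gb!r})")
        wa = collapse(window_genes(ga))
        wb = collapse(window_genes(gb))
        focal = {ga, gb}
        cand = [
            (ra, rb, a, b)
            for (ra, a), (rb, b) in itertools.product(wa, wb)
            if a != b and not focal & {a, b} and frozenset((a, b)) in hom
        ]
        anchors = _longest_monotone_chain(cand)
        m = len(anchors)
        if m < min_pairs:
            continue
        # P(X >= m) for homolog count between two windows at background density
        nn = len(wa) * len(wb)
        k_exp = max(int(round(density * total_pairs)), 1)
        ev = float(stats.hypergeom.sf(m - 1, total_pairs, k_exp, nn)) * n_tests
        if ev <= evalue_cutoff:
            blocks.append(SyntenyBlock(ga, gb, anchors, ev))
    blocks.sort(key=lambda b: (-b.n_anchors, b.evalue, b.gene_a, b.gene_b))
    return blocks


def classify_duplication_types(
    annotation: GenomeAnnotation,
    family_ids: Iterable[str],
    homology_pairs: Iterable[tuple[str, str]],
    blocks: Sequence[SyntenyBlock],
    clusters: Sequence[TandemCluster],
    proximal_distance: int = 10,
) -> list[DuplicationType]:
    """One duplication class per family gene.

    Precedence: segmental (focal gene of a significant block) > tandem
    (member of a tandem cluster) > proximal (family homolog within
    ``proximal_distance`` ranks on the same chromosome) > dispersed (any
    other family homolog) > singleton (no family homolog).
    """
    fam = sorted(set(family_ids))
    famset = set(fam)
    hom: dict[str, set[str]] = {g: set() for g in fam}
    for a, b in homology_pairs:
        if a in famset and b in famset and a != b:
            hom[a].add(b)
            hom[b].add(a)
    segmental = {g for b in blocks for g in (b.gene_a, b.gene_b)}
    tandem = {g for c in clusters for g in c.genes}
    out = []
    for g in fam:
        if g in segmental:
            cls = "segmental"
        elif g in tandem:
            cls = "tandem"
        elif any(
            annotation[h].chromosome == annotation[g].chromosome
            and abs(annotation.rank[h] - annotation.rank[g]) <= proximal_distance
            for h in hom[g]
        ):
            cls = "proximal"
        elif hom[g]:
            cls = "dispersed"
        else:
            cls = "singleton"
        out.append(DuplicationType(g, cls))
    return out


def summarize_block_ks(
    block: SyntenyBlock,
    cds_lookup: Mapping[str, str],
    ks_cap: float = 5.0,
) -> SyntenyBlock:
    """Attach mean/SD of anchor-pair Ks (NG86) to a block.

    Saturated pairs (ps ≥ 3/4) and pairs with Ks above ``ks_cap`` are
    excluded.  With a single usable anchor the SD is reported as 0; with
    none, the summary is flagged undefined rather than raising.
    """
    values = []
    for a, b in block.anchors:
        res = ng86_kaks(cds_lookup[a], cds_lookup[b])
        if res.saturated or not np.isfinite(res.ks) or res.ks > ks_cap:
            continue
        values.append(res.ks)
    if not values:
        block.mean_ks = float("nan")
        block.sd_ks = float("nan")
        block.ks_defined = False
    else:
        block.mean_ks = float(np.mean(values))
        block.sd_ks = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        block.ks_defined = True
    return block


def infer_homology_pairs(
    proteins: Sequence, k: int = 6, min_containment: float = 0.5
) -> list[tuple[str, str]]:
    """Candidate homolog pairs by shared-k-mer containment.

    A seed-based screen in the spirit of alignment heuristics: two
    proteins are called homologous when the smaller one shares at least
    ``min_containment`` of its k-mers with the other.  Suited to the
    synthetic genomes, whose homologs are near-identical copies; real
    proteomes would warrant a full alignment-score screen on the
    candidates this returns.
    """
    kmers: dict[str, set[str]] = {}
    index: dict[str, set[str]] = {}
    for rec in proteins:
        ks = {rec.sequence[i : i + k] for i in range(len(rec.sequence) - k + 1)}
        kmers[rec.id] = ks
        for km in ks:
            index.setdefault(km, set()).add(rec.id)
    pairs = []
    done = set()
    for rec in proteins:
        cands: dict[str, int] = {}
        for km in kmers[rec.id]:
            for other in index[km]:
                if other != rec.id:
                    cands[other] = cands.get(other, 0) + 1
        for other, shared in cands.items():
            key = frozenset((rec.id, other))
            if key in done:
                continue
            done.add(key)
            denom = min(len(kmers[rec.id]), len(kmers[other]))
            if denom and shared / denom >= min_containment:
                pairs.append(tuple(sorted((rec.id, other))))
    return sorted(pairs)
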