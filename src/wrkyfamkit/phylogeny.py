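"""Domain alignment, distance estimation and neighbor-joining trees.

The tree pipeline mirrors a classical distance workflow: a deterministic
progressive aligner (k-mer guide tree + profile-profile Needleman–Wunsch)
stands in for a general-purpose MSA program, amino-acid distances are
computed with pairwise deletion of gapped columns, trees are built with
the Saitou–Nei neighbor-joining algorithm, and clade support comes from
column-bootstrap replicates.

Trees are represented as :mod:`dendropy` ``Tree`` objects so that Newick
round-tripping, bipartition handling and patristic distances use the
library machinery; the NJ and alignment algorithms themselves are
implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "progressive_align",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "domain_rows",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_SUBMAT = np.array([[_BLOSUM62[a][b] for b in _AA] for a in _AA], dtype=float)
_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 − fraction of shared k-mers (min-normalized); crude but guide-tree-grade."""
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the amino-acid alphabet (gaps dropped)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(_AA)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                prof[j, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1
    sums = prof.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1
    return prof / sums


def _nw_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile–profile alignment with affine-ish linear gap costs."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    sa = pa @ _SUBMAT @ pb.T  # expected substitution score per column pair
    n, m = sa.shape
    gap = _GAP_OPEN / 2.0  # linear approximation keeps the DP simple and fast
    score = np.zeros((n + 1, m + 1))
    back = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = gap * np.arange(1, n + 1)
    score[0, 1:] = gap * np.arange(1, m + 1)
    back[1:, 0] = 1
    back[0, 1:] = 2
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sa[i - 1]
        for j in range(1, m + 1):
            d = diag[j - 1]
            u = score[i - 1, j] + gap
            l = score[i, j - 1] + gap
            if d >= u and d >= l:
                score[i, j], back[i, j] = d, 0
            elif u >= l:
                score[i, j], back[i, j] = u, 1
            else:
                score[i, j], back[i, j] = l, 2
    # traceback
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i, j]
        if move == 0:
            i, j = i - 1, j - 1
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
        elif move == 1:
            i -= 1
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r in range(len(rows_b)):
                out_b[r].append("-")
        else:
            j -= 1
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
    return (["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b])


def progressive_align(sequences: Sequence[SequenceRecord]) -> MultipleAlignment:
    """Deterministic progressive multiple alignment.

    Guide order comes from single-linkage joining on k-mer distances with
    index-based tie-breaks, so permuting the input only permutes the rows.
    """
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    order = sorted(range(len(sequences)), key=lambda i: sequences[i].id)
    seqs = [sequences[i] for i in order]
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _kmer_distance(seqs[i].sequence, seqs[j].sequence)
    # single-linkage agglomeration; a cluster holds (member indices, ids, rows)
    clusters: dict[int, tuple[list[int], list[str], list[str]]] = {
        i: ([i], [seqs[i].id], [seqs[i].sequence]) for i in range(n)
    }
    cd = {(i, j): d[i, j] for i, j in itertools.combinations(range(n), 2)}
    nxt = n
    while len(clusters) > 1:
        (i, j), _ = min(cd.items(), key=lambda kv: (kv[1], kv[0]))
        mem_i, ids_i, rows_i = clusters.pop(i)
        mem_j, ids_j, rows_j = clusters.pop(j)
        new_i, new_j = _nw_profiles(rows_i, rows_j)
        merged = (mem_i + mem_j, ids_i + ids_j, new_i + new_j)
        cd = {k: v for k, v in cd.items() if i not in k and j not in k}
        for k, (mem_k, _, _) in clusters.items():
            dk = min(d[a, b] for a in merged[0] for b in mem_k)
            cd[(min(k, nxt), max(k, nxt))] = dk
        clusters[nxt] = merged
        nxt += 1
    _, ids, rows = clusters.popitem()[1]
    # restore the caller's input order
    pos = {rec.id: i for i, rec in enumerate(sequences)}
    paired = sorted(zip(ids, rows), key=lambda t: pos[t[0]])
    return MultipleAlignment([p[0] for p in paired], [p[1] for p in paired])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def distance_matrix(
    alignment: MultipleAlignment,
    model: Literal["p-distance", "poisson"] = "poisson",
) -> DistanceMatrix:
    """Pairwise amino-acid distances with pairwise deletion.

    For each pair, columns where either row is gapped are excluded; the
    proportion of mismatches p over the remaining columns is the p-distance,
    and the Poisson-corrected distance is −ln(1 − p).  A saturated pair
    (p = 1) is capped at the resolution of the comparison, 1 − 1/(2n)
    mismatches over n comparable columns, rather than returning infinity.
    """
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    gap = np.bytes_(b"-")
    n = len(rows)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = (rows[i] != gap) & (rows[j] != gap)
        total = int(ok.sum())
        if total == 0:
            raise ValueError(
                f"no comparable columns between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
            )
        p = float((rows[i][ok] != rows[j][ok]).sum()) / total
        if model == "p-distance":
            dij = p
        else:
            dij = -np.log(1.0 - min(p, 1.0 - 0.5 / total))
        out[i, j] = out[j, i] = dij
    return DistanceMatrix(list(alignment.ids), out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined (lowest
    index pair on ties); negative branch lengths are clamped to zero.  The
    result is an unrooted tree (trifurcating root node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    d = dm.matrix.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    # final edge: attach the remaining node to the last internal node with
    # the full residual length, yielding an unrooted (trifurcating) tree
    a, b = active
    if nodes[b].child_nodes():
        hub, other = b, a
    else:
        hub, other = a, b
    nodes[hub].add_child(nodes[other])
    nodes[other].edge.length = max(d[a, b], 0.0)
    tree.seed_node = nodes[hub]
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def domain_rows(members, proteins: dict[str, str]) -> list[SequenceRecord]:
    """Extract one sequence row per WRKY domain for the domain tree.

    Two-domain (Group 1) proteins contribute their N- and C-terminal
    domains separately, suffixed ``-NTWD``/``-CTWD``, so their distinct
    ancestries stay visible in the tree.
    """
    out = []
    for member in members:
        complete = [h for h in member.hits if h.complete]
        if not complete:
            continue
        seq = proteins[member.protein_id]
        if len(complete) >= 2:
            for h, suffix in zip(complete[:2], ("-NTWD", "-CTWD")):
                out.append(
                    SequenceRecord(member.protein_id + suffix, seq[h.heptapeptide_start : h.end])
                )
        else:
            h = complete[0]
            out.append(SequenceRecord(member.protein_id, seq[h.heptapeptide_start : h.end]))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side)."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            other = frozenset(labels - side)
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    alignment: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: Literal["p-distance", "poisson"] = "poisson",
) -> dendropy.Tree:
    """NJ tree with bootstrap support percentages on internal nodes.

    Columns are resampled with replacement *n_replicates* times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it.  One master seed drives
    per-replicate derived seeds, so results are reproducible and
    replicate-order independent.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(alignment.rows) < 4:
        raise ValueError("bootstrap support needs at least 4 rows")
    base = nj_tree(distance_matrix(alignment, model))
    target = _bipartitions(base)
    counts = {bp: 0 for bp in target}
    ncol = alignment.n_columns
    master = np.random.SeedSequence(seed)
    for child in master.spawn(n_replicates):
        rng = np.random.default_rng(child)
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in alignment.rows]
        rep = MultipleAlignment(list(alignment.ids), rows)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue  # replicate with an all-gap pair carries no signal
        for bp in _bipartitions(rep_tree) & target:
            counts[bp] += 1
    labels = {lf.taxon.label for lf in base.leaf_node_iter()}
    for node in base.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            key = min(side, frozenset(labels - side), key=lambda s: (len(s), sorted(s)))
            node.label = str(round(100.0 * counts[key] / n_replicates))
    return base
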