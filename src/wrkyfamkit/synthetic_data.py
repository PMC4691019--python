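"""Synthetic annotated genomes, codon alignments and expression matrices.

The generators plant exactly the structures the downstream analyses look
for — family proteins with group-specific domain architectures, tandem
arrays within a rank gap, collinear duplicated segments with homologous
anchors, codon alignments evolved under the branch-site process, and
expression matrices with known fold changes — and return truth tables
recording every planted label.  All generators are pure functions of
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeAnnotation, SequenceRecord
from .selection import (
    CODONS,
    CodonModel,
    equal_codon_frequencies,
    transition_matrices,
)

__all__ = [
    "FamilyPlantSpec",
    "BranchSiteSimSpec",
    "ExpressionSimSpec",
    "SyntheticGenome",
    "generate_annotated_genome",
    "simulate_codon_alignment",
    "simulate_expression_matrix",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, for deterministic back-translation
_BY_AA: dict[str, list[str]] = {}
for _c in CODONS:
    from .selection import AA_OF, CODON_INDEX

    _BY_AA.setdefault(AA_OF[CODON_INDEX[_c]], []).append(_c)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

GROUPS = ("1", "2a", "2b", "2c", "2d", "2e", "3")


@dataclass
class FamilyPlantSpec:
    """Layout of a planted WRKY family.

    ``n_members`` counts per group label; ``tandem_clusters`` is a list of
    (chromosome, cluster size, rank gap between consecutive members);
    ``segmental_blocks`` a list of (anchor count, window size) planted
    between rotating chromosome pairs.  Tandem clusters and the two focal
    genes of each segmental block consume members from ``n_members``.
    """

    n_members: Mapping[str, int] = field(
        default_factory=lambda: {"1": 2, "2a": 2, "2b": 2, "2c": 2, "2d": 2, "2e": 2, "3": 3}
    )
    tandem_clusters: list[tuple[str, int, int]] = field(default_factory=list)
    segmental_blocks: list[tuple[int, int]] = field(default_factory=list)
    background_genes: int = 60
    n_chromosomes: int = 4
    anchor_divergence: float = 0.0
    isolation: int = 30  # rank gap between planted structures; keep above the
    # synteny half-window so unrelated family genes never absorb block anchors
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_members.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 0:
                raise ValueError("member counts must be >= 0")
        for chrom, size, gap in self.tandem_clusters:
            if size < 2 or gap < 1:
                raise ValueError("tandem clusters need size >= 2 and gap >= 1")


@dataclass
class BranchSiteSimSpec:
    """Conditions for simulating a codon alignment under branch-site model A."""

    tree: object  # dendropy.Tree or newick string
    foreground: str
    n_codons: int = 300
    kappa: float = 2.0
    p0: float = 0.45
    p1: float = 0.45
    p2a: float = 0.05
    p2b: float = 0.05
    omega0: float = 0.2
    omega2: float = 5.0
    pi: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array([self.p0, self.p1, self.p2a, self.p2b])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("site-class proportions must be >= 0 and sum to 1")
        if not 0 < self.omega0 < 1:
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")


@dataclass
class ExpressionSimSpec:
    """Planted drought-course expression experiment.

    ``conditions`` defaults to a dehydration time course with D0 as the
    untreated control; ``fold_changes`` maps gene id → {condition: fold}
    (unlisted genes/conditions are 1-fold).  Noise is multiplicative
    log-normal on the RPKM scale with log2-sd ``noise_sd``.
    """

    n_genes: int = 200
    conditions: tuple[str, ...] = ("D0", "D1", "D3", "D6", "D24")
    control: str = "D0"
    fold_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise must be >= 0")
        for gene, per_cond in self.fold_changes.items():
            for cond, f in per_cond.items():
                if f <= 0:
                    raise ValueError(f"fold change for {gene}/{cond} must be > 0")
                if cond not in self.conditions:
                    raise ValueError(f"unknown condition {cond!r}")


# ---------------------------------------------------------------------------
# Protein / CDS construction
# ---------------------------------------------------------------------------

def _rand_protein(rng: np.random.Generator, length: int) -> str:
    while True:
        seq = "".join(rng.choice(list(_AA20), size=length))
        if "WRKYGQK" not in seq:
            return seq


def _domain(rng: np.random.Generator, finger: str) -> str:
    filler = _rand_protein(rng, 10)
    if finger == "C2H2":
        body = "C" + _rand_protein(rng, 4) + "C" + _rand_protein(rng, 22) + "H" + \
            rng.choice(list(_AA20)) + "H"
    else:
        body = "C" + _rand_protein(rng, 7) + "C" + _rand_protein(rng, 23) + "H" + \
            rng.choice(list(_AA20)) + "C"
    return "WRKYGQK" + filler + body


def _group_prototype(rng: np.random.Generator, group: str) -> str:
    """One protein prototype per group/subgroup; members copy it verbatim."""
    nflank = "M" + _rand_protein(rng, 19)
    cflank = _rand_protein(rng, 15)
    if group == "1":
        return nflank + _domain(rng, "C2H2") + _rand_protein(rng, 25) + _domain(rng, "C2H2") + cflank
    if group == "3":
        return nflank + _domain(rng, "C2HC") + cflank
    return nflank + _domain(rng, "C2H2") + cflank


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BY_AA[aa]) for aa in protein) + "TAA"


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    annotation: GenomeAnnotation
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    truth_members: pd.DataFrame  # gene_id, group, subgroup, chromosome, rank
    truth_tandem: pd.DataFrame  # cluster_id, chromosome, genes (comma-joined)
    truth_segmental: pd.DataFrame  # block_id, gene_a, gene_b, n_anchors
    truth_anchors: pd.DataFrame  # block_id, anchor_a, anchor_b


def _first_domain_offset(protein: str) -> int:
    return protein.index("WRKYGQK")


def generate_annotated_genome(spec: FamilyPlantSpec) -> SyntheticGenome:
    """Emit an annotated multi-chromosome genome with a planted WRKY family.

    Background genes are random proteins screened to contain no WRKYGQK
    heptapeptide (clean negatives).  Family members copy their group (or
    subgroup) prototype exactly, so at zero noise every downstream stage
    can recover the planted truth tables.  Every family gene carries one
    intron inside its (first) WRKY domain with phase 2; background genes
    are single-exon.  Tandem members sit within the requested rank gaps;
    segmental blocks share ``anchor count`` homologous flanking genes in
    identical relative order around a homologous focal pair.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"Chr{i + 1}" for i in range(spec.n_chromosomes)]
    prototypes = {g: _group_prototype(rng, g) for g in GROUPS}

    # member pool per group
    pool: list[dict] = []
    for g in GROUPS:
        for _ in range(spec.n_members.get(g, 0)):
            pool.append({"group": g[0], "subgroup": g if g.startswith("2") else "none",
                         "label": g, "protein": prototypes[g]})
    n_family = len(pool)
    needed = sum(size for _, size, _ in spec.tandem_clusters) + 2 * len(spec.segmental_blocks)
    if needed > n_family:
        raise ValueError(
            f"layout needs {needed} family members but only {n_family} specified"
        )

    def take_same_label(k: int) -> list[dict]:
        """Remove k members sharing a group label from the pool."""
        from collections import Counter

        counts = Counter(m["label"] for m in pool)
        for label, c in sorted(counts.items()):
            if c >= k:
                out = [m for m in pool if m["label"] == label][:k]
                for m in out:
                    pool.remove(m)
                return out
        raise ValueError(f"no group with {k} remaining members for a planted structure")

    # chromosome slot maps: rank -> descriptor
    slots: dict[str, dict[int, dict]] = {c: {} for c in chrom_names}
    next_free = {c: 2 for c in chrom_names}
    spacing = max(spec.isolation, 13)  # > tandem distance and half-window

    truth_tandem_rows = []
    for ci, (chrom, size, gap) in enumerate(spec.tandem_clusters):
        if chrom not in slots:
            raise ValueError(f"unknown chromosome {chrom!r} in tandem spec")
        members = take_same_label(size)
        r0 = next_free[chrom]
        ranks = [r0 + i * gap for i in range(size)]
        if ranks[-1] >= spec.background_genes:
            raise ValueError(f"tandem cluster {ci} exceeds chromosome capacity")
        for m, r in zip(members, ranks):
            slots[chrom][r] = m
        next_free[chrom] = ranks[-1] + spacing
        truth_tandem_rows.append({"cluster_id": f"tc{ci}", "chromosome": chrom,
                                  "genes": members, "ranks": ranks})

    truth_block_rows = []
    truth_anchor_rows = []
    for bi, (n_anchors, window) in enumerate(spec.segmental_blocks):
        if n_anchors < 1:
            raise ValueError("segmental blocks need >= 1 anchor")
        ca = chrom_names[bi % len(chrom_names)]
        cb = chrom_names[(bi + 1) % len(chrom_names)]
        focal = take_same_label(2)
        span = 2 * n_anchors + 2
        if span > window:
            raise ValueError(f"block {bi}: {n_anchors} anchors do not fit in window {window}")
        ra0, rb0 = next_free[ca], next_free[cb]
        if max(ra0, rb0) + span >= spec.background_genes:
            raise ValueError(f"segmental block {bi} exceeds chromosome capacity")
        anchor_rows = []
        half = n_anchors // 2
        offs = [2 * i for i in range(half)] + [2 * i + 2 for i in range(half, n_anchors)]
        for ai, off in enumerate(offs):
            prot = _rand_protein(rng, 100)
            a_desc = {"group": "bg", "protein": prot, "anchor": (bi, ai, "a")}
            b_desc = {"group": "bg", "protein": prot, "anchor": (bi, ai, "b")}
            slots[ca][ra0 + off] = a_desc
            slots[cb][rb0 + off] = b_desc
            anchor_rows.append((a_desc, b_desc))
        mid = 2 * half + 1  # focal genes between the two anchor runs
        slots[ca][ra0 + mid] = focal[0]
        slots[cb][rb0 + mid] = focal[1]
        next_free[ca] = ra0 + span + spacing
        next_free[cb] = rb0 + span + spacing
        truth_block_rows.append({"block_id": f"sb{bi}", "focal": focal, "n_anchors": n_anchors,
                                 "anchors": anchor_rows})

    # scattered remaining members, far apart
    ci = 0
    while pool:
        chrom = chrom_names[ci % len(chrom_names)]
        r = next_free[chrom]
        if r >= spec.background_genes:
            ci += 1
            if all(next_free[c] >= spec.background_genes for c in chrom_names):
                raise ValueError("family layout exceeds total chromosome capacity")
            continue
        slots[chrom][r] = pool.pop(0)
        next_free[chrom] = r + spacing
        ci += 1

    # fill remaining ranks with background genes, then assemble gene models
    genes: list[GeneModel] = []
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    cds_cache: dict[str, str] = {}
    truth_member_rows = []
    counter = 0
    for chrom in chrom_names:
        for rank in range(spec.background_genes):
            desc = slots[chrom].get(rank)
            if desc is None:
                desc = {"group": "bg", "protein": _rand_protein(rng, int(rng.integers(80, 160)))}
                slots[chrom][rank] = desc
            gid = f"Syn{counter:05d}"
            counter += 1
            desc["gene_id"] = gid
            prot = desc["protein"]
            if prot not in cds_cache:
                cds_cache[prot] = _back_translate(prot, rng)
            cds = cds_cache[prot]
            if desc.get("anchor") and spec.anchor_divergence > 0 and desc["anchor"][2] == "b":
                cds = _mutate_cds(cds, spec.anchor_divergence, rng)
                desc = {**desc, "protein": _translate(cds)}
                prot = desc["protein"]
            start = 200 + rank * 2500
            is_family = desc["group"] != "bg"
            if is_family:
                dom = _first_domain_offset(prot)
                brk = 3 * dom + 14  # phase 2, inside the 5th domain codon
                intron = 120
                e1 = (start, start + brk)
                e2 = (start + brk + intron, start + brk + intron + len(cds) - brk)
                exons = [e1, e2]
                cds_segments = [(e1[0], e1[1], 0), (e2[0], e2[1], (3 - brk % 3) % 3)]
                end = e2[1]
            else:
                exons = [(start, start + len(cds))]
                cds_segments = [(start, start + len(cds), 0)]
                end = start + len(cds)
            strand = "+" if is_family or rank % 2 == 0 else "-"
            genes.append(GeneModel(gid, chrom, start, end, strand, exons, cds_segments))
            proteins.append(SequenceRecord(gid, prot, "protein"))
            cds_records.append(SequenceRecord(gid, cds, "nucleotide"))
            if is_family:
                truth_member_rows.append({
                    "gene_id": gid, "group": desc["group"], "subgroup": desc["subgroup"],
                    "label": desc["label"], "chromosome": chrom, "rank": rank,
                })

    annotation = GenomeAnnotation(genes)
    truth_members = pd.DataFrame(
        truth_member_rows,
        columns=["gene_id", "group", "subgroup", "label", "chromosome", "rank"],
    )
    truth_tandem = pd.DataFrame(
        [
            {
                "cluster_id": row["cluster_id"],
                "chromosome": row["chromosome"],
                "genes": ",".join(m["gene_id"] for m in row["genes"]),
            }
            for row in truth_tandem_rows
        ],
        columns=["cluster_id", "chromosome", "genes"],
    )
    truth_segmental = pd.DataFrame(
        [
            {
                "block_id": row["block_id"],
                "gene_a": row["focal"][0]["gene_id"],
                "gene_b": row["focal"][1]["gene_id"],
                "n_anchors": row["n_anchors"],
            }
            for row in truth_block_rows
        ],
        columns=["block_id", "gene_a", "gene_b", "n_anchors"],
    )
    truth_anchors = pd.DataFrame(
        [
            {
                "block_id": row["block_id"],
                "anchor_a": a["gene_id"],
                "anchor_b": b["gene_id"],
            }
            for row in truth_block_rows
            for a, b in row["anchors"]
        ],
        columns=["block_id", "anchor_a", "anchor_b"],
    )
    return SyntheticGenome(
        annotation, proteins, cds_records,
        truth_members, truth_tandem, truth_segmental, truth_anchors,
    )


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate a CDS, rejecting mutations that create internal stops."""
    from .selection import STOP_CODONS

    chars = list(cds)
    body = len(cds) - 3
    for i in range(body):
        if rng.random() < rate:
            alt = rng.choice([n for n in "ACGT" if n != chars[i]])
            old = chars[i]
            chars[i] = alt
            codon = "".join(chars[3 * (i // 3) : 3 * (i // 3) + 3])
            if codon in STOP_CODONS:
                chars[i] = old
    return "".join(chars)


def _translate(cds: str) -> str:
    from .selection import _TABLE

    return "".join(
        _TABLE.forward_table.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 3, 3)
    )


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    spec: BranchSiteSimSpec,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Evolve a codon alignment under branch-site model A along a tree.

    Site classes are drawn from the stated proportions; substitutions use
    the same rate matrices as the inference code (class-specific ω on the
    foreground branch).  Returns the leaf sequences and the per-site class
    truth (0, 1, 2, 3 for classes 0/1/2a/2b).  Deterministic per seed.
    """
    import dendropy

    tree = spec.tree
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(spec.seed)
    pi = spec.pi if spec.pi is not None else equal_codon_frequencies()
    props = np.array([spec.p0, spec.p1, spec.p2a, spec.p2b])
    classes = rng.choice(4, size=spec.n_codons, p=props)
    # p0/p1 of the CodonModel here only set the normalization mixture
    model = CodonModel(
        kappa=spec.kappa, omega0=spec.omega0, omega2=spec.omega2,
        p0=max(spec.p0, 1e-6), p1=max(spec.p1, 1e-6), pi=pi,
    )
    eigs = transition_matrices(model)
    omega_bf = [
        (spec.omega0, spec.omega0),
        (1.0, 1.0),
        (spec.omega0, spec.omega2),
        (1.0, spec.omega2),
    ]
    root_states = rng.choice(len(CODONS), size=spec.n_codons, p=pi / pi.sum())
    states = {id(tree.seed_node): root_states}
    leaf_records = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent_states = states[id(nd.parent_node)]
        t = float(nd.edge.length or 0.0)
        name = nd.taxon.label if nd.taxon else nd.label
        is_fg = name == spec.foreground
        child = parent_states.copy()
        if t > 0:
            for ci in range(4):
                mask = classes == ci
                if not mask.any():
                    continue
                w = omega_bf[ci][1] if is_fg else omega_bf[ci][0]
                p = eigs[w].expm(t)
                cum = np.cumsum(p, axis=1)
                u = rng.random(mask.sum())
                rowcum = cum[parent_states[mask]]
                child[mask] = (u[:, None] > rowcum).sum(axis=1)
        states[id(nd)] = child
        if nd.is_leaf():
            seq = "".join(CODONS[s] for s in child)
            leaf_records.append(SequenceRecord(nd.taxon.label, seq, "nucleotide"))
    return leaf_records, classes


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM matrix with planted fold changes plus truth labels.

    Returns ``(matrix, truth)`` where the matrix is genes × conditions and
    truth holds each gene's maximal/minimal planted fold change and the
    implied response class at the 2-fold threshold (up beats down when a
    gene crosses both, matching the classifier's precedence).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    baseline = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    mat = np.tile(baseline[:, None], (1, len(spec.conditions)))
    folds = np.ones_like(mat)
    for gi, gene in enumerate(gene_ids):
        per_cond = spec.fold_changes.get(gene, {})
        for cj, cond in enumerate(spec.conditions):
            folds[gi, cj] = per_cond.get(cond, 1.0)
    mat = mat * folds
    if spec.noise_sd > 0:
        mat = mat * 2.0 ** rng.normal(0.0, spec.noise_sd, mat.shape)
    df = pd.DataFrame(mat, index=gene_ids, columns=list(spec.conditions))
    ctrl_idx = spec.conditions.index(spec.control)
    rel = folds / folds[:, ctrl_idx : ctrl_idx + 1]
    max_f, min_f = rel.max(axis=1), rel.min(axis=1)
    label = np.where(max_f >= 2.0, "up", np.where(min_f <= 0.5, "down", "unresponsive"))
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "max_fold": max_f, "min_fold": min_f, "label": label}
    ).set_index("gene_id")
    return df, truth
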