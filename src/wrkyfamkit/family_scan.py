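"""WRKY family identification and group classification.

A WRKY domain is an ~60-residue DNA-binding module: the conserved
heptapeptide ``WRKYGQK`` followed, within a bounded window, by a zinc
finger.  Two finger architectures occur, distinguished by residue spacing:

* ``C2H2``  — ``C-X(4,5)-C-X(22,23)-H-X-H``
* ``C2HC``  — ``C-X(7)-C-X(23)-H-X-C``

Family classification follows the domain count and finger type: proteins
with two complete domains form Group 1 (both fingers C2H2), proteins with
a single C2H2 domain form Group 2 (subgroups a–e resolved on the tree),
and proteins with a single C2HC domain form Group 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel, SequenceRecord

__all__ = [
    "ScanConfig",
    "WrkyDomainHit",
    "FamilyMember",
    "DomainGeneStructure",
    "find_wrky_domains",
    "classify_group",
    "assign_subgroup",
    "map_domain_gene_structure",
    "scan_proteome",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tunables of the pattern scan.

    ``heptapeptides``: accepted N-terminal signatures (exact match; the
    canonical WRKYGQK by default, variants such as WRKYGKK may be added).
    ``finger_search_window``: the first zinc-finger Cys must begin within
    this many residues after the heptapeptide ends.  ``max_domain_span``:
    cap on heptapeptide-start → finger-end span, bounding the search.
    """

    heptapeptides: tuple[str, ...] = ("WRKYGQK",)
    finger_search_window: int = 30
    max_domain_span: int = 120


# C2H2 tried before C2HC: tighter spacers win when both match from one Cys.
_C2H2 = re.compile(r"C(.{4,5})C(.{22,23})H.H")
_C2HC = re.compile(r"C(.{7})C(.{23})H.C")


@dataclass(frozen=True)
class WrkyDomainHit:
    protein_id: str
    heptapeptide_start: int
    heptapeptide: str
    finger_type: str  # C2H2 | C2HC | none
    finger_offsets: tuple[int, ...] = ()  # C, C, H, H/C offsets in the protein
    spacers: tuple[int, int] | None = None  # (x1 between Cys pair, x2 Cys2->His1)

    @property
    def complete(self) -> bool:
        return self.finger_type in ("C2H2", "C2HC")

    @property
    def end(self) -> int:
        if self.finger_offsets:
            return self.finger_offsets[-1] + 1
        return self.heptapeptide_start + len(self.heptapeptide)


@dataclass
class FamilyMember:
    protein_id: str
    hits: list[WrkyDomainHit]
    group: str  # "1", "2", "3", "unclassified"
    subgroup: str = "none"  # "2a".."2e" or "none"


@dataclass
class DomainGeneStructure:
    gene_id: str
    introns_in_domain: int
    domain_intron_phases: list[int]
    introns_in_cds: int


def _match_finger(window: str, base: int):
    """Leftmost zinc-finger match in *window*; C2H2 preferred on equal start.

    Returns ``(finger_type, (C, C, H, H/C offsets), (x1, x2))`` or ``None``.
    """
    cands = []
    for rank, (ftype, pat) in enumerate((("C2H2", _C2H2), ("C2HC", _C2HC))):
        m = pat.search(window)
        if m:
            cands.append((m.start(), rank, ftype, m))
    if not cands:
        return None
    _, _, ftype, m = min(cands)
    c1 = base + m.start()
    x1, x2 = len(m.group(1)), len(m.group(2))
    c2 = c1 + 1 + x1
    h1 = c2 + 1 + x2
    last = base + m.end() - 1
    return (ftype, (c1, c2, h1, last), (x1, x2))


def find_wrky_domains(
    protein: SequenceRecord, config: ScanConfig = ScanConfig()
) -> list[WrkyDomainHit]:
    """Locate every non-overlapping WRKY domain in a protein.

    Each accepted heptapeptide occurrence is paired with the nearest
    downstream zinc-finger match whose first Cys starts within the search
    window; occurrences with no finger in range are reported with type
    ``none`` so that truncated domains remain visible.
    """
    seq = protein.sequence.upper()
    hits: list[WrkyDomainHit] = []
    pos = 0
    pats = sorted(config.heptapeptides)
    while pos < len(seq):
        starts = [(seq.find(p, pos), p) for p in pats]
        starts = [(i, p) for i, p in starts if i != -1]
        if not starts:
            break
        start, pep = min(starts)
        hept_end = start + len(pep)
        win_start = hept_end
        win_end = min(len(seq), start + config.max_domain_span)
        # finger's first Cys must begin within the window after the heptapeptide
        best = None
        limit = min(hept_end + config.finger_search_window, len(seq))
        window = seq[win_start:win_end]
        m = _match_finger(window, win_start)
        if m is not None and m[1][0] < limit:
            best = m
        if best is None:
            hits.append(WrkyDomainHit(protein.id, start, pep, "none"))
            pos = hept_end
        else:
            ftype, offsets, spacers = best
            hits.append(WrkyDomainHit(protein.id, start, pep, ftype, offsets, spacers))
            pos = offsets[-1] + 1
    return hits


def classify_group(hits: Sequence[WrkyDomainHit]) -> str:
    """Group label from the hit multiset (order-independent).

    ≥2 complete domains → Group 1; a single C2HC domain → Group 3; a
    single C2H2 domain → Group 2; anything else → unclassified.
    """
    complete = [h for h in hits if h.complete]
    if len(complete) >= 2:
        return "1"
    if len(complete) == 1:
        return "3" if complete[0].finger_type == "C2HC" else "2"
    return "unclassified"


def assign_subgroup(
    member: FamilyMember,
    tree,
    labeled_references: Mapping[str, str],
) -> str:
    """Subgroup of the nearest labeled reference by patristic distance.

    *labeled_references* maps reference leaf labels to subgroup labels
    ("2a".."2e", or "1" for Group-1 C-terminal-domain references).  Ties in
    patristic distance are broken by the smallest clade (fewest leaves)
    containing both the member and the reference.  A single-domain protein
    whose nearest references are Group-1 C-terminal domains is re-labeled
    Group 1: the case of an apparent Group-2 gene that lost (or was
    mis-annotated at) its N-terminal domain.
    """
    if not labeled_references:
        raise ValueError("no labeled references supplied")
    import dendropy

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if member.protein_id not in taxa:
        raise KeyError(f"member {member.protein_id!r} not in tree")
    mt = taxa[member.protein_id]
    best = None
    for ref, label in sorted(labeled_references.items()):
        if ref not in taxa:
            raise KeyError(f"reference {ref!r} not in tree")
        rt = taxa[ref]
        d = pdm.patristic_distance(mt, rt)
        mrca = pdm.mrca(mt, rt)
        clade_size = len(mrca.leaf_nodes()) if mrca is not None else len(taxa)
        key = (d, clade_size, ref)
        if best is None or key < best[0]:
            best = (key, label)
    label = best[1]
    if label == "1":
        member.group = "1"
        member.subgroup = "none"
        return "none"
    member.subgroup = label
    return label


def map_domain_gene_structure(
    member: FamilyMember, gene: GeneModel, protein_length: int | None = None
) -> DomainGeneStructure:
    """Count introns (and phases) that interrupt the WRKY domain's CDS.

    The protein-level domain interval [heptapeptide start, finger end) is
    converted to CDS nucleotide coordinates (×3), then intron positions —
    junctions between consecutive CDS segments — are located within it.
    Phase = number of CDS nucleotides upstream of the junction mod 3
    (0: between codons; 1/2: after the first/second codon position).
    """
    cds_len = gene.cds_length
    if cds_len % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {cds_len} not divisible by 3")
    if protein_length is not None and cds_len // 3 - protein_length not in (0, 1):
        raise ValueError(
            f"{gene.gene_id}: CDS length {cds_len} does not match protein "
            f"length {protein_length} (±stop codon)"
        )
    # intron positions expressed as the count of CDS nucleotides 5' of them
    intron_breaks: list[int] = []
    acc = 0
    segs = gene.spliced_cds_intervals()
    for s, e in segs[:-1]:
        acc += e - s
        intron_breaks.append(acc)
    domain_intervals = [
        (h.heptapeptide_start * 3, h.end * 3) for h in member.hits
    ]
    in_domain: list[int] = []
    for b in intron_breaks:
        if any(lo < b < hi for lo, hi in domain_intervals):
            in_domain.append(b)
    phases = [b % 3 for b in in_domain]
    return DomainGeneStructure(
        gene_id=gene.gene_id,
        introns_in_domain=len(in_domain),
        domain_intron_phases=phases,
        introns_in_cds=len(intron_breaks),
    )


def scan_proteome(
    proteins: Iterable[SequenceRecord], config: ScanConfig = ScanConfig()
) -> list[FamilyMember]:
    """Scan a proteome and return the classified family members.

    Proteins with no heptapeptide hit at all are omitted; proteins with a
    heptapeptide but no finger are kept as ``unclassified`` for manual
    review, mirroring the manual-curation step of a family census.
    """
    members = []
    for rec in proteins:
        hits = find_wrky_domains(rec, config)
        if not hits:
            continue
        members.append(FamilyMember(rec.id, hits, classify_group(hits)))
    return members
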