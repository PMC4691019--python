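"""Readers and writers for the standard formats the pipeline touches.

Internal genomic coordinates are 0-based half-open throughout the package;
GFF3 input/output converts from/to the on-disk 1-based inclusive convention
at this boundary and nowhere else.  Gene "position" on a chromosome is its
rank by start coordinate among all annotated genes, strand ignored — the
unit in which the tandem-duplication distance rule is expressed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "select_longest_per_locus",
    "load_fixture_table",
    "read_newick",
    "write_newick",
]

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
_NUCLEOTIDE_CHARS = set("ACGTUNRYSWKMBDHV")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an alphabet tag (``protein``/``nucleotide``)."""

    id: str
    sequence: str
    alphabet: str = PROTEIN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        allowed = _PROTEIN_CHARS if self.alphabet == PROTEIN else _NUCLEOTIDE_CHARS
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} has characters {sorted(bad)} not in the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene locus: 0-based half-open coordinates, exons in genomic order."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    # (start, end, frame) per CDS segment, genomic order
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end (half-open)")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons ({s1},{e1}) ({s2},{e2})")
        self.cds_segments = sorted(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    def spliced_cds_intervals(self) -> list[tuple[int, int]]:
        """CDS segments ordered 5'→3' in transcript direction."""
        segs = [(s, e) for s, e, _ in self.cds_segments]
        return segs if self.strand == "+" else segs[::-1]


class GenomeAnnotation:
    """Ordered gene models per chromosome with per-chromosome rank index."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.chromosomes: dict[str, list[GeneModel]] = {}
        by_id: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            by_id[g.gene_id] = g
            self.chromosomes.setdefault(g.chromosome, []).append(g)
        self.genes = by_id
        self.rank: dict[str, int] = {}
        for chrom, models in self.chromosomes.items():
            models.sort(key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(models):
                self.rank[g.gene_id] = i

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]


@dataclass
class FixtureTable:
    table_id: str
    rows: pd.DataFrame


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _guess_alphabet(seq: str) -> str:
    letters = set(seq.upper())
    if letters <= _NUCLEOTIDE_CHARS:
        return NUCLEOTIDE
    return PROTEIN


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and whitespace-stripped; duplicate ids and
    empty files are rejected.  When *alphabet* is ``None`` it is guessed
    from the characters present (nucleotide if everything is an IUPAC
    nucleotide code, protein otherwise).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        alpha = alphabet or _guess_alphabet(seq)
        records.append(SequenceRecord(rec.id, seq, alpha))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene/mRNA/exon/CDS features into a :class:`GenomeAnnotation`.

    Coordinates are converted from GFF3's 1-based inclusive to the internal
    0-based half-open convention.  Exons/CDS are attached through their
    ``Parent`` mRNA; a CDS whose parent cannot be resolved to a gene is an
    error, as are overlapping exons within one mRNA.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    pending: list[tuple[str, str, int, int, int | None]] = []  # kind, parent, s, e, frame
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, frame, attrs = fields[:9]
            start0, end0 = int(start) - 1, int(end)
            a = _parse_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                genes[gid] = dict(
                    chrom=chrom, start=start0, end=end0, strand=strand, exons=[], cds=[]
                )
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise ValueError(f"mRNA feature needs ID and Parent: {line!r}")
                mrna_to_gene[mid] = parent
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent is None:
                    raise ValueError(f"{ftype} feature without Parent: {line!r}")
                fr = int(frame) if ftype == "CDS" and frame in "012" else None
                pending.append((ftype, parent, start0, end0, fr))
    for ftype, parent, s, e, fr in pending:
        gid = mrna_to_gene.get(parent, parent if parent in genes else None)
        if gid is None or gid not in genes:
            raise ValueError(f"{ftype} at ({s + 1},{e}) has unresolvable parent {parent!r}")
        if ftype == "exon":
            genes[gid]["exons"].append((s, e))
        else:
            genes[gid]["cds"].append((s, e, 0 if fr is None else fr))
    models = []
    for gid, g in genes.items():
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=g["chrom"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                exons=g["exons"],
                cds_segments=g["cds"],
            )
        )
    return GenomeAnnotation(models)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation back out (gene + one mRNA + exon/CDS per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            for g in annotation.chromosomes[chrom]:
                base = f"{chrom}\twrkyfamkit\t"
                tail = f"\t.\t{g.strand}\t"
                fh.write(f"{base}gene\t{g.start + 1}\t{g.end}{tail}.\tID={g.gene_id}\n")
                mid = f"{g.gene_id}.t1"
                fh.write(f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}.\tID={mid};Parent={g.gene_id}\n")
                for s, e in g.exons:
                    fh.write(f"{base}exon\t{s + 1}\t{e}{tail}.\tParent={mid}\n")
                for s, e, fr in g.cds_segments:
                    fh.write(f"{base}CDS\t{s + 1}\t{e}{tail}{fr}\tParent={mid}\n")


# ---------------------------------------------------------------------------
# Longest-isoform selection
# ---------------------------------------------------------------------------

def select_longest_per_locus(
    records: Sequence[SequenceRecord], locus_map: Mapping[str, str]
) -> list[SequenceRecord]:
    """Keep one record per locus: the longest, ties broken by smallest id.

    The proteome-preparation rule for loci with several annotated isoforms.
    """
    best: dict[str, SequenceRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.id not in locus_map:
            raise KeyError(f"record {rec.id!r} missing from locus_map")
        locus = locus_map[rec.id]
        cur = best.get(locus)
        if cur is None:
            best[locus] = rec
            order.append(locus)
        elif len(rec) > len(cur) or (len(rec) == len(cur) and rec.id < cur.id):
            best[locus] = rec
    return [best[locus] for locus in order]


# ---------------------------------------------------------------------------
# Packaged fixture tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "T1_tandem": "table1_tandem.tsv",
    "T2_synteny": "table2_synteny.tsv",
    "T3_branchsite": "table3_branchsite.tsv",
}


def load_fixture_table(table_id: str) -> FixtureTable:
    """Load a packaged reference table from a genome-wide pear WRKY survey.

    ``T1_tandem``: 15 tandem clusters (33 genes); ``T2_synteny``: 61
    segmentally duplicated pairs with anchor counts, block E-values and
    anchor Ks summaries; ``T3_branchsite``: the branch-site model fits
    (alternative/null) for the positively selected Group-3 lineage.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture table {table_id!r}; one of {sorted(_FIXTURE_FILES)}")
    ref = importlib.resources.files("wrkyfamkit.data") / _FIXTURE_FILES[table_id]
    with importlib.resources.as_file(ref) as p:
        # keep_default_na: the literal hypothesis label "null" must survive
        rows = pd.read_csv(p, sep="\t", keep_default_na=False, na_values=[""])
    return FixtureTable(table_id=table_id, rows=rows)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path):
    """Read a Newick tree (dendropy ``Tree``); malformed input raises with position."""
    import dendropy

    text = Path(path).read_text()
    depth = 0
    for i, ch in enumerate(text):
        depth += ch == "("
        depth -= ch == ")"
        if depth < 0:
            raise ValueError(f"unbalanced ')' at position {i} in {path}")
    if depth != 0:
        raise ValueError(f"{depth} unclosed '(' in {path}")
    # internal labels (e.g. bootstrap supports) stay plain node labels
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
    )
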