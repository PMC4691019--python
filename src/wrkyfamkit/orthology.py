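"""Seed-ortholog and inparalog detection between two proteomes.

Ortholog groups are built the reciprocal-best-hit way: a seed pair is a
two-way best hit between the proteomes; each side then accretes
inparalogs — same-proteome sequences scoring at least as high to their
own seed as to anything in the other proteome.  Similarity is
Smith–Waterman local alignment score (BLOSUM62, affine gaps),
symmetrized over the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

__all__ = ["OrthologyGroup", "pairwise_similarity", "build_ortholog_groups"]


@dataclass
class OrthologyGroup:
    seed_a: str
    seed_b: str
    seed_score: float
    inparalogs_a: list[tuple[str, float]] = field(default_factory=list)  # (id, confidence)
    inparalogs_b: list[tuple[str, float]] = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def pairwise_similarity(
    proteome_a: Sequence[SequenceRecord], proteome_b: Sequence[SequenceRecord]
) -> dict[tuple[str, str], float]:
    """All-vs-all local alignment scores between (and within) two proteomes.

    Returns a symmetric score table over the union of both proteomes
    (within-proteome scores are needed for the inparalog rule).  Scores
    are symmetrized by the maximum of the two alignment directions.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    for rec in list(proteome_a) + list(proteome_b):
        if not rec.sequence:
            raise ValueError(f"empty sequence {rec.id!r}")
    al = _aligner()
    everything = list(proteome_a) + [r for r in proteome_b if r.id not in {x.id for x in proteome_a}]
    scores: dict[tuple[str, str], float] = {}
    for i, ra in enumerate(everything):
        for rb in everything[i:]:
            s = float(al.score(ra.sequence, rb.sequence))
            s = max(s, float(al.score(rb.sequence, ra.sequence)))
            scores[(ra.id, rb.id)] = s
            scores[(rb.id, ra.id)] = s
    return scores


def build_ortholog_groups(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    scores: dict[tuple[str, str], float] | None = None,
    score_floor: float = 40.0,
) -> list[OrthologyGroup]:
    """Ortholog groups from two-way best hits plus the inparalog rule.

    Seeds are mutual best hits above the score floor (ties broken by id
    order).  A non-seed sequence joins its proteome's side of a group when
    it scores at least as high to that seed as to every sequence of the
    other proteome; its confidence is that score relative to the
    seed–seed score.  Groups are disjoint: each inparalog joins only its
    best seed.
    """
    if scores is None:
        scores = pairwise_similarity(proteome_a, proteome_b)
    ids_a = [r.id for r in proteome_a]
    ids_b = [r.id for r in proteome_b]

    def best_hit(x: str, targets: list[str]) -> tuple[str, float] | None:
        cands = [(scores.get((x, t), 0.0), t) for t in targets if t != x]
        cands = [(s, t) for s, t in cands if s >= score_floor]
        if not cands:
            return None
        # deterministic: highest score, then lexicographically smallest id
        top = max(s0 for s0, _ in cands)
        return min(t0 for s0, t0 in cands if s0 == top), top

    seeds = []
    for a in sorted(ids_a):
        hit = best_hit(a, ids_b)
        if hit is None:
            continue
        b, sab = hit
        back = best_hit(b, ids_a)
        if back is not None and back[0] == a:
            seeds.append(OrthologyGroup(a, b, sab))

    assigned: set[str] = set()
    for g in seeds:
        assigned.update((g.seed_a, g.seed_b))
    for side_ids, other_ids, attr, seed_attr in (
        (ids_a, ids_b, "inparalogs_a", "seed_a"),
        (ids_b, ids_a, "inparalogs_b", "seed_b"),
    ):
        for x in sorted(side_ids):
            if x in assigned:
                continue
            best_cross = max(
                (scores.get((x, y), 0.0) for y in other_ids), default=0.0
            )
            cands = []
            for g in seeds:
                seed = getattr(g, seed_attr)
                s = scores.get((x, seed), 0.0)
                if s >= score_floor and s >= best_cross:
                    cands.append((s, seed, g))
            if not cands:
                continue
            s, _, g = max(cands, key=lambda c: (c[0], c[1]))
            conf = s / g.seed_score if g.seed_score > 0 else 0.0
            getattr(g, attr).append((x, conf))
            assigned.add(x)
    return seeds
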