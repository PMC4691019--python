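import numpy as np
import pytest
from scipy import stats as sstats

from wrkyfamkit.duplication import (
    SyntenyBlock,
    classify_duplication_types,
    find_synteny_blocks,
    find_tandem_clusters,
    infer_homology_pairs,
    summarize_block_ks,
)
from wrkyfamkit.io_formats import GeneModel, GenomeAnnotation, load_fixture_table


def annotation_with_ranks(n=40, chrom="Chr1"):
    genes = [
        GeneModel(f"g{i}", chrom, i * 1000, i * 1000 + 500, "+")
        for i in range(n)
    ]
    return GenomeAnnotation(genes)


class TestTandem:
    def test_gap_within_ten_clusters(self):
        ann = annotation_with_ranks()
        (c,) = find_tandem_clusters(ann, ["g5", "g12"])
        assert c.genes == ["g5", "g12"] and c.ranks == [5, 12]

    def test_gap_beyond_ten_does_not_cluster(self):
        ann = annotation_with_ranks()
        assert find_tandem_clusters(ann, ["g5", "g20"]) == []

    def test_single_linkage_transitivity(self):
        ann = annotation_with_ranks()
        (c,) = find_tandem_clusters(ann, ["g5", "g12", "g20"])
        assert c.genes == ["g5", "g12", "g20"]

    def test_idempotent_and_order_invariant(self):
        ann = annotation_with_ranks()
        fam = ["g20", "g5", "g12", "g33"]
        r1 = find_tandem_clusters(ann, fam)
        r2 = find_tandem_clusters(ann, list(reversed(fam)))
        assert [(c.chromosome, c.genes) for c in r1] == [
            (c.chromosome, c.genes) for c in r2
        ]

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError):
            find_tandem_clusters(annotation_with_ranks(), ["nope"])


def two_chromosome_annotation(n=60):
    genes = [GeneModel(f"a{i}", "Chr1", i * 1000, i * 1000 + 500, "+") for i in range(n)]
    genes += [GeneModel(f"b{i}", "Chr2", i * 1000, i * 1000 + 500, "+") for i in range(n)]
    return GenomeAnnotation(genes)


class TestSynteny:
    def planted(self, n_anchors, reverse=False):
        ann = two_chromosome_annotation()
        hom = [("a30", "b30")]
        offsets = range(1, n_anchors + 1)
        for k in offsets:
            j = 30 - k if reverse else 30 + k
            hom.append((f"a{30 + k}", f"b{j}"))
        return ann, hom

    def test_planted_block_recovered_with_anchor_count(self):
        ann, hom = self.planted(8)
        (block,) = find_synteny_blocks(ann, [("a30", "b30")], hom)
        assert block.n_anchors == 8
        assert block.evalue <= 0.01

    def test_two_homolog_pairs_below_min_pairs(self):
        ann, hom = self.planted(2)
        assert find_synteny_blocks(ann, [("a30", "b30")], hom) == []

    def test_inverted_block_still_chains(self):
        ann, hom = self.planted(8, reverse=True)
        (block,) = find_synteny_blocks(ann, [("a30", "b30")], hom)
        assert block.n_anchors == 8

    def test_evalue_decreases_with_anchor_count(self):
        evs = []
        for m in (4, 6, 8, 10):
            ann, hom = self.planted(m)
            (block,) = find_synteny_blocks(ann, [("a30", "b30")], hom,
                                           evalue_cutoff=1e9)
            evs.append(block.evalue)
        assert evs == sorted(evs, reverse=True)

    def test_window_smaller_than_min_pairs_errors(self):
        ann, hom = self.planted(4)
        with pytest.raises(ValueError):
            find_synteny_blocks(ann, [("a30", "b30")], hom, window=2, min_pairs=3)


class TestClassification:
    def test_precedence_rules(self):
        ann = two_chromosome_annotation()
        fam = ["a10", "a12", "a30", "b30", "a50"]
        hom = [("a10", "a12"), ("a30", "b30")]
        clusters = find_tandem_clusters(ann, fam)
        blocks = [SyntenyBlock("a30", "b30", [("x", "y")] * 3, 1e-5)]
        types = {
            t.gene_id: t.duplication_class
            for t in classify_duplication_types(ann, fam, hom, blocks, clusters)
        }
        assert types == {
            "a10": "tandem",       # clustered with a12 (rank gap 2)
            "a12": "tandem",
            "a30": "segmental",    # block membership beats everything
            "b30": "segmental",
            "a50": "singleton",    # no family homolog
        }

    def test_segmental_beats_tandem(self):
        ann = two_chromosome_annotation()
        fam = ["a10", "a12"]
        hom = [("a10", "a12")]
        clusters = find_tandem_clusters(ann, fam)
        blocks = [SyntenyBlock("a10", "a12", [("x", "y")] * 3, 1e-5)]
        types = {t.gene_id: t.duplication_class
                 for t in classify_duplication_types(ann, fam, hom, blocks, clusters)}
        assert set(types.values()) == {"segmental"}

    def test_proximal_vs_dispersed(self):
        ann = two_chromosome_annotation()
        fam = ["a10", "a16", "a40", "b5"]
        hom = [("a10", "a16"), ("a40", "b5")]
        # suppress tandem clustering by using distance 3 for clusters only
        clusters = find_tandem_clusters(ann, fam, max_gene_distance=3)
        types = {t.gene_id: t.duplication_class
                 for t in classify_duplication_types(ann, fam, hom, [], clusters)}
        assert types["a10"] == "proximal" and types["a16"] == "proximal"
        assert types["a40"] == "dispersed" and types["b5"] == "dispersed"


class TestBlockKs:
    def test_identical_anchor_cds_gives_zero(self):
        block = SyntenyBlock("x", "y", [("p", "q"), ("r", "s")], 1e-4)
        cds = {k: "ATGGCTAAGGTT" for k in "pqrs"}
        summarize_block_ks(block, cds)
        assert block.mean_ks == 0.0 and block.sd_ks == 0.0 and block.ks_defined

    def test_single_usable_anchor_sd_zero(self):
        block = SyntenyBlock("x", "y", [("p", "q")], 1e-4)
        cds = {"p": "ATGGGTGGTGGT", "q": "ATGGGCGGTGGT"}
        summarize_block_ks(block, cds)
        assert block.ks_defined and block.mean_ks > 0 and block.sd_ks == 0.0

    def test_all_saturated_flagged_undefined(self):
        block = SyntenyBlock("x", "y", [("p", "q")], 1e-4)
        cds = {"p": "TTA" * 10, "q": "CTG" * 10}
        summarize_block_ks(block, cds)
        assert not block.ks_defined and np.isnan(block.mean_ks)

    def test_simulated_divergence_recovered(self):
        """Anchors mutated at known synonymous divergence: mean Ks over
        replicates lands within 2 SE of the value implied by the planted
        mismatch rate."""
        rng = np.random.default_rng(7)
        from wrkyfamkit.selection import CODONS, ng86_kaks

        # codon families with exactly one synonymous site (the 4-fold third
        # position) and no synonymous first-position exchanges
        fourfold = [c for c in CODONS if c[:2] in ("GC", "GG", "CC", "AC", "GT", "TC")]
        ks_vals = []
        for i in range(12):
            codons = rng.choice(fourfold, size=120)
            b_codons = [
                c[:2] + rng.choice(list("ACGT")) if rng.random() < 0.25 else c
                for c in codons
            ]
            ks_vals.append(ng86_kaks("".join(codons), "".join(b_codons)).ks)
        mean = np.mean(ks_vals)
        se = np.std(ks_vals, ddof=1) / np.sqrt(len(ks_vals))
        # S = 1 per codon, so ps equals the planted per-codon mismatch rate
        ps = 0.25 * 0.75
        expected_ks = -0.75 * np.log(1 - 4 * ps / 3)
        assert abs(mean - expected_ks) < 2 * se + 0.02


class TestFixtureConsistency:
    def test_tables_match_reported_family_fractions(self):
        t1 = load_fixture_table("T1_tandem")
        genes1 = {g for row in t1.rows.genes for g in row.split(",")}
        t2 = load_fixture_table("T2_synteny")
        genes2 = set(t2.rows.gene_a) | set(t2.rows.gene_b)
        assert len(genes1) == 33 and len(genes1) / 103 == pytest.approx(0.32, abs=0.005)
        assert len(genes2) == 57 and len(genes2) / 103 == pytest.approx(0.553, abs=0.001)


def test_infer_homology_finds_planted_copies(synthetic_genome):
    hom = set(infer_homology_pairs(synthetic_genome.proteins))
    for _, row in synthetic_genome.truth_anchors.iterrows():
        assert tuple(sorted((row.anchor_a, row.anchor_b))) in hom


def test_synthetic_truth_tables_recovered_exactly(synthetic_genome):
    g = synthetic_genome
    fam = sorted(g.truth_members.gene_id)
    hom = infer_homology_pairs(g.proteins)
    famset = set(fam)
    clusters = find_tandem_clusters(g.annotation, fam)
    assert [",".join(c.genes) for c in clusters] == g.truth_tandem.genes.tolist()
    blocks = find_synteny_blocks(
        g.annotation, [p for p in hom if p[0] in famset and p[1] in famset], hom
    )
    found = {tuple(sorted((b.gene_a, b.gene_b))): b.n_anchors for b in blocks}
    want = {
        tuple(sorted((r.gene_a, r.gene_b))): r.n_anchors
        for _, r in g.truth_segmental.iterrows()
    }
    assert found == want
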