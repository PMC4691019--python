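import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats as sstats

from wrkyfamkit.io_formats import SequenceRecord
from wrkyfamkit.selection import (
    CODONS,
    CODON_INDEX,
    CodonModel,
    STOP_CODONS,
    branch_site_lrt,
    build_generator,
    codon_log_likelihood,
    equal_codon_frequencies,
    f3x4_frequencies,
    fit_branch_site_A,
    likelihood_ratio_test,
    ng86_kaks,
    transition_matrices,
)
from wrkyfamkit.synthetic_data import BranchSiteSimSpec, simulate_codon_alignment

from Bio.Data.CodonTable import unambiguous_dna_by_id

_FWD = unambiguous_dna_by_id[1].forward_table


# ---------------------------------------------------------------------------
# Independent NG86 oracle: brute-force over sites and pathways
# ---------------------------------------------------------------------------

def brute_syn_sites(codon):
    """Fraction of non-stop single-nucleotide changes that are synonymous,
    summed over the three positions."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            valid += 1
            syn += _FWD[mut] == _FWD[codon]
        if valid:
            total += syn / valid
    return total


def brute_pathways(ca, cb):
    diffs = [k for k in range(3) if ca[k] != cb[k]]
    paths = []
    for perm in itertools.permutations(diffs):
        cur, steps, ok = ca, [], True
        for pos in perm:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for x, y in steps:
            if _FWD[x] == _FWD[y]:
                sd += 1
            else:
                nd += 1
    n = max(len(paths), 1)
    return sd / n, nd / n


def brute_ng86(cds_a, cds_b):
    ca = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    cb = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    S = sum((brute_syn_sites(x) + brute_syn_sites(y)) / 2 for x, y in zip(ca, cb))
    N = 3 * len(ca) - S
    Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        ds, dn = brute_pathways(x, y)
        Sd += ds
        Nd += dn
    return S, N, Sd, Nd


class TestNg86:
    def test_identical_sequences_zero(self):
        r = ng86_kaks("ATGGCTAAG", "ATGGCTAAG")
        assert r.ka == 0 and r.ks == 0

    def test_glycine_codon_example(self):
        # two four-fold degenerate codons: S=2, N=4; one synonymous change
        r = ng86_kaks("GGTGGA", "GGCGGA")
        assert (r.S, r.N, r.Sd, r.Nd) == (2.0, 4.0, 1.0, 0.0)
        assert r.ka == 0
        assert r.ks == pytest.approx(-0.75 * np.log(1 / 3), abs=1e-9)

    def test_site_counts_sum_to_sequence_length(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            codons = rng.choice(CODONS, size=5)
            r = ng86_kaks("".join(codons), "".join(codons))
            assert r.S + r.N == pytest.approx(15.0)

    def test_agrees_with_bruteforce_on_random_two_codon_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = "".join(rng.choice(CODONS, size=2))
            b = "".join(rng.choice(CODONS, size=2))
            r = ng86_kaks(a, b)
            S, N, Sd, Nd = brute_ng86(a, b)
            assert r.S == pytest.approx(S)
            assert r.N == pytest.approx(N)
            assert r.Sd == pytest.approx(Sd)
            assert r.Nd == pytest.approx(Nd)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = "".join(rng.choice(CODONS, size=4))
            b = "".join(rng.choice(CODONS, size=4))
            r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
            assert (r1.ka, r1.ks, r1.S, r1.N, r1.Sd, r1.Nd) == (
                r2.ka, r2.ks, r2.S, r2.N, r2.Sd, r2.Nd,
            )

    def test_saturation_flagged_not_raised(self):
        # maximally divergent synonymous-rich comparison saturates ps
        a = "TTA" * 10  # Leu
        b = "CTG" * 10  # Leu via two changes, all synonymous pathways
        r = ng86_kaks(a, b)
        assert r.saturated and np.isnan(r.ks)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            ng86_kaks("ATGG", "ATGG")
        with pytest.raises(ValueError, match="internal stop"):
            ng86_kaks("TAAATG", "ATGATG")
        with pytest.raises(ValueError, match="lengths differ"):
            ng86_kaks("ATGATG", "ATG")


class TestCodonModelMachinery:
    def test_generator_rows_sum_to_zero(self):
        pi = equal_codon_frequencies()
        for omega in (0.1, 1.0, 5.0):
            q = build_generator(2.0, omega, pi)
            np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_transition_matrices_are_stochastic(self):
        model = CodonModel(2.0, 0.3, 4.0, 0.5, 0.3)
        eigs = transition_matrices(model)
        for w, eig in eigs.items():
            for t in (0.0, 0.01, 0.1, 1.0, 10.0):
                p = eig.expm(t)
                np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
                assert (p >= 0).all()

    def test_f3x4_positive_and_normalized(self):
        pi = f3x4_frequencies(["ATGAAACCC", "ATGTTTGGG"])
        assert pi.shape == (61,)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()

    def test_model_constraints_validated(self):
        with pytest.raises(ValueError):
            CodonModel(2.0, 1.5, 2.0, 0.5, 0.3)  # omega0 outside (0,1)
        with pytest.raises(ValueError):
            CodonModel(2.0, 0.5, 0.5, 0.5, 0.3)  # omega2 < 1
        with pytest.raises(ValueError):
            CodonModel(2.0, 0.5, 2.0, 0.9, 0.3)  # proportions > 1


class TestCodonLikelihood:
    model = CodonModel(kappa=2.0, omega0=0.5, omega2=2.0, p0=0.6, p1=0.3)

    def test_zero_branch_identical_pair_gives_pi(self):
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        recs = [SequenceRecord("A", "ATG", "nucleotide"),
                SequenceRecord("B", "ATG", "nucleotide")]
        lnl = codon_log_likelihood(recs, tree, self.model)
        assert np.exp(lnl) == pytest.approx(1 / 61)

    def test_marginalizing_a_leaf_recovers_equilibrium(self):
        tree = dendropy.Tree.get(data="(A:0.3,B:0.7);", schema="newick")
        total = 0.0
        for c in CODONS:
            recs = [SequenceRecord("A", "ATG", "nucleotide"),
                    SequenceRecord("B", c, "nucleotide")]
            total += np.exp(codon_log_likelihood(recs, tree, self.model))
        assert total == pytest.approx(1 / 61, rel=1e-9)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(CODONS, 12)) for _ in range(4)]
        recs = [SequenceRecord(l, s, "nucleotide") for l, s in zip("ABCD", rows)]
        t1 = dendropy.Tree.get(
            data="((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.15);", schema="newick")
        t2 = dendropy.Tree.get(
            data="((C:0.3,D:0.1):0.10,(A:0.1,B:0.2):0.10);", schema="newick")
        l1 = codon_log_likelihood(recs, t1, self.model)
        l2 = codon_log_likelihood(recs, t2, self.model)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_matches_bruteforce_with_foreground(self):
        """Exhaustive sum over internal states on a 3-taxon star tree."""
        model = CodonModel(kappa=2.5, omega0=0.3, omega2=4.0, p0=0.5, p1=0.3)
        eigs = transition_matrices(model)
        lens = {"A": 0.2, "B": 0.15, "C": 0.3}
        seqs = {"A": "ATGAAG", "B": "ATGAGG", "C": "TTGAAG"}
        tree = dendropy.Tree.get(data="(A:0.2,B:0.15,C:0.3);", schema="newick")
        recs = [SequenceRecord(l, seqs[l], "nucleotide") for l in "ABC"]
        for fg in ("A", "C"):
            expected = 0.0
            lnl_expected = 0.0
            for site in range(2):
                site_l = 0.0
                for prob, (wb, wf) in zip(model.proportions, model.omega_classes):
                    pmat = {l: eigs[wf if l == fg else wb].expm(lens[l]) for l in "ABC"}
                    s = 0.0
                    for root in range(61):
                        term = model.pi[root]
                        for l in "ABC":
                            obs = CODON_INDEX[seqs[l][3 * site : 3 * site + 3]]
                            term *= pmat[l][root, obs]
                        s += term
                    site_l += prob * s
                lnl_expected += np.log(site_l)
            got = codon_log_likelihood(recs, tree, model, foreground=fg)
            assert got == pytest.approx(lnl_expected, abs=1e-9)


class TestBranchSiteFit:
    def simulate(self, omega2, seed, n_codons=150):
        nwk = ("(((A:0.5,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.08,"
               "((E:0.15,F:0.15):0.08,(G:0.15,H:0.15):0.08):0.08);")
        spec = BranchSiteSimSpec(
            tree=nwk, foreground="A", n_codons=n_codons, kappa=2.0,
            p0=0.4, p1=0.4, p2a=0.1, p2b=0.1, omega0=0.2, omega2=omega2, seed=seed,
        )
        recs, _ = simulate_codon_alignment(spec)
        return recs, dendropy.Tree.get(data=nwk, schema="newick")

    def test_nesting_and_model_a_constraint(self):
        recs, tree = self.simulate(1.0, seed=5)
        alt, null, lrt = branch_site_lrt(recs, tree, "A", seed=0)
        assert alt.lnL >= null.lnL
        assert lrt.statistic >= 0
        for fit in (alt, null):
            assert fit.p0 + fit.p1 + fit.p2a + fit.p2b == pytest.approx(1.0)
            if fit.p2b > 1e-9:
                assert fit.p2a / fit.p2b == pytest.approx(fit.p0 / fit.p1, rel=1e-6)
        assert null.omega2 == 1.0

    def test_positive_selection_detected_when_planted(self):
        recs, tree = self.simulate(8.0, seed=2, n_codons=300)
        alt, null, lrt = branch_site_lrt(recs, tree, "A", seed=0)
        assert alt.omega2 > 1.0
        assert lrt.p_value < 0.01

    def test_unknown_foreground_errors(self):
        recs, tree = self.simulate(1.0, seed=1)
        with pytest.raises(KeyError):
            fit_branch_site_A(recs, tree, "Z", "alternative")

    def test_bad_hypothesis_errors(self):
        recs, tree = self.simulate(1.0, seed=1)
        with pytest.raises(ValueError):
            fit_branch_site_A(recs, tree, "A", "both")


class TestLrt:
    def test_published_lnls_give_expected_statistic(self):
        res = likelihood_ratio_test(-9212.750, -9230.368)
        assert res.statistic == pytest.approx(35.236, abs=1e-3)
        assert res.df == 1
        assert res.p_value < 0.01

    def test_equal_lnls_give_zero_and_p_one(self):
        res = likelihood_ratio_test(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        res = likelihood_ratio_test(-100.0, -100.0 - 6.635 / 2)
        assert res.p_value == pytest.approx(0.01, rel=1e-3)
        assert res.statistic == pytest.approx(
            sstats.chi2.ppf(0.99, 1), rel=1e-4
        )

    def test_mixture_null_halves_positive_statistic_pvalue(self):
        plain = likelihood_ratio_test(-10.0, -12.0)
        mixed = likelihood_ratio_test(-10.0, -12.0, mixture_null=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)

    def test_alt_below_null_is_an_optimizer_failure(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            likelihood_ratio_test(-101.0, -100.0)
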