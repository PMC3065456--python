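import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from pseudochron.codonml import (
    CODON_INDEX,
    CODONS,
    N_CODONS,
    CodonEngine,
    build_rate_matrix,
    codon_frequencies,
    fit_branch_model,
    fit_m0,
    log_likelihood,
    lrt,
    mark_foreground,
)
from pseudochron.codonml import test_vs_average as vs_average
from pseudochron.codonml import test_vs_neutral as vs_neutral
from pseudochron.seqio import CodonAlignment, SequenceRecord
from pseudochron.simgen import SimConfig, simulate_alignment, pick_foreground


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True,
                          suppress_internal_node_taxa=True)
    t.is_rooted = True
    return t


def _aln(seqs):
    return CodonAlignment(
        [SequenceRecord(k, v) for k, v in seqs.items()],
        ref_id=next(iter(seqs)),
    )


def oracle_rate_matrix(kappa, omega, pi):
    """Naive triple-loop GY94 generator, independent of the engine."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    code = unambiguous_dna_by_id[1].forward_table
    ts = ({"A", "G"}, {"C", "T"})
    Q = np.zeros((61, 61))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            r = pi[j]
            if set(diffs[0]) in ts:
                r *= kappa
            if code[ci] != code[cj]:
                r *= omega
            Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -(pi * np.diag(Q)).sum()


def oracle_loglik(seqs, branches, kappa, omega, pi):
    """Brute-force likelihood for ((a,b)n,c(,d on n2)) style small trees.

    ``branches``: dict of branch lengths keyed by node name; enumeration over
    every internal-state assignment (61**n_internal per site).
    """
    Q = oracle_rate_matrix(kappa, omega, pi)
    P = {k: expm(Q * t) for k, t in branches.items()}
    names = sorted(seqs)
    n_sites = len(next(iter(seqs.values()))) // 3
    codes = {
        k: [CODON_INDEX[v[i : i + 3]] for i in range(0, len(v), 3)]
        for k, v in seqs.items()
    }
    ll = 0.0
    if len(names) == 3:  # ((a,b)n,c)root
        for s in range(n_sites):
            xa, xb, xc = (codes[n][s] for n in names)
            tot = sum(
                pi[r] * P["n"][r, n] * P[names[0]][n, xa]
                * P[names[1]][n, xb] * P[names[2]][r, xc]
                for r in range(61) for n in range(61)
            )
            ll += np.log(tot)
    else:  # ((a,b)n1,(c,d)n2)root
        for s in range(n_sites):
            xa, xb, xc, xd = (codes[n][s] for n in names)
            tot = 0.0
            for r in range(61):
                left = sum(
                    P["n1"][r, n] * P[names[0]][n, xa] * P[names[1]][n, xb]
                    for n in range(61)
                )
                right = sum(
                    P["n2"][r, n] * P[names[2]][n, xc] * P[names[3]][n, xd]
                    for n in range(61)
                )
                tot += pi[r] * left * right
            ll += np.log(tot)
    return ll


class TestRateMatrix:
    pi_random = np.random.default_rng(7).dirichlet(np.ones(61) * 5)

    @pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.5, 0.3),
                                             (0.5, 4.0)])
    def test_rows_sum_to_zero(self, kappa, omega):
        Q = build_rate_matrix(kappa, omega, self.pi_random)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_multi_step_entries_are_zero(self):
        Q = build_rate_matrix(2.0, 0.5, self.pi_random)
        i, j = CODON_INDEX["ATG"], CODON_INDEX["GCA"]
        assert Q[i, j] == 0.0
        i, j = CODON_INDEX["AAA"], CODON_INDEX["AGG"]
        assert Q[i, j] == 0.0

    def test_uniform_neutral_model_is_symmetric(self):
        pi = np.full(61, 1 / 61)
        Q = build_rate_matrix(1.0, 1.0, pi, scale=False)
        off = Q[~np.eye(61, dtype=bool)]
        vals = np.unique(np.round(off[off > 0], 15))
        assert len(vals) == 1  # all single-step rates identical

    def test_detailed_balance(self):
        Q = build_rate_matrix(3.0, 0.2, self.pi_random)
        flux = self.pi_random[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-15

    def test_unit_expected_rate(self):
        Q = build_rate_matrix(2.0, 0.5, self.pi_random)
        assert abs(-(self.pi_random * np.diag(Q)).sum() - 1.0) < 1e-12

    def test_matches_naive_construction(self):
        mine = build_rate_matrix(2.3, 0.6, self.pi_random)
        naive = oracle_rate_matrix(2.3, 0.6, self.pi_random)
        assert np.abs(mine - naive).max() < 1e-14

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, np.zeros(61))


class TestCodonFrequencies:
    counts = np.random.default_rng(3).integers(0, 50, 61).astype(float)

    @pytest.mark.parametrize("model", ["equal", "F1x4", "F3x4", "empirical"])
    def test_valid_distribution(self, model):
        pi = codon_frequencies(self.counts, model)
        assert pi.shape == (61,)
        assert abs(pi.sum() - 1) < 1e-12
        assert (pi > 0).all()

    def test_equal_is_uniform(self):
        assert np.allclose(codon_frequencies(self.counts, "equal"), 1 / 61)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            codon_frequencies(self.counts, "F61x1")


class TestLogLikelihood:
    def test_zero_branch_limit_is_log_pi(self):
        aln = _aln({"a": "ATG", "b": "ATG"})
        tree = _tree("(a:0.0,b:0.0);")
        pi = np.full(61, 1 / 61)
        ll = log_likelihood(aln, tree, 2.0, 1.0, freqs=pi)
        assert abs(ll - np.log(pi[CODON_INDEX["ATG"]])) < 1e-5

    def test_three_taxon_brute_force(self):
        pi = np.random.default_rng(0).dirichlet(np.ones(61) * 5)
        seqs = {"a": "ATGCGA", "b": "ATACGG", "c": "TTGCGA"}
        want = oracle_loglik(
            seqs, {"a": 0.1, "b": 0.25, "c": 0.4, "n": 0.15}, 2.3, 0.6, pi
        )
        tree = _tree("((a:0.1,b:0.25):0.15,c:0.4);")
        got = log_likelihood(_aln(seqs), tree, 2.3, 0.6, freqs=pi)
        assert abs(got - want) < 1e-8

    def test_rerooting_invariance(self):
        pi = np.random.default_rng(1).dirichlet(np.ones(61) * 3)
        seqs = {"a": "ATGCGAAAA", "b": "ATACGGAAG", "c": "TTGCGAACA",
                "d": "CTGAGATCA"}
        aln = _aln(seqs)
        t1 = _tree("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.07);")
        t2 = _tree("(a:0.1,(b:0.2,((c:0.3,d:0.15):0.07):0.05):0.0);")
        # same unrooted tree: edge (a..b) split differently
        l1 = log_likelihood(aln, t1, 1.7, 0.9, freqs=pi)
        t3 = _tree("((b:0.2,(c:0.3,d:0.15):0.12):0.04,a:0.06);")
        l3 = log_likelihood(aln, t3, 1.7, 0.9, freqs=pi)
        assert abs(l1 - l3) < 1e-8

    def test_tip_order_invariance(self):
        pi = np.full(61, 1 / 61)
        seqs = {"a": "ATGCGA", "b": "ATACGG", "c": "TTGCGA"}
        tree = _tree("((a:0.1,b:0.25):0.15,c:0.4);")
        l1 = log_likelihood(_aln(seqs), tree, 2.0, 0.5, freqs=pi)
        rev = dict(reversed(list(seqs.items())))
        l2 = log_likelihood(_aln(rev), tree, 2.0, 0.5, freqs=pi)
        assert abs(l1 - l2) < 1e-10

    def test_stop_codon_rejected_when_unmasked(self):
        seqs = {"a": "ATGTGA", "b": "ATGCGA", "c": "ATGCGA"}
        tree = _tree("((a:0.1,b:0.2):0.1,c:0.2);")
        with pytest.raises(ValueError, match="a.*site 2|stop"):
            log_likelihood(_aln(seqs), tree, 2.0, 0.5, mask="none")
        # default policy masks the offending column instead
        log_likelihood(_aln(seqs), tree, 2.0, 0.5)


class TestLRT:
    @pytest.mark.parametrize("stat,p", [(3.841, 0.050), (6.635, 0.010)])
    def test_chi_square_quantiles(self, stat, p):
        res = lrt(-100.0 + stat / 2, -100.0, df=1)
        assert res.p_value == pytest.approx(p, abs=5e-4)

    def test_zero_difference_gives_p_one(self):
        assert lrt(-50.0, -50.0).p_value == 1.0

    def test_small_negative_clamped(self):
        assert lrt(-50.00001, -50.0).statistic == 0.0

    def test_large_negative_is_an_error(self):
        with pytest.raises(ValueError, match="refit"):
            lrt(-60.0, -50.0)


class TestFitting:
    def test_m0_recovers_parameters(self):
        aln, truth = simulate_alignment(
            SimConfig(n_tips=10, n_codons=300, kappa=2.0, omega=0.4, seed=42)
        )
        fit = fit_m0(aln, truth.tree)
        assert fit.converged
        assert 0.3 < fit.omega < 0.5
        assert 1.5 < fit.kappa < 2.6

    def test_branch_model_recovers_two_omegas(self):
        rng = np.random.default_rng(5)
        from pseudochron.simgen import yule_tree

        tree = yule_tree(12, rng, height=1.0)
        fg = pick_foreground(tree, target=4)
        mark_foreground(tree, fg, name="fg")
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, n_codons=400, kappa=2.0,
                      omega={"fg": 1.2, "bg": 0.4}, seed=77)
        )
        fit = fit_branch_model(aln, tree)
        assert 0.85 <= fit.omegas["fg"] <= 1.7
        assert 0.3 <= fit.omegas["bg"] <= 0.52

    def test_nesting_constrained_below_free(self):
        aln, truth = simulate_alignment(
            SimConfig(n_tips=8, n_codons=200, kappa=2.0, omega=0.5, seed=9)
        )
        tree = truth.tree
        fg = pick_foreground(tree, target=3)
        mark_foreground(tree, fg, name="fg")
        m0 = fit_m0(aln, tree)
        free = fit_branch_model(aln, tree, reuse_from=m0)
        pinned = fit_branch_model(aln, tree, fixed={"fg": m0.omega},
                                  reuse_from=m0)
        assert pinned.log_likelihood <= free.log_likelihood + 1e-6

    def test_identical_pair_flagged_degenerate(self):
        aln = _aln({"a": "ATGCGAAAATTT", "b": "ATGCGAAAATTT"})
        tree = _tree("(a:0.1,b:0.1);")
        fit = fit_m0(aln, tree)
        assert fit.degenerate
        assert np.isnan(fit.omega)
        assert fit.tree_length < 1e-6

    def test_omega_cap_when_no_synonymous_change(self):
        # foreground tip differs from its sister only by nonsynonymous
        # changes: dS ~ 0 on that branch and omega runs to the cap
        base = "ATGCTGCGATTTGGCACC" * 6
        fgseq = list(base)
        for k in range(0, len(base), 9):
            fgseq[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fgseq[k]]
        fgseq = "".join(fgseq)
        if any(fgseq[i:i+3] in ("TAA", "TAG", "TGA")
               for i in range(0, len(fgseq), 3)):
            pytest.skip("constructed sequence hit a stop codon")
        seqs = {"a": base, "b": base, "c": base, "fg": fgseq}
        tree = _tree("((a:0.05,b:0.05):0.05,(c:0.05,fg:0.5):0.05);")
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == "fg":
                leaf.branch_class = "fg"
        fit = fit_branch_model(_aln(seqs), tree)
        assert "fg" in fit.capped
        assert fit.omegas["fg"] == 999.0

    def test_fixed_class_must_exist(self):
        aln, truth = simulate_alignment(
            SimConfig(n_tips=4, n_codons=30, seed=2)
        )
        with pytest.raises(ValueError, match="absent branch class"):
            fit_branch_model(aln, truth.tree, fixed={"fg": 1.0})


class TestBranchTests:
    def test_purifying_data_rejects_neutrality(self):
        rng = np.random.default_rng(11)
        from pseudochron.simgen import yule_tree

        tree = yule_tree(10, rng, height=1.0)
        fg = pick_foreground(tree, target=4)
        mark_foreground(tree, fg, name="fg")
        aln, _ = simulate_alignment(
            SimConfig(tree=tree, n_codons=300, kappa=2.0, omega=0.2, seed=13)
        )
        res = vs_neutral(aln, tree, "fg", reuse_lengths=True)
        assert res.lrt.p_value < 0.05
        assert res.alt.omegas["fg"] < 0.5

    def test_average_null_matches_m0_omega(self):
        aln, truth = simulate_alignment(
            SimConfig(n_tips=8, n_codons=150, kappa=2.0, omega=0.5, seed=21)
        )
        tree = truth.tree
        fg = pick_foreground(tree, target=3)
        mark_foreground(tree, fg, name="fg")
        res = vs_average(aln, tree, "fg", reuse_lengths=True)
        assert res.null.omegas["fg"] == pytest.approx(res.m0.omega)
        assert res.lrt.df == 1
        assert 0.0 <= res.lrt.p_value <= 1.0

    def test_short_alignment_warns(self, caplog):
        aln = _aln({"a": "ATG", "b": "ATA", "c": "ACG"})
        tree = _tree("((a:0.1,b:0.1):0.1,c:0.1);")
        with caplog.at_level("WARNING"):
            fit_m0(aln, tree)
        assert any("degenerate" in r.message for r in caplog.records)
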