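import numpy as np
import pytest

from pseudochron import studydata
from pseudochron.codonml import CODON_INDEX, N_CODONS, build_rate_matrix
from pseudochron.lesionscan import merge_events, scan_alignment, scan_species
from pseudochron.chronomap import decompose_homoplasy
from pseudochron.seqio import translate, write_fasta
from pseudochron.simgen import (
    LesionSpec,
    SimConfig,
    dated_newick,
    generate_study_fixture,
    pick_foreground,
    simulate_alignment,
    yule_tree,
)
from pseudochron.trees import DatedTree


def _clade(tree, n_from_root=0):
    """Tips of one root-child subtree."""
    child = tree.seed_node.child_nodes()[n_from_root]
    return frozenset(
        (l.taxon.label if l.taxon else l.label) for l in child.leaf_iter()
    )


class TestSubstitutionProcess:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(n_tips=6, n_codons=50, seed=17,
                        lesions=(LesionSpec("deletion",
                                            frozenset({"t01"}), 31, 4),))
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for p in (p1, p2):
            aln, _ = simulate_alignment(cfg)
            write_fasta(aln.records, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_time_means_identical_sequences(self):
        rng = np.random.default_rng(0)
        tree = yule_tree(5, rng, height=1e-9)
        aln, _ = simulate_alignment(SimConfig(tree=tree, n_codons=40, seed=1))
        seqs = {r.seq for r in aln.records}
        assert len(seqs) == 1

    def test_no_stop_codons_from_substitution(self):
        aln, _ = simulate_alignment(
            SimConfig(n_tips=10, n_codons=200, omega=1.5, seed=5)
        )
        for rec in aln.records:
            assert "*" not in translate(rec.seq)

    def test_long_branch_converges_to_stationary_frequencies(self):
        rng = np.random.default_rng(2)
        tree = yule_tree(2, rng, height=25.0)
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, rate=1.0, n_codons=4000, omega=1.0, seed=3)
        )
        counts = np.zeros(N_CODONS)
        for rec in aln.records:
            for i in range(0, len(rec.seq), 3):
                counts[CODON_INDEX[rec.seq[i : i + 3]]] += 1
        freqs = counts / counts.sum()
        assert np.abs(freqs - truth.freqs).max() < 0.012

    def test_short_branch_substitution_fraction_matches_generator(self):
        # Q is scaled to one expected substitution per codon per unit length,
        # so over t=0.02 the fraction of changed codons is ~2% (+O(t^2))
        rng = np.random.default_rng(6)
        tree = yule_tree(2, rng, height=0.01)  # two tips, path length 0.02
        aln, _ = simulate_alignment(
            SimConfig(tree=tree, rate=1.0, n_codons=30000, omega=1.0, seed=7)
        )
        a, b = (r.seq for r in aln.records)
        diff = sum(a[i : i + 3] != b[i : i + 3]
                   for i in range(0, len(a), 3)) / 30000
        se = np.sqrt(0.02 * 0.98 / 30000)
        assert abs(diff - 0.02) < 4 * se + 2e-4

    def test_gillespie_agrees_with_exponential_sampling(self):
        rng = np.random.default_rng(8)
        tree = yule_tree(2, rng, height=0.15)
        frac = {}
        for method in ("exponential", "gillespie"):
            aln, _ = simulate_alignment(
                SimConfig(tree=tree, rate=1.0, n_codons=3000, omega=0.5,
                          seed=9, method=method)
            )
            a, b = (r.seq for r in aln.records)
            frac[method] = np.mean(
                [a[i : i + 3] != b[i : i + 3] for i in range(0, len(a), 3)]
            )
        assert abs(frac["exponential"] - frac["gillespie"]) < 0.03


class TestLesionInjection:
    def test_stop_lesion_inherited_by_exact_clade(self):
        rng = np.random.default_rng(10)
        tree = yule_tree(8, rng, height=0.5)
        clade = _clade(tree, 1)
        if len(clade) < 2 or len(clade) > 6:
            clade = _clade(tree, 0)
        spec = LesionSpec("nonsense", clade, position=3 * 7 + 1)
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, n_codons=60, lesions=(spec,), seed=11)
        )
        for rec in aln.records:
            codon = rec.seq[21:24]
            if rec.id in clade:
                assert codon == "TGA"
            else:
                assert codon != "TGA"
        (les,) = truth.lesions
        assert les.carriers == clade

    def test_hundred_bp_deletion_recovered_as_disruptive(self):
        rng = np.random.default_rng(12)
        tree = yule_tree(6, rng, height=0.5)
        clade = _clade(tree, 1)
        spec = LesionSpec("deletion", clade, position=9, length=100)
        aln, _ = simulate_alignment(
            SimConfig(tree=tree, n_codons=120, lesions=(spec,), seed=13)
        )
        sp = sorted(clade)[0]
        (ev,) = scan_species(aln, sp)
        assert (ev.kind, ev.length, ev.disruptive) == ("deletion", 100, True)
        assert (ev.ref_start, ev.ref_end) == (9, 108)

    def test_cpg_policy_places_stop_at_shared_cga(self):
        rng = np.random.default_rng(14)
        tree = yule_tree(8, rng, height=0.2)
        clade = _clade(tree, 1)
        spec = LesionSpec("nonsense", clade, cpg=True)
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, n_codons=400, lesions=(spec,), seed=15)
        )
        (les,) = truth.lesions
        sp = sorted(les.carriers)[0]
        assert aln.get(sp).seq[les.ref_start - 1 : les.ref_end] == "TGA"
        # the pre-lesion state at that codon was CGA in every carrier
        site = (les.ref_start - 1) // 3
        for c in les.carriers:
            assert truth.tip_states[c][site] == CODON_INDEX["CGA"]

    def test_cpg_error_when_no_shared_cga(self):
        rng = np.random.default_rng(16)
        tree = yule_tree(4, rng, height=0.3)
        clade = _clade(tree, 1)
        with pytest.raises(ValueError, match="CGA"):
            simulate_alignment(
                SimConfig(tree=tree, n_codons=3,
                          lesions=(LesionSpec("nonsense", clade, cpg=True),),
                          seed=17)
            )

    def test_homoplastic_stops_merge_but_decompose(self):
        rng = np.random.default_rng(18)
        tree = yule_tree(10, rng, height=0.5)
        # two disjoint, non-sister origin clades
        internal = [n for n in tree.postorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        tips = lambda n: frozenset(
            (l.taxon.label if l.taxon else l.label) for l in n.leaf_iter())
        c1 = tips(internal[0])
        c2 = next(tips(n) for n in internal if not tips(n) & c1)
        pos = 3 * 5 + 1
        specs = (LesionSpec("nonsense", c1, position=pos),
                 LesionSpec("nonsense", c2, position=pos))
        aln, truth = simulate_alignment(
            SimConfig(tree=tree, n_codons=50, lesions=specs, seed=19)
        )
        events, _ = merge_events(scan_alignment(aln))
        stops = [e for e in events if e.kind == "nonsense"]
        assert len(stops) == 1
        assert stops[0].carriers == c1 | c2
        rep = decompose_homoplasy(truth.dated_tree(), stops[0])
        assert rep.n_independent_origins == 2

    def test_whole_tree_lesion_rejected(self):
        rng = np.random.default_rng(20)
        tree = yule_tree(4, rng, height=0.5)
        all_tips = _clade(tree, 0) | _clade(tree, 1)
        with pytest.raises(ValueError, match="origin branch|reference"):
            simulate_alignment(
                SimConfig(tree=tree, n_codons=30,
                          lesions=(LesionSpec("nonsense", all_tips,
                                              position=4),), seed=21)
            )


class TestDatedNewick:
    def test_roundtrips_through_datedtree(self):
        aln, truth = simulate_alignment(SimConfig(n_tips=6, n_codons=10,
                                                  seed=22))
        dt = DatedTree.from_newick(dated_newick(truth))
        assert set(dt.tip_labels) == set(truth.tip_states)
        assert dt.root_age() == pytest.approx(1.0, abs=1e-6)


class TestStudyFixtureBundle:
    def test_shape_and_idempotency(self, tmp_path):
        paths1 = generate_study_fixture(tmp_path / "one")
        paths2 = generate_study_fixture(tmp_path / "two")
        import pandas as pd

        matrix = pd.read_csv(paths1["felid_matrix.tsv"], sep="\t",
                             index_col=0)
        assert matrix.shape == (18, 9)
        lesions = pd.read_csv(paths1["lesions.tsv"], sep="\t", index_col=0)
        assert lesions.loc["M1", "kind"] == "nonsense"
        assert lesions.loc["M2", "kind"] == "nonsense"
        assert lesions.loc["M3", "kind"] == "deletion"
        assert lesions.loc["M4", "kind"] == "deletion"
        for name, p1 in paths1.items():
            with open(p1, "rb") as f1, open(paths2[name], "rb") as f2:
                assert f1.read() == f2.read(), name

    def test_regeneration_in_place_identical(self, tmp_path):
        paths = generate_study_fixture(tmp_path)
        before = {n: open(p, "rb").read() for n, p in paths.items()}
        generate_study_fixture(tmp_path)
        after = {n: open(p, "rb").read() for n, p in paths.items()}
        assert before == after
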