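import numpy as np
import pytest

from conftest import make_lesion_sim
from pseudochron import studydata
from pseudochron.lesionscan import (
    LesionEvent,
    annotate_cpg,
    gene_status,
    merge_events,
    scan_alignment,
    scan_species,
)
from pseudochron.seqio import CodonAlignment, SequenceRecord, translate


def _aln(rows, ref="human", offset=1):
    return CodonAlignment(
        [SequenceRecord(i, s) for i, s in rows.items()],
        ref_id=ref, ref_offset=offset,
    )


class TestScanSpecies:
    def test_identity_yields_no_events(self):
        ref = studydata.reference_exon()
        aln = _aln({"human": ref, "twin": ref})
        assert scan_species(aln, "twin") == []

    def test_large_frameshift_deletion(self):
        ref = studydata.reference_exon()
        sp = ref[:8] + "-" * 100 + ref[108:]
        aln = _aln({"human": ref, "cat": sp})
        (ev,) = scan_species(aln, "cat")
        assert (ev.kind, ev.ref_start, ev.ref_end, ev.length) == (
            "deletion", 9, 108, 100)
        assert ev.disruptive  # 100 % 3 == 1

    def test_in_frame_deletion_not_disruptive(self):
        ref = studydata.reference_exon()
        sp = ref[:9] + "---" + ref[12:]
        aln = _aln({"human": ref, "sp": sp})
        (ev,) = scan_species(aln, "sp")
        assert ev.kind == "deletion" and ev.length == 3
        assert not ev.disruptive

    def test_nonsense_at_codon_start(self):
        ref = studydata.reference_exon()
        assert ref[273:276] == "CGA"
        sp = ref[:273] + "TGA" + ref[276:]
        aln = _aln({"human": ref, "hyena": sp})
        (ev,) = scan_species(aln, "hyena")
        assert (ev.kind, ev.ref_start, ev.ref_end) == ("nonsense", 274, 276)
        assert ev.disruptive

    def test_insertion_reported_as_flanking_pair(self):
        ref = "ATGCCAGGA"
        rows = {"human": ref[:6] + "-" + ref[6:], "sp": ref[:6] + "T" + ref[6:]}
        aln = _aln(rows)
        (ev,) = scan_species(aln, "sp")
        assert (ev.kind, ev.ref_start, ev.ref_end, ev.length) == (
            "insertion", 6, 7, 1)

    def test_frameshift_downstream_stops_are_consequences_not_events(self):
        # deleting ref position 4 shifts the species frame so its own
        # translation hits TAA, but no stop exists in the reference frame
        ref = "ATGCTAAGC"
        sp = "ATG-TAAGC"
        # the species' own (shifted) reading frame contains TAA...
        assert translate(sp.replace("-", "") + "A")[1] == "*"
        aln = _aln({"human": ref, "sp": sp})
        events = scan_species(aln, "sp")
        assert [e.kind for e in events] == ["deletion"]

    def test_stop_in_reference_frame_after_upstream_frameshift_is_event(self):
        aln = studydata.caniform_alignment()
        events = scan_species(aln, "northern_elephant_seal")
        assert [(e.kind, e.ref_start) for e in events] == [
            ("insertion", 398), ("nonsense", 667)]

    def test_unknown_species(self, felid_aln):
        with pytest.raises(KeyError):
            scan_species(felid_aln, "sabertooth")

    def test_reference_with_premature_stop_rejected(self):
        aln = _aln({"human": "ATGTGACCC", "sp": "ATGTGACCC"})
        with pytest.raises(ValueError, match="premature stop"):
            scan_species(aln, "sp")

    def test_ambiguous_codon_never_a_stop(self):
        ref = "ATGCGACCC"
        aln = _aln({"human": ref, "sp": "ATGTGNCCC"})
        assert scan_species(aln, "sp") == []


class TestMergeEvents:
    def test_table_matrix_reconstruction(self, felid_aln):
        events, matrix = merge_events(scan_alignment(felid_aln))
        assert len(events) == 9
        universal = [e for e in events if len(e.carriers) == 18]
        assert len(universal) == 4
        kinds = sorted(e.kind for e in universal)
        assert kinds == ["deletion", "deletion", "nonsense", "nonsense"]
        assert matrix.shape == (18, 9)
        assert matrix.values.any(axis=0).all()  # every event has a carrier

    def test_same_position_different_length_stay_distinct(self):
        a = LesionEvent("deletion", 10, 12, 3, frozenset({"a"}))
        b = LesionEvent("deletion", 10, 13, 4, frozenset({"b"}))
        events, _ = merge_events([a, b])
        assert len(events) == 2

    def test_idempotent_and_order_invariant(self, felid_aln):
        per_species = scan_alignment(felid_aln)
        e1, m1 = merge_events(per_species)
        shuffled = dict(reversed(list(per_species.items())))
        e2, m2 = merge_events(shuffled)
        assert [(e.id, e.key, e.carriers) for e in e1] == [
            (e.id, e.key, e.carriers) for e in e2]
        e3, _ = merge_events(e1)
        assert [(e.key, e.carriers) for e in e3] == [
            (e.key, e.carriers) for e in e1]

    def test_divergent_inserted_sequence_merges_with_log(self, caplog):
        # same flanking pair and length, different inserted bases
        rows = {"human": "ATGCCA--GGA", "x": "ATGCCATTGGA",
                "y": "ATGCCAGCGGA"}
        aln = _aln(rows)
        with caplog.at_level("WARNING"):
            events, _ = merge_events(scan_alignment(aln), aln=aln)
        (ev,) = events
        assert ev.kind == "insertion" and ev.carriers == frozenset({"x", "y"})
        assert any("differing inserted sequence" in r.message
                   for r in caplog.records)

    def test_carrier_counts_match_per_species_totals(self, felid_aln):
        per_species = scan_alignment(felid_aln)
        _, matrix = merge_events(per_species)
        assert matrix.values.sum() == sum(
            len(evs) for evs in per_species.values())


class TestAnnotateCpg:
    def test_cga_to_tga_transition_is_hotspot(self):
        aln = studydata.feliform_stop_alignment()
        (ev,) = scan_species(aln, "brown_hyena")
        assert annotate_cpg(ev, aln).cpg_hotspot is True

    def test_transversion_source_is_not_hotspot(self):
        ref = "ATGAAACCC"
        aln = _aln({"human": ref, "x": "ATGTAACCC"})
        (ev,) = scan_species(aln, "x")
        assert annotate_cpg(ev, aln).cpg_hotspot is False

    def test_no_intact_source_codon(self):
        # the only non-carrier is unresolved (N) at the stop codon, so no
        # intact source codon is observable anywhere
        rows = {"human": "ATGNNNCCCATC", "a": "ATGTGACCCATC",
                "b": "ATGTGACCCATC"}
        aln = _aln(rows)
        events, _ = merge_events(scan_species(aln, "a") + scan_species(aln, "b"))
        (ev2,) = events
        assert ev2.carriers == frozenset({"a", "b"})
        assert annotate_cpg(ev2, aln).cpg_hotspot is False

    def test_requires_nonsense_event(self):
        ev = LesionEvent("deletion", 1, 3, 3, frozenset({"a"}))
        with pytest.raises(ValueError, match="nonsense"):
            annotate_cpg(ev, studydata.felid_alignment())


class TestGeneStatus:
    def test_all_felids_pseudogene(self, felid_aln):
        events, matrix = merge_events(scan_alignment(felid_aln))
        statuses = gene_status(matrix, events)
        assert len(statuses) == 18
        assert all(s.status == "pseudogene" for s in statuses)
        assert all(s.n_disruptive >= 4 for s in statuses)

    def test_event_free_species_intact(self):
        ev = LesionEvent("nonsense", 4, 6, 3, frozenset({"a"}), id="E1")
        events, matrix = merge_events([ev])
        matrix = matrix.reindex(["a", "b"], fill_value=False)
        statuses = {s.species: s for s in gene_status(matrix, events)}
        assert statuses["a"].status == "pseudogene"
        assert statuses["b"].status == "intact"

    def test_in_frame_indel_only_is_intact(self):
        ev = LesionEvent("deletion", 4, 6, 3, frozenset({"a"}), id="E1")
        events, matrix = merge_events([ev])
        (status,) = gene_status(matrix, events)
        assert status.status == "intact" and status.n_disruptive == 0


class TestRoundTrip:
    def test_injected_lesions_recovered_exactly(self):
        n_checked = 0
        for seed in range(40):
            aln, truth = make_lesion_sim(seed)
            by_key = {}
            for les in truth.lesions:
                by_key.setdefault(les.key, set()).update(les.carriers)
            for sp in aln.species:
                if sp == aln.ref_id:
                    continue
                found = {e.key for e in scan_species(aln, sp)}
                expected = {k for k, carriers in by_key.items()
                            if sp in carriers}
                assert found == expected, (seed, sp)
                n_checked += len(expected)
        assert n_checked > 100

    def test_reverting_lesions_restores_open_reading_frame(self, felid_aln):
        from pseudochron.seqio import map_to_reference

        refmap = map_to_reference(felid_aln)
        ref = felid_aln.reference.seq
        per_species = scan_alignment(felid_aln)
        for sp, events in per_species.items():
            seq = list(felid_aln.get(sp).seq)
            for ev in events:
                if ev.kind == "insertion":
                    continue  # handled by dropping reference-gap columns
                for p in range(ev.ref_start, ev.ref_end + 1):
                    col = refmap.column(p)
                    seq[col - 1] = ref[col - 1]
            restored = "".join(
                b for col, b in enumerate(seq, start=1)
                if ref[col - 1] != "-" and b != "-"
            )
            aa = translate(restored)
            assert "*" not in aa.rstrip("*")
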