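"""Junction-chain collapsing into isoforms and AS event classification."""

import random

import pytest

from unitrans import isoforms, sim, spliced_map
from unitrans.isoforms import classify_chain_pair
from unitrans.spliced_map import SplicedAlignment


def aln(tid, model, chain, span=(0, 2000)):
    """Synthesize a mapped alignment whose extracted chain equals `chain`."""
    blocks = []
    pos = span[0]
    rpos = 0
    for d, a in chain:
        blocks.append((pos, d, rpos, rpos + (d - pos)))
        rpos += d - pos
        pos = a
    blocks.append((pos, span[1], rpos, rpos + (span[1] - pos)))
    return SplicedAlignment(tid, model, blocks=blocks, identity=1.0, coverage=1.0)


class TestCollapse:
    def test_identical_chains_collapse(self):
        isos = isoforms.collapse_isoforms([aln("a", "m", [(100, 300)]), aln("b", "m", [(100, 300)])])
        assert len(isos) == 1
        assert isos[0].support == 2
        assert isos[0].member_ids == ["a", "b"]

    def test_different_chains_stay_apart(self):
        isos = isoforms.collapse_isoforms(
            [aln("a", "m", [(100, 300)]), aln("b", "m", [(100, 300), (500, 700)])]
        )
        assert len(isos) == 2

    def test_epsilon_tolerance(self):
        pair = [aln("a", "m", [(100, 300)]), aln("b", "m", [(103, 300)])]
        assert len(isoforms.collapse_isoforms(pair, eps=5)) == 1
        assert len(isoforms.collapse_isoforms(pair, eps=0)) == 2

    def test_chainless_transcripts_collapse_regardless_of_ends(self):
        isos = isoforms.collapse_isoforms([aln("a", "m", [], span=(0, 900)), aln("b", "m", [], span=(50, 800))])
        assert len(isos) == 1
        assert isos[0].chain.junctions == ()

    def test_support_conservation_and_permutation_invariance(self, dataset20):
        alns = [
            spliced_map.splice_align(i.id, i.sequence, i.gene_id, dataset20.truth.model_sequence_of[i.gene_id])
            for i in dataset20.isoforms
        ]
        isos = isoforms.collapse_isoforms(alns)
        per_model = {}
        for iso in isos:
            per_model[iso.model_id] = per_model.get(iso.model_id, 0) + iso.support
        mapped_per_model = {}
        for a in alns:
            mapped_per_model[a.model_id] = mapped_per_model.get(a.model_id, 0) + 1
        assert per_model == mapped_per_model

        shuffled = list(alns)
        random.Random(0).shuffle(shuffled)
        again = isoforms.collapse_isoforms(shuffled)
        assert [(i.isoform_id, i.member_ids) for i in isos] == [(i.isoform_id, i.member_ids) for i in again]


class TestClassifyRules:
    def test_retained_intron(self):
        events = classify_chain_pair(((100, 300),), (0, 1000), (), (0, 1000))
        assert events == [("RI", (100, 300))]

    def test_retained_intron_needs_span_cover(self):
        events = classify_chain_pair(((100, 300),), (0, 1000), (), (400, 1000))
        assert events == []

    def test_skipped_exon(self):
        events = classify_chain_pair(
            ((100, 300), (450, 700)), (0, 1000), ((100, 700),), (0, 1000)
        )
        assert ("SE", (100, 300, 450, 700)) in events

    def test_alternative_donor_a5(self):
        events = classify_chain_pair(((100, 300),), (0, 1000), ((150, 300),), (0, 1000))
        assert events == [("A5", (100, 150, 300))]

    def test_alternative_acceptor_a3(self):
        events = classify_chain_pair(((100, 250),), (0, 1000), ((100, 300),), (0, 1000))
        assert events == [("A3", (100, 250, 300))]

    def test_af_beats_a5_when_upstream_disjoint(self):
        events = classify_chain_pair(((100, 500),), (0, 1000), ((300, 500),), (150, 1000))
        assert events == [("AF", (100, 300, 500))]

    def test_al_beats_a3_when_downstream_disjoint(self):
        events = classify_chain_pair(((500, 700),), (0, 780), ((500, 800),), (0, 1000))
        assert events == [("AL", (500, 700, 800))]

    def test_event_vocabulary(self):
        assert set(isoforms.EVENT_TYPES) == {"SE", "RI", "A5", "A3", "AF", "AL"}


class TestClassifyEvents:
    def test_deduplicates_by_type_and_coordinates(self):
        alns = [
            aln("a", "m", []),
            aln("b", "m", [(100, 300)]),
            aln("c", "m", [(100, 300), (500, 700)]),
        ]
        isos = isoforms.collapse_isoforms(alns)
        events = isoforms.classify_events(isos)
        keys = [(e.type, e.coordinates) for e in events]
        assert len(keys) == len(set(keys))
        assert ("RI", (100, 300)) in keys

    def test_mixed_models_rejected(self):
        isos = isoforms.collapse_isoforms([aln("a", "m1", []), aln("b", "m2", [])])
        with pytest.raises(ValueError):
            isoforms.classify_events(isos)

    def test_event_coordinates_appear_in_member_chains(self, dataset20):
        alns = [
            spliced_map.splice_align(i.id, i.sequence, i.gene_id, dataset20.truth.model_sequence_of[i.gene_id])
            for i in dataset20.isoforms
        ]
        isos = isoforms.collapse_isoforms(alns)
        by_model = {}
        for iso in isos:
            by_model.setdefault(iso.model_id, []).append(iso)
        for mid, group in by_model.items():
            if len(group) < 2:
                continue
            coords_seen = {c for iso in group for j in iso.chain.junctions for c in j}
            spans = {c for iso in group for c in iso.span}
            for ev in isoforms.classify_events(group):
                for c in ev.coordinates:
                    assert c in coords_seen | spans


class TestSummary:
    def test_distribution_bins(self):
        def iso(model, n):
            return [
                isoforms.Isoform(f"{model}.I{i}", model, spliced_map.JunctionChain(model, ()), 1)
                for i in range(n)
            ]

        table = isoforms.isoform_summary(iso("m1", 1) + iso("m2", 2) + iso("m3", 12))
        assert table["bins"]["1"] == 1
        assert table["bins"]["2"] == 1
        assert table["bins"][">10"] == 1
        assert table["multi_isoform_fraction"] == pytest.approx(2 / 3)

    def test_empty(self):
        table = isoforms.isoform_summary([])
        assert table["n_models"] == 0 and table["multi_isoform_fraction"] == 0.0
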