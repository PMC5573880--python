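"""ORF discovery vs naive oracle, filter boundary semantics, coding potential,
and the three-step lncRNA cascade."""

import math
import warnings

import numpy as np
import pytest

from unitrans import orf_lncrna as ol
from unitrans import sim

STOPS = {"TAA", "TAG", "TGA"}
#: 12 nt carrying a stop codon in all three reading frames
ALL_FRAME_STOPPER = "TTAATTAATTAA"


def naive_orfs(seq):
    """Independent frame-scan oracle following the documented conventions."""
    out = []
    for frame in range(3):
        codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        if not codons:
            continue
        stop_pos = [j for j, (_, c) in enumerate(codons) if c in STOPS]
        if not stop_pos:
            out.append((frame, codons[0][0], codons[-1][0] + 3, len(codons), "open_both"))
            continue
        lead = codons[: stop_pos[0]]
        if lead and lead[0][1] != "ATG":
            out.append((frame, lead[0][0], codons[stop_pos[0]][0] + 3, len(lead), "open5"))
        regions = [(0, stop_pos[0])] + [(a + 1, b) for a, b in zip(stop_pos, stop_pos[1:])]
        for lo, hi in regions:
            atg = [j for j in range(lo, hi) if codons[j][1] == "ATG"]
            if atg:
                out.append((frame, codons[atg[0]][0], codons[hi][0] + 3, hi - atg[0], "complete"))
        tail = codons[stop_pos[-1] + 1 :]
        atg = [j for j, (_, c) in enumerate(tail) if c == "ATG"]
        if atg:
            out.append((frame, tail[atg[0]][0], tail[-1][0] + 3, len(tail) - atg[0], "open3"))
    return sorted(out)


class TestFindOrfs:
    def test_hand_translated_complete_orf(self):
        orfs = ol.find_orfs("ATGAAATAA")
        complete = [o for o in orfs if o.completeness == "complete"]
        assert len(complete) == 1
        assert complete[0].length_aa == 2
        assert (complete[0].start, complete[0].end) == (0, 9)

    def test_stop_free_frame_is_open_both(self):
        seq = "ATG" + "GCT" * 99  # 300 nt, no stop in frame 0
        orfs = [o for o in ol.find_orfs(seq) if o.frame == 0]
        assert orfs == [ol.Orf(0, 0, 300, 100, "open_both")]

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            seq = sim._random_seq(rng, int(rng.integers(3, 240)))
            got = sorted((o.frame, o.start, o.end, o.length_aa, o.completeness) for o in ol.find_orfs(seq))
            assert got == naive_orfs(seq)

    def test_both_strands_flag(self):
        seq = "TTATTTCAT"  # reverse complement carries ATG AAA TAA
        assert not any(o.strand == "-" for o in ol.find_orfs(seq))
        minus = [o for o in ol.find_orfs(seq, both_strands=True) if o.strand == "-"]
        assert [(o.completeness, o.length_aa) for o in minus if o.completeness == "complete"] == [
            ("complete", 2)
        ]


class TestOrfFilter:
    @pytest.mark.parametrize(
        "length_aa,completeness,expected",
        [
            (100, "complete", True),
            (101, "complete", False),
            (50, "open5", True),
            (51, "open5", False),
            (50, "open3", True),
            (51, "open_both", False),
        ],
    )
    def test_boundary_rule(self, length_aa, completeness, expected):
        orf = ol.Orf(0, 0, 3 * length_aa, length_aa, completeness)
        assert ol.orf_filter([orf]) is expected

    def test_mixed_orfs_pass(self):
        orfs = [ol.Orf(0, 0, 273, 90, "complete"), ol.Orf(1, 1, 121, 40, "open3")]
        assert ol.orf_filter(orfs) is True

    def test_boundary_on_constructed_sequences(self):
        """Sequences straddling the 100 aa internal / 50 aa end thresholds."""
        background = sim.random_noncoding_rna(7, length=300)
        for n_codons, expected in ((99, True), (100, False)):
            # complete ORF of n_codons + 1 aa (the ATG counts, the stop does not)
            cds = "ATG" + "CTA" * n_codons + "TAA"
            seq = background + ALL_FRAME_STOPPER + cds + ALL_FRAME_STOPPER
            assert ol.orf_filter(ol.find_orfs(seq)) is expected
        for n_codons, expected in ((49, True), (50, False)):
            # open3 ORF of n_codons + 1 aa running off the 3' end
            tail = "ATG" + "CTA" * n_codons
            seq = background + ALL_FRAME_STOPPER + tail
            assert ol.orf_filter(ol.find_orfs(seq)) is expected


class TestHexamerTable:
    def test_identical_training_sets_give_zero_ratios(self):
        seqs = [sim.random_coding_mrna(i, n_codons=120) for i in range(25)]
        table = ol.train_hexamer_tables(seqs, seqs)
        assert all(abs(v) < 1e-12 for v in table.log_ratio.values())

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            ol.train_hexamer_tables(["ATGAAATAA"], ["ACGTACGTT"])

    def test_coding_class_scores_positive(self, hexamer_table):
        llrs = [hexamer_table.llr(sim.random_coding_mrna(50_000 + i, n_codons=150)) for i in range(20)]
        assert sum(llrs) / len(llrs) > 0


class TestCodingPotential:
    def test_random_sequence_noncoding(self, hexamer_table):
        seq = sim.random_noncoding_rna(99, length=600)
        cp = ol.coding_potential(seq, ol.find_orfs(seq), hexamer_table)
        assert cp.label == "noncoding"

    def test_long_biased_orf_coding(self, hexamer_table):
        seq = sim.random_coding_mrna(98, n_codons=300, utr5=20, utr3=30)
        cp = ol.coding_potential(seq, ol.find_orfs(seq), hexamer_table)
        assert cp.label == "coding"
        assert cp.orf_coverage > 0.9

    def test_longer_orf_never_decreases_score(self, hexamer_table):
        scores = []
        for n in (60, 150, 300):
            seq = sim.random_coding_mrna(42, n_codons=n, utr5=30, utr3=30)
            cp = ol.coding_potential(seq, ol.find_orfs(seq), hexamer_table)
            scores.append(cp.combined)
        assert scores == sorted(scores)


class TestCascade:
    def test_homology_hit_eliminated_first(self, hexamer_table):
        seqs = {"t1": sim.random_noncoding_rna(1, length=400)}
        calls = ol.lncrna_pipeline(seqs, [("t1", 1e-5)], hexamer_table)
        assert calls[0].passed_steps == set()
        assert not calls[0].is_lncRNA

    def test_long_orf_eliminated_second(self, hexamer_table):
        seq = sim.random_coding_mrna(2, n_codons=150)  # 150 aa complete ORF
        calls = ol.lncrna_pipeline({"t1": seq}, [], hexamer_table)
        assert calls[0].passed_steps == {"no_protein_hit"}
        assert not calls[0].is_lncRNA

    def test_clean_noncoding_survives_all_steps(self, hexamer_table):
        seq = sim.random_noncoding_rna(3, length=500)
        calls = ol.lncrna_pipeline({"t1": seq}, [], hexamer_table)
        assert calls[0].passed_steps == {"no_protein_hit", "orf_filter", "coding_potential"}
        assert calls[0].is_lncRNA

    def test_unknown_hit_ids_warned_and_ignored(self, hexamer_table):
        seqs = {"t1": sim.random_noncoding_rna(4, length=400)}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            calls = ol.lncrna_pipeline(seqs, [("ghost", 1e-9)], hexamer_table)
        assert any("ghost" in str(w.message) for w in caught)
        assert calls[0].is_lncRNA

    def test_external_labels_replace_scorer(self):
        seqs = {"t1": sim.random_noncoding_rna(5, length=400)}
        calls = ol.lncrna_pipeline(seqs, [], coding_labels={"t1": "coding"})
        assert not calls[0].is_lncRNA
        calls = ol.lncrna_pipeline(seqs, [], coding_labels={"t1": "noncoding"})
        assert calls[0].is_lncRNA

    def test_cascade_order_respected(self, hexamer_table):
        """No transcript reaches a later step having failed an earlier one."""
        seqs = {
            "hit": sim.random_noncoding_rna(6, length=400),
            "orfy": sim.random_coding_mrna(7, n_codons=200),
            "clean": sim.random_noncoding_rna(8, length=400),
        }
        calls = {c.transcript_id: c for c in ol.lncrna_pipeline(seqs, [("hit", 1e-6)], hexamer_table)}
        assert calls["hit"].passed_steps == set()
        assert calls["orfy"].passed_steps == {"no_protein_hit"}
        assert calls["clean"].is_lncRNA
        for c in calls.values():
            if "coding_potential" in c.passed_steps:
                assert {"no_protein_hit", "orf_filter"} <= c.passed_steps
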