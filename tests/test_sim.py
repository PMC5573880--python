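"""Simulator: gene structure, event realization, truth-table consistency."""

import numpy as np
import pytest

from unitrans import sim


def left_normalize(chain, union, span_start):
    """Reference left-normalization of junction coordinates (mirrors the
    documented convention independently of the simulator's code path)."""
    out = []
    prev_a = span_start
    for d, a in chain:
        while d > prev_a + 1 and union[d - 1] == union[a - 1]:
            d -= 1
            a -= 1
        out.append((d, a))
        prev_a = a
    return tuple(out)


class TestMakeGene:
    def test_single_exon_degenerate(self):
        gene = sim.make_gene(1, (100, 100), (150, 300), seed=7)
        assert len(gene.segments) == 1
        kind, seq = gene.segments[0]
        assert kind == "exon" and len(seq) == 100

    def test_structure_and_length_ranges(self):
        gene = sim.make_gene(3, (200, 400), (150, 300), seed=1)
        kinds = [k for k, _ in gene.segments]
        assert kinds == ["exon", "intron", "exon", "intron", "exon"]
        for kind, seq in gene.segments:
            lo, hi = (200, 400) if kind == "exon" else (150, 300)
            assert lo <= len(seq) <= hi
            assert set(seq) <= set("ACGT")

    def test_determinism(self):
        g1 = sim.make_gene(3, (200, 400), (150, 300), seed=1)
        g2 = sim.make_gene(3, (200, 400), (150, 300), seed=1)
        assert g1.segments == g2.segments

    def test_31mer_uniqueness(self):
        gene = sim.make_gene(6, (100, 300), (150, 300), seed=3)
        full = "".join(s for _, s in gene.segments)
        kmers = [full[i : i + 31] for i in range(len(full) - 30)]
        assert len(set(kmers)) == len(kmers)

    @pytest.mark.parametrize("bad", [dict(n_exons=0), dict(exon_len_range=(0, 5)), dict(intron_len_range=(10, 5))])
    def test_invalid_arguments(self, bad):
        kwargs = dict(n_exons=2, exon_len_range=(100, 200), intron_len_range=(100, 200), seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sim.make_gene(**kwargs)


class TestMakeIsoforms:
    def test_empty_spec_gives_canonical_only(self):
        gene = sim.make_gene(3, (100, 200), (150, 200), seed=0)
        isos, _, truth = sim.make_isoforms(gene, {}, seed=0)
        assert len(isos) == 1
        assert isos[0].truth_chain == ()
        assert truth.events_of[gene.id] == []

    def test_se_drops_internal_exon(self):
        gene = sim.make_gene(3, (100, 200), (150, 200), seed=2)
        isos, refined, truth = sim.make_isoforms(gene, {"SE": 1}, seed=2)
        assert len(isos) == 2
        canonical, variant = isos
        exons = refined.exon_indices
        assert canonical.included_segments == tuple(exons)
        assert variant.included_segments == (exons[0], exons[2])
        # hand-derived chain: the union model is the three exons concatenated,
        # the variant skips the middle one
        e1, e2 = len(refined.segments[exons[0]][1]), len(refined.segments[exons[1]][1])
        union = truth.model_sequence_of[gene.id]
        assert variant.truth_chain == left_normalize(((e1, e1 + e2),), union, 0)
        assert canonical.truth_chain == ()
        # in model space a skipped exon between exonic neighbours is a
        # retained-intron pattern
        assert [t for t, _ in truth.events_of[gene.id]] == ["RI"]

    def test_ri_retains_intron(self):
        gene = sim.make_gene(2, (100, 200), (150, 200), seed=3)
        isos, refined, truth = sim.make_isoforms(gene, {"RI": 1}, seed=3)
        assert len(isos) == 2
        canonical, variant = isos
        assert len(variant.included_segments) == 3  # exon, intron, exon
        e1 = len(refined.segments[0][1])
        i1 = len(refined.segments[1][1])
        union = truth.model_sequence_of[gene.id]
        assert canonical.truth_chain == left_normalize(((e1, e1 + i1),), union, 0)
        assert variant.truth_chain == ()
        assert [t for t, _ in truth.events_of[gene.id]] == ["RI"]

    def test_a5_variants_share_acceptor(self):
        gene = sim.make_gene(3, (100, 200), (150, 200), seed=5)
        isos, _, truth = sim.make_isoforms(gene, {"A5": 1}, seed=5)
        assert len(isos) == 3
        types = {t for t, _ in truth.events_of[gene.id]}
        assert "A5" in types

    def test_af_al_need_four_exons(self):
        gene = sim.make_gene(3, (100, 200), (150, 200), seed=1)
        with pytest.raises(ValueError, match="AF"):
            sim.make_isoforms(gene, {"AF": 1}, seed=1)
        gene4 = sim.make_gene(4, (100, 200), (150, 200), seed=1)
        _, _, truth = sim.make_isoforms(gene4, {"AF": 1}, seed=1)
        assert "AF" in {t for t, _ in truth.events_of[gene4.id]}
        _, _, truth = sim.make_isoforms(gene4, {"AL": 1}, seed=2)
        assert "AL" in {t for t, _ in truth.events_of[gene4.id]}

    def test_unrealizable_spec_names_event(self):
        gene = sim.make_gene(1, (100, 200), (150, 200), seed=0)
        with pytest.raises(ValueError, match="SE"):
            sim.make_isoforms(gene, {"SE": 1}, seed=0)


class TestDatasetInvariants:
    def test_sequences_concatenate_included_segments(self, dataset20):
        genes = {g.id: g for g in dataset20.genes}
        for iso in dataset20.isoforms:
            segs = genes[iso.gene_id].segments
            assert iso.sequence == "".join(segs[i][1] for i in iso.included_segments)
            assert list(iso.included_segments) == sorted(iso.included_segments)

    def test_union_model_length(self, dataset20):
        genes = {g.id: g for g in dataset20.genes}
        by_gene = {}
        for iso in dataset20.isoforms:
            by_gene.setdefault(iso.gene_id, set()).update(iso.included_segments)
        for gid, included in by_gene.items():
            expected = sum(len(genes[gid].segments[i][1]) for i in included)
            assert len(dataset20.truth.model_sequence_of[gid]) == expected

    def test_chains_within_union_and_increasing(self, dataset20):
        for tid, chain in dataset20.truth.chain_of.items():
            gid = dataset20.truth.family_of[tid]
            model_len = len(dataset20.truth.model_sequence_of[gid])
            prev = -1
            for d, a in chain:
                assert 0 < d < a <= model_len
                assert d > prev
                prev = a

    def test_dataset_determinism(self):
        d1 = sim.simulate_dataset(4, seed=9, sub_rate=0.01, short_read_coverage=5)
        d2 = sim.simulate_dataset(4, seed=9, sub_rate=0.01, short_read_coverage=5)
        assert d1.transcripts == d2.transcripts
        assert d1.short_reads == d2.short_reads
        assert d1.truth.model_sequence_of == d2.truth.model_sequence_of


class TestAddNoise:
    def test_zero_rates_identity(self):
        seq = sim._random_seq(np.random.default_rng(0), 500)
        assert sim.add_noise(seq, 0, 0, 0, seed=1) == seq

    def test_substitution_count_binomial(self):
        seq = sim._random_seq(np.random.default_rng(1), 10_000)
        noisy = sim.add_noise(seq, 0.01, 0, 0, seed=5)
        assert len(noisy) == len(seq)
        hamming = sum(a != b for a, b in zip(seq, noisy))
        # binomial n=10000 p=0.01: mean 100, sd ~10; 3 sigma band
        assert 70 <= hamming <= 130

    def test_rate_cap_rejected(self):
        with pytest.raises(ValueError):
            sim.add_noise("ACGT", 1.0, 0, 0, seed=0)


class TestShortReads:
    def test_error_free_reads_are_substrings(self):
        rng = np.random.default_rng(3)
        iso = ("t1", sim._random_seq(rng, 1000))
        reads = sim.make_short_reads([iso], read_len=100, coverage=50, err_rate=0, seed=4)
        assert len(reads) == 500  # ceil(1000 * 50 / 100)
        assert all(seq in iso[1] for _, seq in reads)

    def test_zero_coverage_empty(self):
        reads = sim.make_short_reads([("t1", "A" * 200)], 100, 0, 0, seed=0)
        assert reads == []

    def test_determinism(self):
        iso = [("t1", sim._random_seq(np.random.default_rng(5), 600))]
        r1 = sim.make_short_reads(iso, 100, 10, 0.01, seed=6)
        r2 = sim.make_short_reads(iso, 100, 10, 0.01, seed=6)
        assert r1 == r2

    def test_read_longer_than_isoform_rejected(self):
        with pytest.raises(ValueError):
            sim.make_short_reads([("t1", "ACGT" * 10)], read_len=100, coverage=1, err_rate=0, seed=0)
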