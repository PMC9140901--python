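"""Conformation enumeration, read classification, support fractions, multipartite model."""

from collections import Counter

import numpy as np
import pytest

import mitoforms as mf
from mitoforms import revcomp
from mitoforms.recombination import ALTERNATIVE, MASTER, UNINFORMATIVE

from conftest import random_dna


def surgery_oracle(genome_seq, a1, a2, rlen, orientation):
    """Independent string surgery: cut, exchange, re-circularise.

    Returns the alternative conformation molecules as plain strings.
    Assumes no interval wraps the origin (toy inputs are built that way).
    """
    g = genome_seq
    if orientation == "direct":
        return [g[a1:a2], g[a2:] + g[:a1]]
    b2 = a2 + rlen
    return [g[:a1] + revcomp(g[a1:b2]) + g[b2:]]


def make_genome(L, a1, a2, rlen, orientation="direct", seed=0):
    spec = mf.SimGenomeSpec(
        genome_length=L, repeat_plants=(mf.RepeatPlant(rlen, a1, a2, orientation),), seed=seed
    )
    genome, _, _ = mf.build_genome(spec)
    pair = mf.RepeatPair("R1", rlen, (a1, a1 + rlen), (a2, a2 + rlen), orientation, 100.0)
    return genome, pair


class TestEnumerateConformations:
    def test_direct_pair_subcircle_sizes_small_circle(self):
        # 1 kb circle, 50 bp copies at 1-based starts 1 and 401
        genome, pair = make_genome(1000, 0, 400, 50)
        cs = mf.enumerate_conformations(genome, pair, flank=100)
        assert sorted(cs.subcircle_sizes) == [400, 600]
        assert sum(cs.subcircle_sizes) == 1000
        oracle = surgery_oracle(genome.sequence, 0, 400, 50, "direct")
        assert sorted(len(m) for m in oracle) == [400, 600]
        for mol, expected in zip(cs.alt_circles, oracle):
            assert mol.sequence == expected

    def test_table_scale_direct_pair_subcircles(self):
        # copies at 1-5616 and 265,249-270,864 on a 380,980 bp circle
        genome, pair = make_genome(380_980, 0, 265_248, 5616, seed=3)
        cs = mf.enumerate_conformations(genome, pair)
        assert sorted(cs.subcircle_sizes) == [115_732, 265_248]
        assert sum(cs.subcircle_sizes) == 380_980

    def test_inverted_pair_conserves_length(self):
        genome, pair = make_genome(20_000, 2_000, 12_000, 500, "inverted")
        cs = mf.enumerate_conformations(genome, pair)
        assert cs.subcircle_sizes == (20_000,)
        assert len(cs.alt_circles[0]) == len(genome)

    def test_direct_base_multiset_conserved_across_subcircles(self):
        genome, pair = make_genome(5000, 300, 2500, 200, seed=9)
        cs = mf.enumerate_conformations(genome, pair, flank=50)
        combined = "".join(sorted(cs.alt_circles[0].sequence + cs.alt_circles[1].sequence))
        assert combined == "".join(sorted(genome.sequence))

    def test_inverted_conserves_double_stranded_content(self):
        genome, pair = make_genome(5000, 300, 2500, 200, "inverted", seed=9)
        cs = mf.enumerate_conformations(genome, pair, flank=50)
        alt = cs.alt_circles[0].sequence
        g = genome.sequence
        assert len(alt) == len(g)
        # inversion reverse-complements a segment: A+T and C+G totals survive
        assert alt.count("A") + alt.count("T") == g.count("A") + g.count("T")
        assert alt.count("C") + alt.count("G") == g.count("C") + g.count("G")

    @pytest.mark.parametrize("orientation", ["direct", "inverted"])
    def test_junctions_are_substrings_of_surgery_products(self, orientation):
        rng = np.random.default_rng(555)
        for _ in range(50):
            L = int(rng.integers(2000, 6000))
            rlen = int(rng.integers(60, 300))
            a1 = int(rng.integers(100, L // 3))
            a2 = int(rng.integers(a1 + rlen + 100, 2 * L // 3))
            genome, pair = make_genome(L, a1, a2, rlen, orientation, seed=int(rng.integers(1e6)))
            cs = mf.enumerate_conformations(genome, pair, flank=50)
            alt_doubled = [m + m for m in (c.sequence for c in cs.alt_circles)]
            for j in cs.alt_junctions:
                assert any(j in d for d in alt_doubled)
            master_doubled = genome.sequence * 2
            for j in cs.master_junctions:
                assert j in master_doubled

    def test_overlapping_copies_rejected(self):
        genome, _ = make_genome(5000, 300, 2500, 200)
        bad = mf.RepeatPair("X", 300, (100, 400), (250, 550), "direct", 100.0)
        with pytest.raises(ValueError, match="overlap"):
            mf.enumerate_conformations(genome, bad)


class TestClassifyRead:
    def test_master_read_is_master(self, toy_confs):
        genome, pair, cs = toy_confs
        read = genome.fetch(pair.copy1[0] - 400, 300 + 800)
        assert mf.classify_read(read, cs) == MASTER

    def test_alt_junction_read_is_alternative(self, toy_confs):
        _, _, cs = toy_confs
        read = cs.alt_circles[0].fetch(-400, 300 + 800)
        assert mf.classify_read(read, cs) == ALTERNATIVE

    def test_reverse_strand_read_classified_identically(self, toy_confs):
        genome, pair, cs = toy_confs
        read = genome.fetch(pair.copy1[0] - 400, 300 + 800)
        assert mf.classify_read(revcomp(read), cs) == MASTER

    def test_read_inside_repeat_uninformative(self, toy_confs):
        genome, pair, cs = toy_confs
        read = genome.fetch(pair.copy1[0] + 10, 280)
        assert mf.classify_read(read, cs) == UNINFORMATIVE

    def test_read_touching_one_flank_uninformative(self, toy_confs):
        genome, pair, cs = toy_confs
        read = genome.fetch(pair.copy1[0] - 400, 400 + 150)  # stops inside the repeat
        assert mf.classify_read(read, cs) == UNINFORMATIVE

    def test_empty_and_unrelated_reads_uninformative(self, toy_confs):
        _, _, cs = toy_confs
        assert mf.classify_read("", cs) == UNINFORMATIVE
        rng = np.random.default_rng(4)
        assert mf.classify_read(random_dna(rng, 1000), cs) == UNINFORMATIVE

    def test_anchor_must_not_exceed_flank(self, toy_confs):
        _, _, cs = toy_confs
        with pytest.raises(ValueError):
            mf.classify_read("ACGT" * 300, cs, anchor=cs.flank + 1)

    def test_mixture_recovery_2000_reads_5pct_error(self):
        # 50/50 mixture, 5 % total error: recovered alt fraction within
        # +-5 points of truth (reads must dwarf repeat + anchors to span)
        genome, pair = make_genome(30_000, 5_000, 20_000, 1_000, seed=8)
        cs = mf.enumerate_conformations(genome, pair)
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 0.5, cs.conformation_id: 0.5},
            n_reads=2000,
            length_distribution=(np.log(8000.0), 0.3),
            substitution_rate=0.03,
            insertion_rate=0.01,
            deletion_rate=0.01,
            seed=13,
        )
        reads = mf.simulate_reads(genome, [cs], spec)
        labels = mf.classify_reads([r.sequence for r in reads], cs)
        n_m, n_a, _ = mf.recombination.tally_labels(labels)
        assert n_m + n_a > 500
        frac_alt = 100.0 * n_a / (n_m + n_a)
        assert abs(frac_alt - 50.0) <= 5.0

    def test_zero_error_pure_master_gives_zero_alt(self, toy_confs):
        genome, _, cs = toy_confs
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 1.0},
            n_reads=300,
            length_distribution=(np.log(3000.0), 0.3),
            substitution_rate=0.0,
            insertion_rate=0.0,
            deletion_rate=0.0,
            seed=21,
        )
        reads = mf.simulate_reads(genome, [cs], spec)
        labels = mf.classify_reads([r.sequence for r in reads], cs)
        counts = Counter(labels)
        assert counts[ALTERNATIVE] == 0
        assert counts[MASTER] > 0


class TestSupportTable:
    @pytest.mark.parametrize(
        "n_m,n_a,fm,fa",
        [
            (40, 48, 45.45, 54.55),
            (66, 64, 50.77, 49.23),
            (10, 16, 38.46, 61.54),
            (184, 6, 96.84, 3.16),
            (0, 5, 0.0, 100.0),
        ],
    )
    def test_fraction_arithmetic(self, n_m, n_a, fm, fa):
        rec = mf.support_record("R", n_m, n_a)
        assert (rec.frac_master, rec.frac_alt) == (fm, fa)

    def test_fractions_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_m, n_a = int(rng.integers(0, 500)), int(rng.integers(1, 500))
            rec = mf.support_record("R", n_m, n_a)
            assert abs(rec.frac_master + rec.frac_alt - 100.0) < 0.011

    def test_zero_informative_reads_undefined_not_zero(self):
        rec = mf.support_record("R", 0, 0, 7)
        assert rec.frac_master is None and rec.frac_alt is None
        frame = mf.recombination.support_to_frame([rec])
        assert frame.loc[0, "frac_master_percent"] == "NA"

    def test_records_ordered_by_repeat_length_descending(self):
        pairs = [
            mf.RepeatPair("Ra", 200, (0, 200), (1000, 1200), "direct", 100.0),
            mf.RepeatPair("Rb", 5000, (2000, 7000), (9000, 14_000), "direct", 100.0),
        ]
        table = mf.support_table(
            {"Ra": ["master"] * 3, "Rb": ["alternative"] * 2}, pairs
        )
        assert [r.repeat_id for r in table] == ["Rb", "Ra"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mf.support_record("R", -1, 5)


class TestMultipartite:
    def _support(self, frac_alt_percent, rid="R1"):
        n_alt = int(round(frac_alt_percent))
        return mf.support_record(rid, 100 - n_alt, n_alt)

    def test_active_direct_repeat_yields_two_circles_summing_to_master(self):
        genome, pair = make_genome(10_000, 1000, 6000, 400)
        model = mf.infer_multipartite([self._support(54.0)], genome, [pair])
        assert model.active[0][0] == "R1"
        sizes = [c.size for c in model.circles["R1"]]
        assert sum(sizes) == len(genome)
        assert sorted(sizes) == [5000, 5000]

    def test_low_support_repeat_inactive(self):
        genome, pair = make_genome(10_000, 1000, 6000, 400)
        model = mf.infer_multipartite([self._support(2.0)], genome, [pair])
        assert model.active == ()
        assert model.circles == {}
        assert model.inactive[0][0] == "R1"

    def test_no_repeats_master_circle_only(self):
        genome, _ = make_genome(10_000, 1000, 6000, 400)
        model = mf.infer_multipartite([], genome, [])
        assert model.active == () and model.circles == {}
        assert model.master_length == 10_000

    def test_every_master_base_in_exactly_one_subcircle(self):
        genome, pair = make_genome(10_000, 1000, 6000, 400)
        model = mf.infer_multipartite([self._support(50.0)], genome, [pair])
        from mitoforms.intervals import covered_length, wrap_intervals

        segs = [s for c in model.circles["R1"] for s in c.segments]
        assert covered_length(wrap_intervals(segs, 10_000)) == 10_000

    def test_interleaving_active_repeats_flagged_ambiguous(self):
        spec = mf.SimGenomeSpec(
            genome_length=20_000,
            repeat_plants=(
                mf.RepeatPlant(300, 1000, 10_000),
                mf.RepeatPlant(300, 5_000, 15_000),
            ),
            seed=6,
        )
        genome, _, _ = mf.build_genome(spec)
        pairs = [
            mf.RepeatPair("R1", 300, (1000, 1300), (10_000, 10_300), "direct", 100.0),
            mf.RepeatPair("R2", 300, (5000, 5300), (15_000, 15_300), "direct", 100.0),
        ]
        support = [self._support(50.0, "R1"), self._support(40.0, "R2")]
        model = mf.infer_multipartite(support, genome, pairs)
        assert model.ambiguous
        assert set(model.circles) == {"R1", "R2"}  # pairwise products still emitted

    def test_inverted_active_repeat_listed_as_inversion(self):
        genome, pair = make_genome(10_000, 1000, 6000, 400, "inverted")
        model = mf.infer_multipartite([self._support(30.0)], genome, [pair])
        assert model.inversions == ("R1",)
        assert model.circles == {}
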