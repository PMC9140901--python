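"""Generator correctness: planted structure, determinism, error calibration."""

import edlib
import numpy as np
import pytest
from scipy import stats

import mitoforms as mf
from mitoforms import revcomp


def _extract(genome, start, length):
    return genome.fetch(start, length)


class TestBuildGenome:
    def test_direct_plant_copies_are_identical(self):
        spec = mf.SimGenomeSpec(
            genome_length=1000, repeat_plants=(mf.RepeatPlant(50, 0, 400),), seed=7
        )
        mito, _, truth = mf.build_genome(spec)
        assert _extract(mito, 0, 50) == _extract(mito, 400, 50)
        rec = [t for t in truth if t.kind == "repeat"][0]
        assert (rec.mito_start, rec.mito_start2) == (0, 400)

    def test_inverted_plant_is_reverse_complement(self):
        spec = mf.SimGenomeSpec(
            genome_length=1000,
            repeat_plants=(mf.RepeatPlant(60, 100, 600, "inverted"),),
            seed=7,
        )
        mito, _, _ = mf.build_genome(spec)
        assert _extract(mito, 600, 60) == revcomp(_extract(mito, 100, 60))

    def test_full_scale_molecule_length(self):
        # the scale this generator emulates: a ~381 kb circle carrying
        # dispersed repeats of 5616, 4148 and 283 bp
        spec = mf.SimGenomeSpec(
            genome_length=380_980,
            repeat_plants=(
                mf.RepeatPlant(5616, 0, 265_248),
                mf.RepeatPlant(4148, 30_845, 305_623),
                mf.RepeatPlant(283, 100_000, 380_697),
            ),
            seed=1,
        )
        mito, _, _ = mf.build_genome(spec)
        assert len(mito) == 380_980

    def test_overlapping_plants_rejected_with_interval_names(self):
        spec = mf.SimGenomeSpec(
            genome_length=1000, repeat_plants=(mf.RepeatPlant(300, 100, 250),), seed=7
        )
        with pytest.raises(ValueError, match=r"repeat1\.copy1.*repeat1\.copy2"):
            mf.build_genome(spec)

    def test_mtpt_plant_identical_in_both_molecules(self):
        spec = mf.SimGenomeSpec(
            genome_length=5000,
            mtpt_plants=(mf.MtptPlant(500, 1000),),
            plastid_length=3000,
            seed=3,
        )
        mito, plastid, truth = mf.build_genome(spec)
        rec = [t for t in truth if t.kind == "mtpt"][0]
        assert _extract(mito, rec.mito_start, 500) == _extract(plastid, rec.plastid_start, 500)

    def test_determinism_same_spec_same_bytes(self, tmp_path):
        spec = mf.SimGenomeSpec(
            genome_length=3000, repeat_plants=(mf.RepeatPlant(200, 0, 1500),), seed=11
        )
        paths = []
        for i in range(2):
            mito, plastid, _ = mf.build_genome(spec)
            p = tmp_path / f"run{i}.fasta"
            mf.write_fasta([mito, plastid], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_records_reproduce_planted_sequences(self):
        spec = mf.SimGenomeSpec(
            genome_length=8000,
            repeat_plants=(
                mf.RepeatPlant(150, 100, 4000),
                mf.RepeatPlant(120, 1000, 6000, "inverted"),
            ),
            mtpt_plants=(mf.MtptPlant(300, 2500),),
            plastid_length=4000,
            seed=5,
        )
        mito, plastid, truth = mf.build_genome(spec)
        for t in truth:
            if t.kind == "repeat":
                c1 = _extract(mito, t.mito_start, t.length)
                c2 = _extract(mito, t.mito_start2, t.length)
                assert c2 == (c1 if t.orientation == "direct" else revcomp(c1))
            else:
                assert _extract(mito, t.mito_start, t.length) == _extract(
                    plastid, t.plastid_start, t.length
                )


class TestSimulateReads:
    def _genome_and_confs(self, seed=42):
        spec = mf.SimGenomeSpec(
            genome_length=6000, repeat_plants=(mf.RepeatPlant(300, 500, 3000),), seed=seed
        )
        genome, _, _ = mf.build_genome(spec)
        pair = mf.RepeatPair("R1", 300, (500, 800), (3000, 3300), "direct", 100.0)
        return genome, mf.enumerate_conformations(genome, pair, flank=500)

    def test_zero_error_master_reads_are_exact_substrings(self):
        genome, confs = self._genome_and_confs()
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 1.0},
            n_reads=100,
            length_distribution=(np.log(800.0), 0.3),
            substitution_rate=0.0,
            insertion_rate=0.0,
            deletion_rate=0.0,
            seed=9,
        )
        doubled = genome.sequence * 2
        doubled_rc = revcomp(doubled)
        for r in mf.simulate_reads(genome, [confs], spec):
            assert r.sequence in doubled or r.sequence in doubled_rc

    def test_mixture_label_counts_within_binomial_bounds(self):
        genome, confs = self._genome_and_confs()
        n = 2000
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 0.5, confs.conformation_id: 0.5},
            n_reads=n,
            length_distribution=(np.log(600.0), 0.3),
            seed=17,
        )
        reads = mf.simulate_reads(genome, [confs], spec)
        n_master = sum(1 for r in reads if r.true_conformation == "master")
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= n_master <= hi

    def test_error_rate_calibration_poisson_bound(self):
        genome, confs = self._genome_and_confs()
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 1.0},
            n_reads=1,
            length_distribution=(np.log(3000.0), 0.01),
            substitution_rate=0.05,
            insertion_rate=0.0,
            deletion_rate=0.0,
            seed=23,
        )
        (read,) = mf.simulate_reads(genome, [confs], spec)
        mol, start, strand = read.true_origin
        # reconstruct the error-free fragment and measure the edit distance
        frag = genome.fetch(start, len(read.sequence))
        if strand == "-":
            frag = revcomp(frag)
        d = edlib.align(read.sequence, frag, mode="NW")["editDistance"]
        lam = 0.05 * len(frag)
        # substitution draws are binomial; each substitution costs <= 1 edit
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= d <= hi

    def test_mixture_calibration_chi_square_large_n(self):
        genome, confs = self._genome_and_confs()
        weights = {"master": 0.6, confs.conformation_id: 0.4}
        spec = mf.ReadSimSpec(
            conformation_weights=weights,
            n_reads=10_000,
            length_distribution=(np.log(300.0), 0.2),
            substitution_rate=0.0,
            insertion_rate=0.0,
            deletion_rate=0.0,
            seed=31,
        )
        reads = mf.simulate_reads(genome, [confs], spec)
        obs = [
            sum(1 for r in reads if r.true_conformation == cid) for cid in sorted(weights)
        ]
        exp = [10_000 * weights[cid] for cid in sorted(weights)]
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_read_longer_than_molecule_truncated_and_flagged(self):
        genome, confs = self._genome_and_confs()
        spec = mf.ReadSimSpec(
            conformation_weights={"master": 1.0},
            n_reads=5,
            length_distribution=(np.log(50_000.0), 0.01),
            seed=2,
        )
        for r in mf.simulate_reads(genome, [confs], spec):
            assert r.wrapped

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mf.ReadSimSpec(conformation_weights={"master": 0.7}, n_reads=10)
        with pytest.raises(ValueError, match="substitution_rate"):
            mf.ReadSimSpec(
                conformation_weights={"master": 1.0}, n_reads=10, substitution_rate=0.5
            )
        genome, confs = self._genome_and_confs()
        spec = mf.ReadSimSpec(conformation_weights={"ghost": 1.0}, n_reads=10)
        with pytest.raises(ValueError, match="ghost"):
            mf.simulate_reads(genome, [confs], spec)
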