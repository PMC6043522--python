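"""Generator marginals, determinism, and truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from saccpop import synthgen as sg


def _spec(**kw):
    defaults = dict(chromosomes=(("chrI", 10_000),), seed=1)
    defaults.update(kw)
    return sg.GenomeSpec(**defaults)


class TestGenomeSpec:
    def test_rejects_zero_length_chromosome(self):
        with pytest.raises(ValueError):
            sg.GenomeSpec(chromosomes=(("chrI", 0),))

    def test_rejects_gene_outside_chromosome(self):
        with pytest.raises(ValueError):
            sg.GenomeSpec(chromosomes=(("chrI", 1000),),
                          genes=(sg.GeneInterval("g", "chrI", 500, 1500),))


class TestAncestor:
    def test_length_and_alphabet(self):
        seqs = sg.simulate_ancestor(_spec())
        assert seqs["chrI"].size == 10_000
        assert set(np.unique(seqs["chrI"])) <= {0, 1, 2, 3}

    def test_same_spec_is_deterministic(self):
        a = sg.simulate_ancestor(_spec())
        b = sg.simulate_ancestor(_spec())
        assert np.array_equal(a["chrI"], b["chrI"])

    def test_different_seeds_mismatch_near_three_quarters(self):
        a = sg.simulate_ancestor(_spec(seed=1))["chrI"]
        b = sg.simulate_ancestor(_spec(seed=2))["chrI"]
        mismatch = float((a != b).mean())
        # two uniform sequences differ at 3/4 of sites; 3 sigma of
        # Binomial(10000, 0.75)
        assert abs(mismatch - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 10_000)


class TestEvolveHaplotype:
    def test_zero_divergence_is_identity(self):
        ref = sg.simulate_ancestor(_spec())
        hap, pos = sg.evolve_haplotype(ref, 0.0, np.random.default_rng(0))
        assert np.array_equal(hap["chrI"], ref["chrI"])
        assert pos["chrI"].size == 0

    def test_substitution_count_is_binomial(self):
        spec = sg.GenomeSpec(chromosomes=(("chrI", 100_000),), seed=3)
        ref = sg.simulate_ancestor(spec)
        hap, pos = sg.evolve_haplotype(ref, 0.01, np.random.default_rng(1))
        n = pos["chrI"].size
        sigma = np.sqrt(100_000 * 0.01 * 0.99)
        assert abs(n - 1000) < 3 * sigma
        assert np.array_equal(np.nonzero(hap["chrI"] != ref["chrI"])[0],
                              pos["chrI"])

    def test_two_haplotypes_add_divergence(self):
        spec = sg.GenomeSpec(chromosomes=(("chrI", 100_000),), seed=4)
        ref = sg.simulate_ancestor(spec)
        rng = np.random.default_rng(2)
        a, _ = sg.evolve_haplotype(ref, 0.008, rng)
        b, _ = sg.evolve_haplotype(ref, 0.008, rng)
        d = float((a["chrI"] != b["chrI"]).mean())
        # additive minus coincident hits: 2p(1-p) + p^2 * 2/3
        expect = 2 * 0.008 * 0.992 + 0.008 ** 2 * 2 / 3
        assert abs(d - expect) < 3 * np.sqrt(expect * (1 - expect) / 100_000)

    def test_out_of_range_divergence_rejected(self):
        ref = sg.simulate_ancestor(_spec())
        with pytest.raises(ValueError):
            sg.evolve_haplotype(ref, 0.2, np.random.default_rng(0))


class TestDiploid:
    def test_het_positions_are_exact_differences(self):
        ref = sg.simulate_ancestor(_spec())
        rng = np.random.default_rng(5)
        a, _ = sg.evolve_haplotype(ref, 0.005, rng)
        b, _ = sg.evolve_haplotype(ref, 0.005, rng)
        dip = sg.make_diploid(a, b)
        het = dip.het_positions()["chrI"]
        assert np.array_equal(het, np.nonzero(a["chrI"] != b["chrI"])[0])
        same = sg.make_diploid(a, a)
        assert same.n_het() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sg.DiploidGenome({"chrI": np.zeros(10, dtype=np.uint8)},
                             {"chrI": np.zeros(11, dtype=np.uint8)})


class TestPlantFeatures:
    def _setup(self):
        spec = _spec(genes=(sg.GeneInterval("g1", "chrI", 4000, 5500),))
        ref = sg.simulate_ancestor(spec)
        rng = np.random.default_rng(6)
        lib = sg.make_donor_library(ref, [("dz", "outside-genus", 0.15)], rng)
        dip = sg.make_diploid(ref, ref)
        return spec, ref, lib, dip

    def test_alien_fragment_identity_matches_divergence(self):
        spec, ref, lib, dip = self._setup()
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"),
                                aliens=[sg.PlantedFragment("dz", "chrI",
                                                           1000, 3000, 0.15)])
        sg.plant_features(dip, truth, lib, spec)
        seg = dip.hapA["chrI"][1000:3000]
        ident = float((seg == ref["chrI"][1000:3000]).mean())
        assert abs(ident - 0.85) < 3 * np.sqrt(0.85 * 0.15 / 2000)
        # both haplotypes carry the replacement
        assert np.array_equal(dip.hapA["chrI"], dip.hapB["chrI"])

    def test_overlapping_fragments_rejected(self):
        spec, ref, lib, dip = self._setup()
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"), aliens=[
            sg.PlantedFragment("dz", "chrI", 1000, 3000, 0.15),
            sg.PlantedFragment("dz", "chrI", 2500, 4500, 0.15)])
        with pytest.raises(ValueError, match="overlap"):
            sg.plant_features(dip, truth, lib, spec)

    def test_negative_copy_number_rejected(self):
        spec, ref, lib, dip = self._setup()
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"),
                                chrom_copies={"chrI": -1})
        with pytest.raises(ValueError, match="copy number"):
            sg.plant_features(dip, truth, lib, spec)


class TestPileups:
    def test_homozygous_site_error_free_counts(self):
        spec = _spec()
        ref = sg.simulate_ancestor(spec)
        dip = sg.make_diploid(ref, ref)
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"))
        p = sg.simulate_pileups(dip, ref, truth, spec, 100, 0.0,
                                np.random.default_rng(0))
        counts = p[["countA", "countC", "countG", "countT"]].to_numpy()
        assert (counts.sum(axis=1) == p["depth"].to_numpy()).all()
        assert ((counts > 0).sum(axis=1) <= 1).all()

    def test_het_site_allele_fraction_near_half(self):
        spec = _spec()
        ref = sg.simulate_ancestor(spec)
        alt = {"chrI": (ref["chrI"] + 1) % 4}   # every site heterozygous
        dip = sg.make_diploid(ref, alt)
        truth = sg.IsolateTruth("x", "dom", "D1", ("a", "b"))
        p = sg.simulate_pileups(dip, ref, truth, spec, 80, 0.0,
                                np.random.default_rng(1))
        counts = p[["countA", "countC", "countG", "countT"]].to_numpy()
        ref_counts = counts[np.arange(len(p)), ref["chrI"]]
        frac = ref_counts.sum() / p["depth"].sum()
        n = int(p["depth"].sum())
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_extra_chromosome_copy_scales_depth(self):
        spec = sg.GenomeSpec(chromosomes=(("chrI", 20_000), ("chrII", 20_000)),
                             seed=9)
        ref = sg.simulate_ancestor(spec)
        dip = sg.make_diploid(ref, ref)
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"),
                                chrom_copies={"chrI": 3})
        p = sg.simulate_pileups(dip, ref, truth, spec, 50, 0.0,
                                np.random.default_rng(2))
        m1 = p.loc[p.chrom == "chrI", "depth"].mean()
        m2 = p.loc[p.chrom == "chrII", "depth"].mean()
        assert abs(m1 / m2 - 1.5) < 0.05

    def test_reproducible_by_seed(self):
        spec = _spec()
        ref = sg.simulate_ancestor(spec)
        dip = sg.make_diploid(ref, ref)
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"))
        a = sg.simulate_pileups(dip, ref, truth, spec, 30, 0.01,
                                np.random.default_rng(42))
        b = sg.simulate_pileups(dip, ref, truth, spec, 30, 0.01,
                                np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_parameters_rejected(self):
        spec = _spec()
        ref = sg.simulate_ancestor(spec)
        dip = sg.make_diploid(ref, ref)
        truth = sg.IsolateTruth("x", "wild", "W1", ("W1", "W1"))
        with pytest.raises(ValueError):
            sg.simulate_pileups(dip, ref, truth, spec, 0.5, 0.0,
                                np.random.default_rng(0))
        with pytest.raises(ValueError):
            sg.simulate_pileups(dip, ref, truth, spec, 30, 0.5,
                                np.random.default_rng(0))


class TestFlowD:
    def test_noise_free_values_are_exact(self):
        assert sg.simulate_flow_D(2, 0.0) == 2.0
        assert sg.simulate_flow_D(1, 0.0) == 1.0

    def test_noisy_mean_concentrates(self):
        rng = np.random.default_rng(3)
        draws = [sg.simulate_flow_D(2, 0.05, rng) for _ in range(1000)]
        assert abs(np.mean(draws) - 2.0) < 0.01    # 3 sigma of CLT at n=1000
        assert min(draws) > 0


class TestCohort:
    def test_cohort_is_deterministic(self, small_spec, small_cohort):
        params = sg.CohortParams(n_wild=4, n_domesticated=4,
                                 mean_depth=50.0, error_rate=0.002)
        again = sg.simulate_cohort(small_spec, params, seed=7)
        for iid in small_cohort.isolate_ids:
            for chrom in small_cohort.isolates[iid].hapA:
                assert np.array_equal(small_cohort.isolates[iid].hapA[chrom],
                                      again.isolates[iid].hapA[chrom])
        assert small_cohort.truth_json() == again.truth_json()

    def test_truth_features_recoverable_from_sequences(self, small_cohort):
        """Every planted alien is visible as a diverged block against the
        unmodified ancestor; het counts match the haplotype differences."""
        ref = small_cohort.reference
        for iid, truth in small_cohort.truths.items():
            dip = small_cohort.isolates[iid]
            assert truth.n_het_sites == dip.n_het()
            for frag in truth.aliens:
                seg = dip.hapA[frag.chrom][frag.start:frag.end]
                div = float((seg != ref[frag.chrom][frag.start:frag.end]).mean())
                assert div > 0.5 * frag.divergence

    def test_wild_isolates_homozygous_domesticated_not(self, small_cohort):
        for iid, truth in small_cohort.truths.items():
            if truth.group == "wild":
                assert truth.n_het_sites == 0
            else:
                assert truth.n_het_sites > 0
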