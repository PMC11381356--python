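"""Synthetic-data generator: planted structures, counts and mixtures."""

import numpy as np
import pytest
from scipy import stats

from mapfold.reactivity import ReactivityProfile, raw_reactivity
from mapfold.regions import RegionSet
from mapfold.synth import (
    PlantedStructure,
    SimulationParams,
    StructurePlacementError,
    design_sequence,
    make_structure,
    mix_profiles,
    plant_motifs,
    simulate_counts,
    simulate_replicate,
    simulate_two_states,
)

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class TestMakeStructure:
    def test_single_helix_pair_count(self):
        st = make_structure(30, 1, (4, 4), seed=1)
        assert st.n_paired() == 8
        assert int(np.sum(st.pair_table == 0)) == 22

    def test_no_helices(self):
        st = make_structure(30, 0, seed=1)
        assert st.n_paired() == 0

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_invariants_validated_independently(self, seed):
        """Independent re-check of every structural invariant at n=200."""
        st = make_structure(200, 5, (4, 8), seed=seed)
        pt = st.pair_table
        pairs = [(i + 1, int(j)) for i, j in enumerate(pt) if j > i + 1]
        # no position in two pairs & symmetry
        partners = [p for ij in pairs for p in ij]
        assert len(partners) == len(set(partners))
        for i, j in pairs:
            assert pt[j - 1] == i
            assert j - i >= 4
            assert j - i <= 600
        for a, (i, j) in enumerate(pairs):
            for k, l in pairs[a + 1 :]:
                assert not (i < k < j < l or k < i < l < j)

    def test_placement_failure_is_explicit(self):
        with pytest.raises(StructurePlacementError):
            make_structure(30, 5, (4, 4), seed=1)

    def test_determinism(self):
        a = make_structure(120, 4, seed=3)
        b = make_structure(120, 4, seed=3)
        assert np.array_equal(a.pair_table, b.pair_table)


class TestDesignSequence:
    def test_gc_one_gives_gc_pairs(self):
        pt = np.zeros(30, dtype=np.int64)
        pt[0], pt[5] = 6, 1
        st = PlantedStructure(30, [(1, 6, 1)], pt)
        seq = design_sequence(st, gc_fraction=1.0, seed=2)
        assert (seq[0], seq[5]) in {("G", "C"), ("C", "G")}

    def test_gc_zero_gives_au_stems(self):
        st = make_structure(60, 2, (4, 5), seed=4)
        seq = design_sequence(st, gc_fraction=0.0, seed=5)
        for i, j in st.pairs:
            assert (seq[i - 1], seq[j - 1]) in {("A", "U"), ("U", "A")}

    def test_all_pairs_watson_crick(self):
        st = make_structure(150, 5, seed=6)
        seq = design_sequence(st, 0.5, seed=7)
        for i, j in st.pairs:
            assert (seq[i - 1], seq[j - 1]) in WC

    def test_gc_count_binomial_mean(self):
        """Over many seeds the GC-pair count matches Binomial(10, 0.5)."""
        st = make_structure(80, 2, (5, 5), seed=8)
        assert len(st.pairs) == 10
        counts = []
        for s in range(500):
            seq = design_sequence(st, 0.5, seed=s)
            counts.append(
                sum({seq[i - 1], seq[j - 1]} == {"G", "C"} for i, j in st.pairs)
            )
        # mean 5, sd of the mean = sqrt(10*0.25/500) ~ 0.07; allow 4 sigma
        assert abs(np.mean(counts) - 5.0) < 0.3


class TestSimulateCounts:
    def test_zero_scale_null_case(self):
        st = make_structure(100, 3, seed=1)
        params = SimulationParams(mod_scale=0.0)
        mod = simulate_counts(st, params, "modified", 2)
        assert np.allclose(mod.rate, mod.background)

    def test_mean_rate_difference_matches_closed_form(self):
        """Fully unpaired molecule: E[mod - untr rate] = s * E[Gamma(2, .35)]."""
        st = make_structure(100, 0, seed=1)
        params = SimulationParams()
        diffs = []
        for s in range(500):
            mod = simulate_counts(st, params, "modified", s)
            untr = simulate_counts(
                st, params, "untreated", s + 10_000,
                latent=mod.latent, background=mod.background,
            )
            diffs.append(np.mean(mod.table.rate - untr.table.rate))
        expected = 0.02 * 2 * 0.35  # s * shape * scale = 0.014
        assert abs(np.mean(diffs) - expected) < 5e-4

    def test_depth_median(self):
        st = make_structure(400, 0, seed=2)
        mod = simulate_counts(st, SimulationParams(), "modified", 3)
        assert abs(np.median(mod.table.depth) - 50_000) < 600

    def test_events_never_exceed_depth(self):
        st = make_structure(200, 6, seed=4)
        for ch in ("modified", "untreated"):
            sim = simulate_counts(st, SimulationParams(), ch, 5)
            assert np.all(sim.table.events <= sim.table.depth)

    def test_seed_reproducibility(self):
        st = make_structure(100, 3, seed=1)
        a = simulate_counts(st, SimulationParams(), "modified", 9)
        b = simulate_counts(st, SimulationParams(), "modified", 9)
        assert np.array_equal(a.table.events, b.table.events)
        assert np.array_equal(a.table.depth, b.table.depth)

    def test_paired_unpaired_separation(self):
        """Rate differences at unpaired positions dominate paired ones."""
        st = make_structure(200, 8, (5, 8), seed=6)
        params = SimulationParams()
        mod = simulate_counts(st, params, "modified", 7)
        untr = simulate_counts(
            st, params, "untreated", 8,
            latent=mod.latent, background=mod.background,
        )
        diff = mod.table.rate - untr.table.rate
        paired = st.pair_table > 0
        res = stats.mannwhitneyu(
            diff[~paired], diff[paired], alternative="greater"
        )
        assert res.pvalue < 0.01


class TestSimulateTwoStates:
    def test_full_core_gives_identical_states(self):
        core = RegionSet.from_tuples([(1, 300)])
        ds = simulate_two_states(core, 300, seed=1, flank_helix_spacing=10**9)
        assert np.array_equal(
            ds.structures["A"].pair_table, ds.structures["B"].pair_table
        )

    def test_empty_core_gives_independent_states(self):
        ds = simulate_two_states(RegionSet(), 400, seed=2)
        assert not np.array_equal(
            ds.structures["A"].pair_table, ds.structures["B"].pair_table
        )

    def test_one_sequence_satisfies_both_states(self):
        core = RegionSet.from_tuples([(101, 220)])
        ds = simulate_two_states(core, 400, seed=3)
        for st in ("A", "B"):
            for i, j in ds.structures[st].pairs:
                assert (ds.sequence[i - 1], ds.sequence[j - 1]) in WC

    def test_replicate_rate_difference_correlation(self):
        """Same state, two replicates: raw rate differences correlate > 0.9."""
        core = RegionSet.from_tuples([(101, 300)])
        ds = simulate_two_states(core, 500, seed=4)
        (m1, u1), (m2, u2) = ds.replicates["A"][:2]
        d1 = m1.table.rate - u1.table.rate
        d2 = m2.table.rate - u2.table.rate
        assert stats.pearsonr(d1, d2).statistic > 0.9

    def test_core_outside_molecule_rejected(self):
        with pytest.raises(ValueError):
            simulate_two_states(RegionSet.from_tuples([(1, 500)]), 300, seed=1)


class TestMixProfiles:
    def _profiles(self, rng):
        mono = ReactivityProfile(rng.gamma(2, 0.35, 60))
        dim = ReactivityProfile(rng.gamma(2, 0.35, 60))
        return mono, dim

    def test_endpoints(self, rng):
        mono, dim = self._profiles(rng)
        assert np.allclose(mix_profiles(mono, dim, 0.0).values, mono.values)
        assert np.allclose(mix_profiles(mono, dim, 1.0).values, dim.values)

    def test_arithmetic(self):
        mono = ReactivityProfile(np.array([1.0] * 60))
        dim = ReactivityProfile(np.array([0.2] * 60))
        out = mix_profiles(mono, dim, 0.4)
        assert np.allclose(out.values, 0.68)

    def test_mask_union(self, rng):
        mono, dim = self._profiles(rng)
        mono.mask[3] = True
        dim.mask[7] = True
        out = mix_profiles(mono, dim, 0.5)
        assert out.mask[3] and out.mask[7]
        assert not out.mask[5]

    def test_length_mismatch(self, rng):
        mono, _ = self._profiles(rng)
        with pytest.raises(ValueError):
            mix_profiles(mono, ReactivityProfile(np.ones(10)), 0.5)


class TestPlantMotifs:
    def test_single_motif(self):
        assert plant_motifs("C", 10, [("AUUAAU", 3)]) == "CCAUUAAUCC"

    def test_homopolymer(self):
        assert plant_motifs("A", 8, []) == "A" * 8

    def test_printed_hexamers_non_background_count(self):
        from mapfold.datasets import TY3_5P_PALINDROMES

        seq = plant_motifs("C", 429, TY3_5P_PALINDROMES)
        # the six hexamers carry 29 letters that are not C themselves
        assert sum(1 for c in seq if c != "C") == 29

    def test_overlap_and_range_errors(self):
        with pytest.raises(ValueError):
            plant_motifs("C", 10, [("AUUAAU", 8)])
        with pytest.raises(ValueError):
            plant_motifs("C", 20, [("AUUAAU", 3), ("GGG", 5)])
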