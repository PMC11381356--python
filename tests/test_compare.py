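"""Two-state comparison analytics against naive reference implementations."""

import numpy as np
import pytest

from mapfold.compare import (
    ComparisonScore,
    WindowConfig,
    delta_shape,
    g_minus_a,
    gini,
    gini_profile,
    hp_basepairs,
    local_bp_content,
    lowss_regions,
    score_structures,
    sliding_stat,
    well_folded_core,
)
from mapfold.fold import PairProbabilityMatrix, SecondaryStructure
from mapfold.reactivity import ReactivityProfile
from mapfold.regions import RegionSet

from oracles import naive_gini, naive_sliding


def make_structure_from_pairs(n, pairs, seq=None):
    pt = np.zeros(n, dtype=int)
    for i, j in pairs:
        pt[i - 1], pt[j - 1] = j, i
    return SecondaryStructure(seq or "A" * n, pt)


class TestSlidingStat:
    def test_constant_profile(self):
        track = sliding_stat(np.full(100, 2.5), WindowConfig(), "median")
        assert np.allclose(track, 2.5)

    def test_median_order_statistic(self):
        track = sliding_stat(
            np.array([0.0, 0, 0, 5, 5]), WindowConfig(stat_window=5), "median"
        )
        assert track[2] == 0.0

    @pytest.mark.parametrize("stat,fn", [("median", np.median), ("mean", np.mean)])
    def test_matches_naive_recomputation(self, rng, stat, fn):
        vals = rng.gamma(2, 0.35, 120)
        mask = rng.random(120) < 0.2
        vals[mask] = np.nan
        prof = ReactivityProfile(vals)
        got = sliding_stat(prof, WindowConfig(stat_window=7), stat)
        want = naive_sliding(prof.values, prof.mask, 7, fn)
        assert np.allclose(got, want, equal_nan=True)

    def test_low_data_window_masked(self):
        vals = np.full(30, np.nan)
        vals[::6] = 1.0  # 1 of 6 positions has data
        track = sliding_stat(vals, WindowConfig(stat_window=5), "mean")
        assert np.all(np.isnan(track))


class TestGini:
    def test_uniform_is_zero(self):
        assert gini(np.full(51, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        assert gini(np.array([0.0, 0, 0, 1])) == pytest.approx(0.75)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            x = rng.gamma(2, 0.35, 51)
            assert gini(x) == pytest.approx(naive_gini(x))

    def test_scale_invariance_and_range(self, rng):
        for _ in range(10):
            x = rng.gamma(2, 0.35, 40)
            g = gini(x)
            assert gini(3.7 * x) == pytest.approx(g)
            assert 0.0 <= g <= 1.0 - 1.0 / len(x)

    def test_degenerate_cases(self):
        assert np.isnan(gini(np.array([1.0])))
        assert np.isnan(gini(np.zeros(10)))

    def test_profile_clips_negatives_and_masks_zero_windows(self):
        vals = np.concatenate([np.full(60, -0.2), np.full(60, 1.0)])
        track, global_g = gini_profile(vals, WindowConfig(stat_window=51))
        # all-negative windows clip to zero mean -> masked
        assert np.isnan(track[10])
        assert np.isfinite(track[90])
        assert np.isfinite(global_g)


class TestDeltaShape:
    def _profile(self, values, se=0.05):
        return ReactivityProfile(values, np.full(len(values), se))

    def test_identical_states_no_sites(self, rng):
        vals = rng.gamma(2, 0.35, 150)
        a = self._profile(vals)
        regions, tracks = delta_shape(a, self._profile(vals.copy()))
        assert len(regions) == 0
        assert tracks["called"].sum() == 0

    def test_planted_difference_called(self, rng):
        base = rng.gamma(2, 0.35, 150)
        other = base.copy()
        other[70:80] += 1.0
        regions, tracks = delta_shape(self._profile(other), self._profile(base))
        called = np.nonzero(tracks["called"])[0] + 1
        assert len(called) >= 8
        assert called.min() >= 69 and called.max() <= 82
        assert all(r.label == "A>B" for r in regions)

    def test_sign_recorded(self, rng):
        base = rng.gamma(2, 0.35, 150)
        other = base.copy()
        other[40:50] += 1.0
        regions, _ = delta_shape(self._profile(base), self._profile(other))
        assert any(r.label == "B>A" for r in regions)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            delta_shape(
                self._profile(rng.gamma(2, 0.35, 10)),
                self._profile(rng.gamma(2, 0.35, 12)),
            )


class TestHpBasepairs:
    def _ppm(self, n, entries):
        p = np.zeros((n, n))
        for i, j, v in entries:
            p[i - 1, j - 1] = p[j - 1, i - 1] = v
        return PairProbabilityMatrix(p)

    def test_strict_threshold_boundary(self):
        ppm = self._ppm(10, [(1, 8, 0.8), (2, 7, 0.81)])
        hp = hp_basepairs(ppm, 0.8)
        assert [(i, j) for i, j, _ in hp] == [(2, 7)]

    def test_at_most_one_partner_per_position(self, fold_cfg, rng):
        from mapfold.fold import pair_probabilities

        seq = "".join(rng.choice(list("ACGU"), 120))
        hp = hp_basepairs(pair_probabilities(seq, None, fold_cfg), 0.8)
        flat = [p for ij in ((i, j) for i, j, _ in hp) for p in ij]
        assert len(flat) == len(set(flat))


class TestLowssRegions:
    def test_constant_tracks_give_nothing(self):
        r = lowss_regions(np.ones(300), np.ones(300))
        assert len(r) == 0

    def test_planted_low_segment(self):
        react = np.full(400, 1.0)
        entr = np.full(400, 1.0)
        react[100:200] = 0.1
        entr[100:200] = 0.05
        regions = lowss_regions(react, entr, WindowConfig(stat_window=51))
        assert len(regions) == 1
        r = regions.regions[0]
        assert abs(r.start - 101) <= 26 and abs(r.end - 200) <= 26

    def test_merge_gap(self):
        react = np.full(400, 1.0)
        entr = np.full(400, 1.0)
        react[100:150] = react[158:208] = 0.1
        entr[100:150] = entr[158:208] = 0.05
        regions = lowss_regions(
            react, entr, WindowConfig(stat_window=5), merge_gap=10, min_len=40
        )
        assert len(regions) == 1

    def test_min_length_filter(self):
        react = np.full(400, 1.0)
        entr = np.full(400, 1.0)
        react[100:120] = 0.1
        entr[100:120] = 0.05
        regions = lowss_regions(react, entr, WindowConfig(stat_window=5),
                                min_len=40)
        assert len(regions) == 0


class TestWellFoldedCore:
    def _inputs(self, n=300):
        pairs = [(110, 150), (111, 149), (112, 148)]
        mfe = make_structure_from_pairs(n, pairs)
        hp = [(110, 150, 0.9), (111, 149, 0.95)]
        lowss = RegionSet.from_tuples([(100, 160)])
        return lowss, mfe, hp

    def test_identical_states_idempotent(self):
        lowss, mfe, hp = self._inputs()
        core, cov = well_folded_core(lowss, lowss, mfe, mfe, hp, hp)
        assert core == lowss
        assert cov == pytest.approx(100.0 * 61 / 300)

    def test_disjoint_lowss_empty_core(self):
        lowss, mfe, hp = self._inputs()
        other = RegionSet.from_tuples([(200, 260)])
        core, cov = well_folded_core(lowss, other, mfe, mfe, hp, hp)
        assert len(core) == 0 and cov == 0.0

    def test_shared_pair_fraction_gate(self):
        lowss, mfe_a, hp = self._inputs()
        # state B pairs entirely different inside the candidate
        mfe_b = make_structure_from_pairs(300, [(115, 145), (116, 144), (117, 143)])
        core, _ = well_folded_core(lowss, lowss, mfe_a, mfe_b, hp, hp)
        assert len(core) == 0

    def test_requires_shared_hp_pair(self):
        lowss, mfe, hp = self._inputs()
        hp_b = [(20, 60, 0.9)]  # no HP pair inside the candidate in state B
        core, _ = well_folded_core(lowss, lowss, mfe, mfe, hp, hp_b)
        assert len(core) == 0


class TestScoreStructures:
    def test_identical(self):
        s = make_structure_from_pairs(50, [(1, 50), (2, 49), (10, 30)])
        sc = score_structures(s, s)
        assert (sc.sensitivity, sc.ppv) == (100.0, 100.0)

    def test_half_predicted(self):
        ref = make_structure_from_pairs(50, [(1, 50), (2, 49), (10, 30), (11, 29)])
        pred = make_structure_from_pairs(50, [(1, 50), (2, 49)])
        sc = score_structures(ref, pred)
        assert sc.sensitivity == 50.0 and sc.ppv == 100.0

    def test_slip_one_register_tolerance(self):
        ref = make_structure_from_pairs(60, [(10, 51)])
        pred = make_structure_from_pairs(60, [(10, 50)])
        assert score_structures(ref, pred, slip=0).matched == 0
        assert score_structures(ref, pred, slip=1).matched == 1

    def test_swap_symmetry(self):
        ref = make_structure_from_pairs(60, [(1, 60), (2, 59), (20, 40)])
        pred = make_structure_from_pairs(60, [(1, 60), (20, 40), (21, 39)])
        a = score_structures(ref, pred)
        b = score_structures(pred, ref)
        assert a.sensitivity == pytest.approx(b.ppv)
        assert a.ppv == pytest.approx(b.sensitivity)

    def test_helix_completion_extends_partial_match(self):
        ref = make_structure_from_pairs(
            60, [(10, 50), (11, 49), (12, 48), (13, 47)]
        )
        pred = make_structure_from_pairs(60, [(10, 50)])
        plain = score_structures(ref, pred)
        completed = score_structures(ref, pred, helix_completion=True)
        assert plain.sensitivity == 25.0
        assert completed.sensitivity == 100.0


class TestCompositionTracks:
    def test_local_bp_content_bounds(self):
        assert np.allclose(local_bp_content([], 200), 0.0)
        all_pairs = [(i, 200 - i + 1) for i in range(1, 101)]
        assert np.allclose(local_bp_content(all_pairs, 200), 100.0)

    def test_single_helix_peak(self):
        pairs = [(40 + k, 81 - k) for k in range(1, 11)]
        track = local_bp_content(pairs, 160, WindowConfig())
        assert track.max() == pytest.approx(100 * 20 / 75)

    def test_g_minus_a_homopolymers(self):
        assert g_minus_a("G" * 200)[100] == 75
        assert g_minus_a("A" * 200)[100] == -75
        assert abs(g_minus_a("GA" * 100)[100]) <= 1
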