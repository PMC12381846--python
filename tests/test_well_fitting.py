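"""Mixture fitting, pruning, per-chi binning, and well assembly."""

import numpy as np
import pytest

import rotafit as rf
from rotafit.errors import EmptyLibraryError
from rotafit.synthetic import DEFAULT_BOND_ANGLE, DEFAULT_BOND_LENGTH


def wells_to_peaks(wells):
    """Rebuild Cartesian peaks that convert back to the given wells exactly
    (ideal geometry, isotropic XY spread tangent-matched to the std)."""
    polar = np.radians(180.0 - DEFAULT_BOND_ANGLE)
    r = DEFAULT_BOND_LENGTH * np.sin(polar)
    z = DEFAULT_BOND_LENGTH * (1 + np.cos(polar))
    peaks = []
    for w in wells:
        mean, var = [], []
        for ang, std in zip(w.chi_means, w.chi_stds):
            a = np.radians(ang)
            mean += [r * np.cos(a), r * np.sin(a), z]
            s = r * np.tan(np.radians(std))
            var += [s ** 2, s ** 2, 0.01]
        peaks.append(rf.CartesianPeak(mean=np.array(mean),
                                      variances=np.array(var),
                                      weight=w.density))
    return peaks


class TestCartesianFit:
    def test_single_tight_gaussian_one_peak(self):
        rng = np.random.default_rng(0)
        X = rng.normal([1.2, 0.4, 2.0], 0.05, size=(500, 3))
        peaks = rf.fit_cartesian_bgmm(X, rf.FitConfig(seed=1))
        surviving = rf.prune_peaks(peaks, 0.005)
        assert len(surviving) == 1
        assert surviving[0].weight == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(surviving[0].mean, [1.2, 0.4, 2.0], atol=0.02)

    def test_three_well_separated_gaussians(self):
        rng = np.random.default_rng(7)
        centers = np.array([[2, 0, 1], [-2, 1, 1], [0, -3, 2]], dtype=float)
        weights = [0.5, 0.3, 0.2]
        labels = rng.choice(3, size=600, p=weights)
        X = rng.normal(centers[labels], 0.1)
        peaks = rf.prune_peaks(rf.fit_cartesian_bgmm(X, rf.FitConfig(seed=3)), 0.005)
        assert len(peaks) == 3
        got = sorted(p.weight for p in peaks)
        for w, expect in zip(got, sorted(weights)):
            assert w == pytest.approx(expect, abs=0.05)

    def test_weights_normalized(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 400, seed=5)
        peaks = rf.fit_cartesian_bgmm(sm, rf.FitConfig(seed=5))
        assert sum(p.weight for p in peaks) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_per_seed(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 300, seed=2)
        p1 = rf.fit_cartesian_bgmm(sm, rf.FitConfig(seed=8))
        p2 = rf.fit_cartesian_bgmm(sm, rf.FitConfig(seed=8))
        np.testing.assert_array_equal(np.stack([p.mean for p in p1]),
                                      np.stack([p.mean for p in p2]))

    def test_initial_components_capped_by_samples(self):
        # 2-chi data would ask for 100 components; 30 samples cap it
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6)) + [2, 0, 1, 0, 2, 1]
        peaks = rf.fit_cartesian_bgmm(X, rf.FitConfig(seed=1))
        assert len(peaks) <= 30


class TestPrune:
    def test_threshold_arithmetic(self):
        mk = lambda w: rf.CartesianPeak(mean=np.zeros(3) + 1, variances=np.ones(3),
                                        weight=w)
        pruned = rf.prune_peaks([mk(0.6), mk(0.397), mk(0.003)], 0.005)
        assert [p.weight for p in pruned] == [
            pytest.approx(0.6 / 0.997), pytest.approx(0.397 / 0.997)]

    def test_all_above_threshold_is_identity(self):
        mk = lambda w: rf.CartesianPeak(mean=np.ones(3), variances=np.ones(3), weight=w)
        pruned = rf.prune_peaks([mk(0.5), mk(0.5)], 0.005)
        assert [p.weight for p in pruned] == [0.5, 0.5]

    def test_nothing_survives_raises(self):
        mk = lambda w: rf.CartesianPeak(mean=np.ones(3), variances=np.ones(3), weight=w)
        with pytest.raises(EmptyLibraryError):
            rf.prune_peaks([mk(0.001), mk(0.002)], 0.005)


class TestPerChiBins:
    def test_single_well_single_bin(self):
        """A clean single well should bin as one component in the large
        majority of draws (a finite sample can legitimately support a
        lopsided two-component representation now and then)."""
        wells = [rf.SyntheticWellSpec((45.0,), (9.0,), 1.0)]
        single = 0
        for seed in range(5):
            sm = rf.sample_cartesian(wells, 800, seed=seed)
            bins = rf.fit_per_chi_bins(sm, 1, rf.FitConfig(seed=seed))
            assert rf.circular_difference(bins[0].mean, 45.0) < 3.0
            single += len(bins) == 1
        assert single >= 4

    def test_three_staggered_bins_sorted(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 1000, seed=4)
        bins = rf.fit_per_chi_bins(sm, 1, rf.FitConfig(seed=4))
        assert len(bins) == 3
        means = [b.mean for b in bins]
        assert means == sorted(means)
        assert sum(b.density for b in bins) == pytest.approx(1.0, abs=1e-9)

    def test_seam_straddling_well_stays_single(self):
        wells = [rf.SyntheticWellSpec((178.0,), (6.0,), 0.5),
                 rf.SyntheticWellSpec((-60.0,), (8.0,), 0.5)]
        sm = rf.sample_cartesian(wells, 800, seed=6)
        bins = rf.fit_per_chi_bins(sm, 1, rf.FitConfig(seed=6))
        assert len(bins) == 2

    def test_cartesian_flag_also_bins(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 500, seed=9)
        bins = rf.fit_per_chi_bins(sm, 1,
                                   rf.FitConfig(seed=9, per_chi_cartesian=True))
        assert 1 <= len(bins) <= 10
        assert sum(b.density for b in bins) == pytest.approx(1.0, abs=1e-9)


class TestAssignAndMerge:
    def _bins(self, means):
        return [rf.ChiBin(mean=m, std=8.0, density=1.0 / len(means)) for m in means]

    def test_distinct_assignments_pass_through(self):
        wells = [rf.DihedralWell((60.0,), (8.0,), 0.7, (2,)),
                 rf.DihedralWell((-60.0,), (8.0,), 0.3, (1,))]
        peaks = wells_to_peaks(wells)
        out = rf.assign_and_merge(peaks, [self._bins([-60.0, 60.0])])
        assert len(out) == 2
        assert out[0].density == pytest.approx(0.7)
        assert rf.circular_difference(out[0].chi_means[0], 60.0) < 1e-6

    def test_equal_weight_merge_hits_midpoint(self):
        wells = [rf.DihedralWell((55.0,), (8.0,), 0.5, (1,)),
                 rf.DihedralWell((65.0,), (8.0,), 0.5, (1,))]
        peaks = wells_to_peaks(wells)
        out = rf.assign_and_merge(peaks, [self._bins([60.0, 180.0])])
        assert len(out) == 1
        assert out[0].density == pytest.approx(1.0, abs=1e-9)
        # Cartesian weighted average of symmetric points lands on the
        # circular midpoint direction
        assert rf.circular_difference(out[0].chi_means[0], 60.0) < 1e-6

    def test_density_conservation(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 1000, seed=1)
        wells, bins = rf.fit_wells(sm, rf.FitConfig(seed=1))
        assert sum(w.density for w in wells) == pytest.approx(1.0, abs=1e-9)
        for bl in bins:
            assert sum(b.density for b in bl) == pytest.approx(1.0, abs=1e-9)

    def test_merge_idempotent_on_own_output(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 1000, seed=2)
        wells, bins = rf.fit_wells(sm, rf.FitConfig(seed=2))
        again = rf.assign_and_merge(wells_to_peaks(wells), bins)
        assert len(again) == len(wells)
        for w0, w1 in zip(sorted(wells, key=lambda w: w.bin_assignment),
                          sorted(again, key=lambda w: w.bin_assignment)):
            assert w0.bin_assignment == w1.bin_assignment
            assert w1.density == pytest.approx(w0.density, abs=1e-9)
            for a, b in zip(w0.chi_means, w1.chi_means):
                assert rf.circular_difference(a, b) < 1e-6

    def test_bin_indices_subset_of_fitted_bins(self, two_chi_wells):
        sm = rf.sample_cartesian(two_chi_wells, 1000, seed=3)
        wells, bins = rf.fit_wells(sm, rf.FitConfig(seed=3))
        for k in range(2):
            used = {w.bin_assignment[k] for w in wells}
            assert used <= set(range(1, len(bins[k]) + 1))

    def test_assignment_tie_prefers_lower_bin(self):
        wells = [rf.DihedralWell((0.0,), (8.0,), 1.0, (1,))]
        peaks = wells_to_peaks(wells)
        out = rf.assign_and_merge(peaks, [self._bins([-30.0, 30.0])])
        assert out[0].bin_assignment == (1,)


class TestParameterRecovery:
    def test_two_chi_mixture_recovery_across_seeds(self, two_chi_wells):
        """>= 9/10 seeds recover the exact well count, means within 5 deg,
        weights within 0.05."""
        ok = 0
        for seed in range(10):
            sm = rf.sample_cartesian(two_chi_wells, 1000, seed=seed)
            wells, _ = rf.fit_wells(sm, rf.FitConfig(seed=seed + 100))
            good = len(wells) == len(two_chi_wells)
            if good:
                for truth in two_chi_wells:
                    best = min(wells, key=lambda w: sum(
                        rf.circular_difference(a, b)
                        for a, b in zip(w.chi_means, truth.chi_means)))
                    if any(rf.circular_difference(a, b) > 5.0
                           for a, b in zip(best.chi_means, truth.chi_means)):
                        good = False
                    if abs(best.density - truth.weight) > 0.05:
                        good = False
            ok += good
        assert ok >= 9
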