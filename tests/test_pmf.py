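import numpy as np
import pytest

from peptoidsolv.constants import kT
from peptoidsolv.pmf import (
    WHAM,
    PMFResult,
    UmbrellaWindow,
    build_windows,
    desorption_cost,
    pmf_uncertainty,
    softmin_distance,
    wham,
)
from peptoidsolv.synthetic import DoubleWell, Flat, sample_umbrella


class TestSoftmin:
    def test_single_distance_identity(self):
        assert softmin_distance([0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_equal_distances_closed_form(self):
        expected = 100.0 / (np.log(2.0) + 100.0)
        assert softmin_distance([1.0, 1.0], beta=100) == pytest.approx(expected, abs=1e-9)

    def test_far_term_suppressed(self):
        assert softmin_distance([0.4, 4.0], beta=100) == pytest.approx(0.4, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            softmin_distance([0.5, -0.1])

    def test_converges_to_min_from_below_monotonically_in_beta(self):
        d = [0.7, 0.9, 1.3]
        values = [softmin_distance(d, beta=b) for b in (10, 30, 100, 300, 1000)]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert all(v <= min(d) for v in values)
        assert values[-1] == pytest.approx(0.7, abs=1e-3)


class TestWindows:
    def test_schedule_has_81_windows(self):
        centers = build_windows(0.35, 4.4, 0.05)
        assert len(centers) == 81
        assert centers[0] == pytest.approx(0.35)
        assert centers[-1] == pytest.approx(4.35)

    def test_tiny_interval_single_center(self):
        assert len(build_windows(1.0, 1.0 + 1e-9, 0.5)) == 1

    def test_quarter_steps(self):
        assert np.allclose(build_windows(0, 1, 0.25), [0, 0.25, 0.5, 0.75])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            build_windows(1.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            build_windows(0.0, 1.0, -0.1)


class TestWHAM:
    def test_unbiased_limit_reduces_to_histogram(self):
        """One window with negligible bias: PMF equals -kT ln(histogram)."""
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.1, 20000)
        samples = samples[samples > 0]
        win = UmbrellaWindow(center=1.0, samples=samples, force_constant=1e-9)
        res = WHAM([win], bin_width=0.02).fit()
        counts, edges = np.histogram(samples, bins=res.bin_centers.size,
                                     range=(res.bin_centers[0] - 0.01, res.bin_centers[-1] + 0.01))
        ok = counts > 0
        expected = -kT(300) * np.log(counts[ok] / counts.sum())
        expected -= expected.min()
        got = res.free_energy[ok] - np.nanmin(res.free_energy[ok])
        assert np.allclose(got, expected, atol=0.05)

    def test_flat_potential_null(self):
        centers = np.linspace(0.35, 1.65, 10)
        wins = sample_umbrella(Flat(), centers, force_constant=200.0,
                               n_per_window=4000, seed=0)
        res = WHAM(wins, bin_width=0.05).fit()
        cov = (res.bin_centers >= centers[0]) & (res.bin_centers <= centers[-1])
        f = res.free_energy[cov & np.isfinite(res.free_energy)]
        assert f.max() - f.min() < 0.4 * kT(300)  # small-n smoke check

    def test_double_well_barrier_recovered(self):
        dw = DoubleWell(5.0)
        centers = np.linspace(0.35, 1.65, 10)
        wins = sample_umbrella(dw, centers, force_constant=200.0,
                               n_per_window=3000, seed=1)
        res = WHAM(wins, bin_width=0.05).fit()
        c, F = res.bin_centers, res.free_energy
        mid = (c > 0.8) & (c < 1.2) & np.isfinite(F)
        outer = ((c < 0.8) | (c > 1.2)) & np.isfinite(F)
        barrier = np.nanmax(F[mid]) - np.nanmin(F[outer])
        assert barrier == pytest.approx(5.0, abs=0.7)

    def test_gauge_invariance_of_window_offsets(self):
        """The converged solution is unchanged by the f_k normalisation."""
        centers = np.linspace(0.35, 1.65, 6)
        wins = sample_umbrella(Flat(), centers, force_constant=200.0,
                               n_per_window=500, seed=2)
        a = WHAM(wins, bin_width=0.05).fit(tol=1e-10)
        b = WHAM(wins, bin_width=0.05).fit(tol=1e-10, max_iter=200_000)
        assert np.allclose(a.free_energy, b.free_energy, equal_nan=True, atol=1e-6)

    def test_empty_window_dropped_with_warning(self):
        good = UmbrellaWindow(1.0, np.random.default_rng(3).uniform(0.9, 1.1, 100))
        empty = UmbrellaWindow(2.0, np.empty(0))
        with pytest.warns(UserWarning, match="empty"):
            WHAM([good, empty])

    def test_non_overlapping_windows_warn(self):
        rng = np.random.default_rng(4)
        a = UmbrellaWindow(0.5, rng.uniform(0.45, 0.55, 200))
        b = UmbrellaWindow(2.0, rng.uniform(1.95, 2.05, 200))
        with pytest.warns(UserWarning, match="non-overlapping"):
            wham([a, b], max_iter=100)


class TestUncertaintyAndCost:
    def _result(self, pmf, centers=None):
        centers = np.arange(0.5, 3.0, 0.1) if centers is None else centers
        return PMFResult(
            bin_centers=centers,
            free_energy=np.asarray(pmf, dtype=float),
            counts=np.ones(len(centers)),
            window_free_energies=np.zeros(1),
            converged=True,
            iterations=1,
            temperature=300.0,
            anchor_cutoff=1.0,
        )

    def test_identical_replicates_zero_std(self):
        r = self._result(np.linspace(0, 3, 25))
        df = pmf_uncertainty([r, r, r])
        assert np.allclose(df["pmf_std"], 0.0)

    def test_constant_offsets_removed_by_anchoring(self):
        base = np.linspace(0, 3, 25)
        reps = [self._result(base + c) for c in (0.0, 5.0, -2.5)]
        df = pmf_uncertainty(reps)
        assert np.allclose(df["pmf_std"], 0.0, atol=1e-12)

    def test_binning_mismatch_rejected(self):
        a = self._result(np.zeros(25))
        b = self._result(np.zeros(10), centers=np.arange(0.5, 1.5, 0.1))
        with pytest.raises(ValueError):
            pmf_uncertainty([a, b])

    def test_noisy_replicates_cover_truth(self):
        dw = DoubleWell(5.0)
        centers = np.linspace(0.35, 1.65, 10)
        edges = np.arange(0.2, 1.9, 0.05)
        reps = []
        for seed in (1, 2, 3):
            wins = sample_umbrella(dw, centers, force_constant=200.0,
                                   n_per_window=2000, seed=seed)
            reps.append(WHAM(wins, bin_edges=edges).fit())
        df = pmf_uncertainty(reps)
        mids = df["xi_nm"].to_numpy()
        truth = dw(mids) - dw(mids).min()
        ok = (df["n_defined"] == 3) & (mids > 0.4) & (mids < 1.6)
        covered = np.abs(df["pmf_mean"][ok] - truth[ok]) <= np.maximum(
            2 * df["pmf_std"][ok], 0.5
        )
        assert covered.mean() >= 0.9

    def test_flat_pmf_zero_cost(self):
        r = self._result(np.zeros(25))
        assert desorption_cost(r) == pytest.approx(0.0)

    def test_planted_well_depth_recovered(self):
        centers = np.arange(0.5, 3.0, 0.1)
        pmf = 3.0 - 3.0 * np.exp(-((centers - 0.6) ** 2) / 0.01)
        r = self._result(pmf, centers)
        assert desorption_cost(r) == pytest.approx(3.0, abs=0.05)

    def test_cost_gauge_invariant(self):
        centers = np.arange(0.5, 3.0, 0.1)
        pmf = 3.0 - 3.0 * np.exp(-((centers - 0.6) ** 2) / 0.01)
        a = desorption_cost(self._result(pmf, centers))
        b = desorption_cost(self._result(pmf + 11.0, centers))
        assert a == pytest.approx(b)

    def test_missing_plateau_warns(self):
        centers = np.arange(0.5, 3.0, 0.1)
        r = self._result(10.0 * centers, centers)
        with pytest.warns(UserWarning, match="plateau"):
            desorption_cost(r)
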