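import numpy as np
import pytest

from lipopore import synth
from lipopore.wham import (
    KB,
    PMFProfile,
    UmbrellaWindow,
    bias_potential,
    compare_profiles,
    pmf_error_bootstrap,
    pore_free_energy,
    read_wham_metadata,
    wham_solve,
    write_window_files,
)

kT300 = KB * 300.0


class TestBiasPotential:
    def test_harmonic_value(self):
        w = UmbrellaWindow(center=0.5, stiffness=5000.0, samples=[])
        assert bias_potential(w, 0.52) == pytest.approx(1.0)

    def test_zero_at_center(self):
        w = UmbrellaWindow(center=0.3, stiffness=800.0, samples=[])
        assert bias_potential(w, 0.3) == 0.0

    def test_symmetry(self):
        w = UmbrellaWindow(center=0.4, stiffness=800.0, samples=[])
        assert bias_potential(w, 0.4 + 0.13) == pytest.approx(
            bias_potential(w, 0.4 - 0.13)
        )

    def test_kT_at_300K(self):
        w = UmbrellaWindow(center=0.0, stiffness=0.0, samples=[])
        assert w.kT == pytest.approx(2.494, abs=1e-3)


class TestWhamSolve:
    def test_single_unbiased_window_flat(self):
        rng = np.random.default_rng(8)
        w = UmbrellaWindow(center=0.5, stiffness=0.0, samples=rng.random(50_000))
        prof = wham_solve([w], n_bins=50)
        err = pmf_error_bootstrap([w], n_boot=20, seed=1, n_bins=50)
        valid = np.isfinite(prof.free_energy)
        g = prof.free_energy[valid]
        # flat within 3x bootstrap error around the profile's own level
        # (the min-shift convention biases comparison against zero)
        assert (np.abs(g - g.mean()) <= 3 * err[valid] + 1e-9).all()

    def test_two_windows_flat_landscape(self):
        flat = lambda xi: np.zeros_like(np.asarray(xi, dtype=float))
        windows, _ = synth.gen_umbrella_dataset(
            flat, np.array([0.35, 0.65]), stiffness=30.0,
            n_per_window=30_000, seed=9,
        )
        prof = wham_solve(windows, n_bins=50)
        err = pmf_error_bootstrap(windows, n_boot=20, seed=2, n_bins=50)
        valid = np.isfinite(prof.free_energy)
        inner = valid & (prof.bin_centers > 0.1) & (prof.bin_centers < 0.9)
        g = prof.free_energy[inner]
        assert (np.abs(g - g.mean()) <= 3 * err[inner] + 0.1).all()

    def test_cosine_barrier_recovery(self, umbrella_cosine):
        windows, _, G = umbrella_cosine
        prof = wham_solve(windows)
        true = G(prof.bin_centers)
        true -= true.min()
        barrier = prof.interpolate(0.5)
        assert barrier == pytest.approx(20.0, abs=1.0)
        mask = (
            np.isfinite(prof.free_energy)
            & (prof.bin_centers >= 0.1)
            & (prof.bin_centers <= 0.9)
        )
        rmse = np.sqrt(np.mean((prof.free_energy[mask] - true[mask]) ** 2))
        assert rmse <= 0.5

    def test_minimum_shifted_to_zero(self, umbrella_cosine):
        prof = wham_solve(umbrella_cosine[0])
        assert np.nanmin(prof.free_energy) == 0.0

    def test_bias_offset_invariance(self, umbrella_cosine):
        # adding a constant to a window's bias cannot change the PMF:
        # a constant shifts that window's F_i and cancels in the equations
        windows = umbrella_cosine[0]
        prof = wham_solve(windows, tol=1e-8)
        shifted = [
            UmbrellaWindow(
                w.center, w.stiffness, w.samples, w.temperature,
                offset=13.0 * i,
            )
            for i, w in enumerate(windows)
        ]
        prof2 = wham_solve(shifted, tol=1e-8)
        valid = np.isfinite(prof.free_energy)
        assert np.allclose(
            prof.free_energy[valid], prof2.free_energy[valid], atol=1e-6
        )

    def test_disconnected_ladder_rejected(self):
        rng = np.random.default_rng(3)
        w1 = UmbrellaWindow(0.1, 5000.0, 0.1 + 0.01 * rng.normal(size=500))
        w2 = UmbrellaWindow(0.9, 5000.0, 0.9 + 0.01 * rng.normal(size=500))
        with pytest.raises(ValueError, match="disconnected"):
            wham_solve([w1, w2], n_bins=100)

    def test_single_window_boltzmann_reweighting(self):
        # detailed-balance check: samples from one biased window, with the
        # bias Boltzmann factor divided back out, reproduce the analytic
        # unbiased density (CDF distance)
        G = synth.cosine_landscape(8.0)
        windows, _ = synth.gen_umbrella_dataset(
            G, np.array([0.5]), stiffness=20.0, n_per_window=50_000, seed=12
        )
        w = windows[0]
        edges = np.linspace(0, 1, 81)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hist, _ = np.histogram(w.samples, bins=edges, density=True)
        unbiased = hist * np.exp(bias_potential(w, centers) / w.kT)
        unbiased /= unbiased.sum()
        ref = np.exp(-(G(centers) + 0.0) / w.kT)
        ref /= ref.sum()
        ks = np.abs(np.cumsum(unbiased) - np.cumsum(ref)).max()
        assert ks < 0.02


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, umbrella_cosine):
        windows = umbrella_cosine[0]
        e1 = pmf_error_bootstrap(windows, n_boot=20, seed=5)
        e2 = pmf_error_bootstrap(windows, n_boot=20, seed=5)
        assert np.array_equal(e1, e2)

    def test_error_shrinks_with_sampling(self):
        G = synth.cosine_landscape(10.0)
        centers = np.linspace(0, 1, 10)
        small, _ = synth.gen_umbrella_dataset(
            G, centers, n_per_window=2_000, seed=6
        )
        large, _ = synth.gen_umbrella_dataset(
            G, centers, n_per_window=8_000, seed=6
        )
        e_small = pmf_error_bootstrap(small, n_boot=25, seed=7, n_bins=100)
        e_large = pmf_error_bootstrap(large, n_boot=25, seed=7, n_bins=100)
        ratio = np.nanmean(e_large) / np.nanmean(e_small)
        # 1/sqrt(N): quadrupling samples should halve the error (within 25%)
        assert 0.5 * 0.75 <= ratio <= 0.5 * 1.25

    def test_too_few_bootstrap_replicates_rejected(self, umbrella_cosine):
        with pytest.raises(ValueError):
            pmf_error_bootstrap(umbrella_cosine[0], n_boot=5)


class TestPoreFreeEnergy:
    def _flat_profile(self, offset=0.0):
        xi = np.linspace(0, 1, 100)
        return PMFProfile(bin_centers=xi, free_energy=np.full(100, offset))

    def test_flat_profile_zero_cost(self):
        assert pore_free_energy(self._flat_profile(), 0.1, 0.9) == 0.0

    def test_offset_invariance(self, umbrella_cosine):
        prof = wham_solve(umbrella_cosine[0])
        dg = pore_free_energy(prof, 0.1, 0.5)
        shifted = PMFProfile(
            bin_centers=prof.bin_centers, free_energy=prof.free_energy + 7.0
        )
        assert pore_free_energy(shifted, 0.1, 0.5) == pytest.approx(dg)

    def test_built_in_ddg_recovered(self):
        # two landscapes differing by 10 kJ/mol in barrier height
        c1 = np.linspace(0, 1, 12)
        w1, _ = synth.gen_umbrella_dataset(
            synth.cosine_landscape(20.0), c1, n_per_window=10_000, seed=13
        )
        w2, _ = synth.gen_umbrella_dataset(
            synth.cosine_landscape(10.0), c1, n_per_window=10_000, seed=14
        )
        p1, p2 = wham_solve(w1), wham_solve(w2)
        ddg = compare_profiles(p1, p2, xi_flat=0.02, xi_open=0.5)
        e1 = pmf_error_bootstrap(w1, n_boot=20, seed=15)
        e2 = pmf_error_bootstrap(w2, n_boot=20, seed=16)
        combined = np.sqrt(np.nanmax(e1) ** 2 + np.nanmax(e2) ** 2)
        assert abs(ddg - 10.0) <= max(3 * combined, 1.0)

    def test_out_of_support_rejected(self):
        prof = self._flat_profile()
        with pytest.raises(ValueError):
            pore_free_energy(prof, -0.5, 0.5)


class TestWindowFiles:
    def test_metadata_round_trip(self, tmp_path, umbrella_cosine):
        windows = umbrella_cosine[0][:3]
        meta = write_window_files(windows, tmp_path)
        back = read_wham_metadata(meta)
        assert len(back) == 3
        for w, b in zip(windows, back):
            assert b.center == pytest.approx(w.center)
            assert b.stiffness == pytest.approx(w.stiffness)
            assert np.allclose(b.samples, w.samples, atol=1e-6)
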