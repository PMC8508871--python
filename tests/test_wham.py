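"""Window planning, WHAM self-consistency, shifting, errors, and features."""

import numpy as np
import pytest

from permeakit.constants import thermal_energy
from permeakit.wham import (
    ConvergenceRecord,
    PMFProfile,
    UmbrellaWindow,
    WhamConfig,
    WhamError,
    bin_window,
    block_error,
    compute_pmf,
    extract_features,
    plan_windows,
    shift_profile,
    wham_solve,
)

from conftest import sample_umbrella_windows

kT = thermal_energy()


class TestPlanWindows:
    def test_half_angstrom_spacing_over_full_pull(self):
        plan = plan_windows(50.0, 0.5)
        assert plan.n_total == 100
        assert len(plan.centers) == 100
        assert np.allclose(np.diff(plan.centers), 0.5)

    def test_terminal_gate_region_dropped(self):
        plan = plan_windows(50.0, 0.5, drop_terminal=15.0)
        assert plan.n_dropped_terminal == 30
        assert plan.n_retained == 70
        assert len(plan.retained_centers) == 70

    def test_single_window(self):
        plan = plan_windows(1.0, 1.0)
        assert plan.n_total == 1

    def test_spacing_larger_than_span_rejected(self):
        with pytest.raises(ValueError):
            plan_windows(1.0, 2.0)


class TestBinWindow:
    def test_all_samples_in_one_bin(self):
        w = UmbrellaWindow(center=0.0, force_constant=10.0,
                           samples=np.full(10, 0.55))
        counts = bin_window(w, np.linspace(0, 1, 11))
        assert counts[5] == 10 and counts.sum() == 10

    def test_equilibration_discard_removes_leading_frames(self):
        """10 ns at 1000 frames/ns with a 3 ns discard leaves 7000 frames."""
        samples = np.linspace(0, 1, 10_000)
        w = UmbrellaWindow(center=0.5, force_constant=10.0, samples=samples,
                           n_equilibration_discard=3_000)
        counts = bin_window(w, np.linspace(-0.1, 1.1, 25))
        assert counts.sum() == 7_000

    def test_empty_after_discard_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, force_constant=10.0,
                           samples=np.arange(5.0), n_equilibration_discard=5)

    def test_all_samples_outside_grid_rejected(self):
        w = UmbrellaWindow(center=0.0, force_constant=10.0,
                           samples=np.full(4, 100.0))
        with pytest.raises(WhamError, match="outside"):
            bin_window(w, np.linspace(0, 1, 5))


class TestWhamSolve:
    def test_unbiased_window_is_boltzmann_inversion(self):
        """With k = 0, WHAM must reduce to G = −kT ln(histogram) + const."""
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 1.0, 20_000)
        w = UmbrellaWindow(center=0.0, force_constant=0.0, samples=samples)
        cfg = WhamConfig(n_bins=40, tolerance=1e-9)
        prof = wham_solve([w], cfg)
        counts, edges = np.histogram(samples, bins=40,
                                     range=(prof.xi[0] - (prof.xi[1] - prof.xi[0]) / 2,
                                            prof.xi[-1] + (prof.xi[1] - prof.xi[0]) / 2))
        mask = counts > 0
        direct = -cfg.kT * np.log(counts[mask] / counts.sum())
        diff = prof.free_energy[mask] - direct
        assert np.ptp(diff) < 1e-10

    def test_duplicate_windows_change_nothing(self, ca_like_windows):
        cfg = WhamConfig(n_bins=80, tolerance=1e-8)
        sub = ca_like_windows[:4]
        lo = min(w.retained.min() for w in sub)
        hi = max(w.retained.max() for w in sub)
        one = shift_profile(wham_solve(sub, cfg, grid_range=(lo, hi)), 5)
        dup = shift_profile(wham_solve(list(sub) + list(sub), cfg,
                                       grid_range=(lo, hi)), 5)
        mask = one.finite_mask & dup.finite_mask
        assert np.allclose(one.free_energy[mask], dup.free_energy[mask],
                           atol=1e-6)

    def test_window_order_is_irrelevant(self, ca_like_windows):
        cfg = WhamConfig(n_bins=100, tolerance=1e-8)
        lo = min(w.retained.min() for w in ca_like_windows)
        hi = max(w.retained.max() for w in ca_like_windows)
        a = shift_profile(wham_solve(ca_like_windows, cfg, (lo, hi)), 10)
        rng = np.random.default_rng(1)
        order = rng.permutation(len(ca_like_windows))
        b = shift_profile(wham_solve([ca_like_windows[i] for i in order],
                                     cfg, (lo, hi)), 10)
        mask = a.finite_mask & b.finite_mask
        assert np.max(np.abs(a.free_energy[mask] - b.free_energy[mask])) < 1e-6

    def test_matches_brute_force_fixed_point_on_small_problem(self):
        """Iterative solver equals a naive alternation written from the
        defining equations, on a 3-window, 30-bin problem."""
        rng = np.random.default_rng(5)
        k = 5.0
        windows = [
            UmbrellaWindow(center=c, force_constant=k,
                           samples=rng.normal(c, np.sqrt(kT / k), 2_000))
            for c in (-0.5, 0.0, 0.5)
        ]
        cfg = WhamConfig(n_bins=30, tolerance=1e-12, max_iterations=500_000)
        lo = min(w.retained.min() for w in windows)
        hi = max(w.retained.max() for w in windows)
        prof = wham_solve(windows, cfg, (lo, hi))

        # independent brute-force alternation
        edges = np.linspace(lo, hi, 31)
        edges[-1] = np.nextafter(edges[-1], np.inf)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n_jb = np.stack([np.histogram(w.retained, bins=edges)[0]
                         for w in windows]).astype(float)
        w_jb = np.stack([0.5 * k * (centers - w.center) ** 2 for w in windows])
        f = np.zeros(3)
        for _ in range(300_000):
            denom = np.zeros_like(centers)
            for j in range(3):
                denom += n_jb[j].sum() * np.exp((f[j] - w_jb[j]) / kT)
            p = n_jb.sum(axis=0) / denom
            f_new = np.array([
                -kT * np.log(np.sum(p * np.exp(-w_jb[j] / kT)))
                for j in range(3)
            ])
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) < 1e-13:
                f = f_new
                break
            f = f_new
        p /= p.sum()
        g_ref = -kT * np.log(p)
        g_ref -= g_ref.min()
        mask = prof.finite_mask
        assert np.max(np.abs(prof.free_energy[mask] - g_ref[mask])) < 1e-8

    def test_recovers_known_landscape(self, ca_like_spec, ca_like_windows):
        """End-to-end recovery: RMSE to the true landscape < 0.3 kcal/mol."""
        cfg = WhamConfig(n_bins=300, tolerance=1e-7)
        prof = compute_pmf(ca_like_windows, cfg, errors=False)
        truth = ca_like_spec.energy(prof.xi)
        bp = cfg.bulk_points
        truth = truth - np.concatenate([truth[:bp], truth[-bp:]]).mean()
        mask = prof.finite_mask
        rmse = np.sqrt(np.mean((prof.free_energy[mask] - truth[mask]) ** 2))
        assert rmse < 0.3

    def test_more_samples_reduce_recovery_error(self, ca_like_spec):
        """Doubling window sampling (fresh seeds) lowers the mean recovery
        RMSE in >= 80% of 10 paired repeats.

        Each arm averages 3 independent recovery estimates: a single WHAM
        profile's error is dominated by a few low-frequency stitching modes,
        so single-estimate pairs are too noisy to show the sqrt(2) gain.
        """
        centers = np.arange(-2.75, 2.0, 0.5)

        def arm_rmse(n_steps, seeds):
            out = []
            for s in seeds:
                windows = sample_umbrella_windows(
                    ca_like_spec, centers, n_steps=n_steps, discard=10_000,
                    stride=5, seed0=s)
                cfg = WhamConfig(n_bins=60, tolerance=1e-6, bulk_points=3)
                prof = compute_pmf(windows, cfg, errors=False,
                                   grid_range=(-2.6, 1.9))
                truth = ca_like_spec.energy(prof.xi)
                truth = truth - np.concatenate([truth[:3], truth[-3:]]).mean()
                mask = prof.finite_mask
                out.append(np.sqrt(np.mean(
                    (prof.free_energy[mask] - truth[mask]) ** 2)))
            return np.mean(out)

        wins = 0
        for rep in range(10):
            base = arm_rmse(60_000, [10_000 * rep + j * 100 for j in range(3)])
            doubled = arm_rmse(120_000,
                               [10_000 * rep + 50_000 + j * 100
                                for j in range(3)])
            wins += doubled < base
        assert wins >= 8

    def test_disconnected_coverage_reported(self):
        rng = np.random.default_rng(2)
        windows = [
            UmbrellaWindow(center=c, force_constant=10.0,
                           samples=rng.normal(c, 0.2, 2_000))
            for c in (0.0, 10.0)
        ]
        with pytest.raises(WhamError, match="disconnected"):
            wham_solve(windows, WhamConfig(n_bins=100, tolerance=1e-6))

    def test_nonconvergence_carries_residual(self, ca_like_windows):
        with pytest.raises(WhamError, match="residual"):
            wham_solve(ca_like_windows[:6],
                       WhamConfig(n_bins=50, tolerance=1e-12, max_iterations=3))


class TestShift:
    def _profile(self, g):
        g = np.asarray(g, dtype=float)
        return PMFProfile(xi=np.arange(len(g), dtype=float), free_energy=g)

    def test_flat_profile_shifts_to_zero(self):
        p = shift_profile(self._profile(np.full(30, 7.3)), 10)
        assert np.allclose(p.free_energy, 0.0)
        assert p.shift == pytest.approx(7.3)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        p = self._profile(rng.normal(size=40))
        once = shift_profile(p, 10)
        twice = shift_profile(once, 10)
        assert np.allclose(once.free_energy, twice.free_energy)

    def test_subtracts_bulk_mean_exactly(self):
        g = np.zeros(30)
        g[:10] = 2.0
        g[-10:] = 3.0  # bulk mean = 2.5
        g[15] = 9.9
        p = shift_profile(self._profile(g), 10)
        assert p.free_energy[15] == pytest.approx(9.9 - 2.5)
        bulk = np.concatenate([p.free_energy[:10], p.free_energy[-10:]])
        assert abs(bulk.mean()) < 1e-9

    def test_shape_preserved(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=50)
        p = shift_profile(self._profile(g), 10)
        assert np.allclose(np.diff(p.free_energy), np.diff(g))

    def test_too_few_bins_rejected(self):
        with pytest.raises(WhamError):
            shift_profile(self._profile(np.zeros(10)), 10)


class TestBlockError:
    def test_identical_blocks_have_zero_sem(self):
        rng = np.random.default_rng(4)
        block = rng.normal(0.0, 0.5, 1_000)
        windows = [UmbrellaWindow(center=0.0, force_constant=5.0,
                                  samples=np.tile(block, 7),
                                  block_length=1_000)]
        sem, profiles = block_error(windows, WhamConfig(n_bins=20,
                                                        tolerance=1e-9,
                                                        bulk_points=2))
        assert len(profiles) == 7
        assert np.nanmax(sem) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_blocks_rejected(self):
        w = UmbrellaWindow(center=0.0, force_constant=5.0,
                           samples=np.random.default_rng(0).normal(size=900),
                           block_length=800)
        with pytest.raises(WhamError, match="2 full blocks"):
            block_error([w], WhamConfig(n_bins=10, bulk_points=2))

    def test_error_bars_cover_the_truth(self, ca_like_spec, ca_like_windows):
        """>= 95% of bins lie within 3 SEM of the known landscape."""
        cfg = WhamConfig(n_bins=150, tolerance=1e-7)
        prof = compute_pmf(ca_like_windows, cfg, errors=True)
        truth = ca_like_spec.energy(prof.xi)
        bp = cfg.bulk_points
        truth = truth - np.concatenate([truth[:bp], truth[-bp:]]).mean()
        ok = prof.finite_mask & np.isfinite(prof.error) & (prof.error > 0)
        covered = np.abs(prof.free_energy[ok] - truth[ok]) < 3 * prof.error[ok]
        assert covered.mean() >= 0.95


class TestFeatures:
    def _profile(self, g):
        g = np.asarray(g, dtype=float)
        return PMFProfile(xi=np.linspace(0, 10, len(g)), free_energy=g)

    def test_well_then_barrier_arithmetic(self):
        """A −4.1 minimum followed by a 2.8 barrier costs 6.9 to climb."""
        xi = np.linspace(0, 10, 101)
        g = -4.1 * np.exp(-0.5 * ((xi - 3) / 0.8) ** 2) \
            + 2.8 * np.exp(-0.5 * ((xi - 6) / 0.8) ** 2)
        feats = extract_features(PMFProfile(xi=xi, free_energy=g),
                                 sf_region=(5.0, 7.0))
        assert feats.sf_barrier == pytest.approx(2.8, abs=0.01)
        assert feats.global_minimum == pytest.approx(-4.1, abs=0.01)
        assert feats.luminal_to_cytosolic_barrier == pytest.approx(6.9, abs=0.02)

    def test_monotone_profile(self):
        g = np.linspace(0.0, 5.0, 60)
        feats = extract_features(self._profile(g), sf_region=(0.0, 2.0))
        assert feats.global_minimum == 0.0
        assert feats.minimum_position == 0.0
        assert feats.luminal_to_cytosolic_barrier == pytest.approx(5.0)

    def test_flat_profile_has_no_features(self):
        feats = extract_features(self._profile(np.zeros(40)))
        assert feats.sf_barrier == 0.0
        assert feats.global_minimum == 0.0
        assert feats.luminal_to_cytosolic_barrier == 0.0

    def test_empty_sf_region_rejected(self):
        with pytest.raises(WhamError):
            extract_features(self._profile(np.zeros(40)), sf_region=(50, 60))

    def test_wildtype_vs_neutralized_contrast(self, ca_like_spec,
                                              mutant_like_spec):
        """Removing the luminal well makes the full climb equal the SF
        barrier itself."""
        wt = extract_features(PMFProfile(
            xi=np.linspace(-5, 5, 201),
            free_energy=ca_like_spec.energy(np.linspace(-5, 5, 201))),
            sf_region=(-0.5, 2.5))
        mut = extract_features(PMFProfile(
            xi=np.linspace(-5, 5, 201),
            free_energy=mutant_like_spec.energy(np.linspace(-5, 5, 201))),
            sf_region=(-0.5, 2.5))
        assert wt.luminal_to_cytosolic_barrier > wt.sf_barrier + 3.0
        assert mut.sf_barrier > 10.0
        assert mut.luminal_to_cytosolic_barrier == pytest.approx(
            mut.sf_barrier, abs=0.05)
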