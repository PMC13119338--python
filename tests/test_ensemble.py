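"""Förster conversion, contacts, contact lifetimes, and WHAM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parfret.ensemble import (
    KB_KJ_MOL_K,
    ContactParams,
    DistanceSeries,
    ForsterModel,
    NoContactWarning,
    UmbrellaWindow,
    contact_lifetime,
    count_contacts,
    forster_efficiency,
    mean_efficiency,
    wham_pmf,
)

R0 = 5.4


class TestForster:
    def test_midpoint_at_forster_radius(self):
        assert forster_efficiency(R0) == pytest.approx(0.5)

    def test_contact_limit(self):
        assert forster_efficiency(1e-6) == pytest.approx(1.0)

    def test_double_radius(self):
        assert forster_efficiency(2 * R0) == pytest.approx(1 / 65)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            forster_efficiency(0.0)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identity(self, r):
        # E(r) * (1 + (r/R0)^6) == 1 for all r
        E = forster_efficiency(r)
        assert E * (1 + (r / R0) ** 6) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_decreasing(self):
        r = np.linspace(0.5, 20, 500)
        E = forster_efficiency(r)
        assert np.all(np.diff(E) < 0)


class TestMeanEfficiency:
    def test_constant_series(self):
        assert mean_efficiency(DistanceSeries(np.full(10, R0))) == pytest.approx(0.5)

    def test_symmetric_limits(self):
        s = DistanceSeries(np.array([1e-6, 1e6]))
        assert mean_efficiency(s) == pytest.approx(0.5)

    def test_hand_value(self):
        s = DistanceSeries(np.array([5.4, 10.8]))
        assert mean_efficiency(s) == pytest.approx((0.5 + 1 / 65) / 2)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            DistanceSeries(np.array([]))

    def test_jensen_inequality_on_broad_ensembles(self):
        """<E(r)> vs E(<r>): on a broad lognormal distance ensemble the
        two differ in the direction given by the local curvature of E(r),
        checked against dense quadrature."""
        from scipy.stats import lognorm

        rng = np.random.default_rng(9)
        for mu_r, sigma in ((R0, 0.25), (1.8 * R0, 0.2)):
            dist = lognorm(s=sigma, scale=mu_r)
            r = dist.rvs(200000, random_state=rng)
            mc = mean_efficiency(DistanceSeries(r))
            grid = np.linspace(dist.ppf(1e-6), dist.ppf(1 - 1e-6), 20001)
            quad = np.trapezoid(forster_efficiency(grid) * dist.pdf(grid), grid)
            assert mc == pytest.approx(quad, abs=0.003)


class TestContacts:
    def test_pair_inside_cutoff(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0]])
        p = ContactParams(cutoff=1.2, group_A=(0,), group_B=(1,))
        assert count_contacts(coords, p) == 1

    def test_pair_outside_cutoff(self):
        coords = np.array([[0, 0, 0], [1.3, 0, 0]])
        p = ContactParams(cutoff=1.2, group_A=(0,), group_B=(1,))
        assert count_contacts(coords, p) == 0

    def test_boundary_is_excluded(self):
        coords = np.array([[0, 0, 0], [1.2, 0, 0]])
        p = ContactParams(cutoff=1.2, group_A=(0,), group_B=(1,))
        assert count_contacts(coords, p) == 0

    def test_empty_group_gives_zero(self):
        coords = np.zeros((3, 3))
        p = ContactParams(group_A=(), group_B=(0, 1))
        assert count_contacts(coords, p) == 0

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            ContactParams(group_A=(0, 1), group_B=(1, 2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.random((40, 3)) * 4.0
        A, B = tuple(range(20)), tuple(range(20, 40))
        p = ContactParams(cutoff=1.2, group_A=A, group_B=B)
        expected = sum(
            1
            for a in A
            for b in B
            if np.linalg.norm(coords[a] - coords[b]) < 1.2
        )
        assert count_contacts(coords, p) == expected


class TestContactLifetime:
    def test_direct_run_length(self):
        assert contact_lifetime([True, True, False, True], 1.0) == pytest.approx(1.5)

    def test_no_contact_flags_zero(self):
        with pytest.warns(NoContactWarning):
            assert contact_lifetime([False, False], 1.0) == 0.0

    def test_boundary_runs_included(self):
        assert contact_lifetime([True, False, False, True, True], 2.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_run_length_encoding_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        series = rng.random(500) < 0.4
        if not series.any():
            return
        runs, cur = [], 0
        for v in series:
            if v:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        assert contact_lifetime(series, 0.02) == pytest.approx(np.mean(runs) * 0.02)


def harmonic_windows(rng, k_bias=10.0, k_pmf=2.0, x0=8.0, n_windows=16,
                     span=(0.0, 16.0), n_samples=8000):
    """Umbrella windows sampled exactly from the Boltzmann distribution of
    U(x) = 0.5*k_pmf*(x-x0)^2 plus each harmonic bias: the combined
    potential is Gaussian, so sampling is closed-form (analytic oracle)."""
    kT = KB_KJ_MOL_K * 300.0
    centers = np.linspace(span[0], span[1], n_windows)
    windows = []
    for c in centers:
        k_tot = k_pmf + k_bias
        mean = (k_pmf * x0 + k_bias * c) / k_tot
        sd = np.sqrt(kT / k_tot)
        windows.append(
            UmbrellaWindow(center=c, force_constant=k_bias,
                           samples=rng.normal(mean, sd, n_samples))
        )
    return windows, (lambda x: 0.5 * k_pmf * (x - x0) ** 2)


class TestWham:
    def test_recovers_harmonic_pmf(self, rng):
        """16 windows at 10 kJ/mol/nm^2 over 0-16 nm: the recovered PMF
        matches the known harmonic potential within 0.5 kJ/mol over the
        well-sampled range."""
        windows, U = harmonic_windows(rng)
        profile = wham_pmf(windows, n_bins=80, temperature=300.0)
        well = profile.counts > 500
        ref = U(profile.bin_centers)
        ref = ref - ref[well].min()
        pmf = profile.pmf - np.nanmin(profile.pmf[well])
        assert np.nanmax(np.abs(pmf[well] - ref[well])) < 0.5

    def test_flat_pmf_with_weak_bias_is_flat(self, rng):
        """Near-zero bias on a flat landscape: recovered profile flat
        within noise."""
        span = (0.0, 4.0)
        windows = [
            UmbrellaWindow(center=c, force_constant=1e-6,
                           samples=rng.uniform(*span, 20000))
            for c in np.linspace(*span, 4)
        ]
        profile = wham_pmf(windows, n_bins=20, temperature=300.0)
        inner = profile.pmf[2:-2]
        # statistical noise floor: ~kT/sqrt(counts per bin) ~ 0.04 kJ/mol
        assert np.nanmax(inner) - np.nanmin(inner) < 0.2

    def test_window_order_invariance(self, rng):
        windows, _ = harmonic_windows(rng, n_samples=1000)
        p1 = wham_pmf(windows, n_bins=80)
        rng.shuffle(windows)
        p2 = wham_pmf(windows, n_bins=80)
        # agreement down to the self-consistency tolerance of the iteration
        np.testing.assert_allclose(p1.pmf, p2.pmf, atol=1e-4)

    def test_more_samples_converge(self, rng):
        """Doubling samples changes the PMF by less than the statistical
        tolerance over the well-sampled range."""
        w1, U = harmonic_windows(rng, n_samples=2000)
        w2, _ = harmonic_windows(rng, n_samples=4000)
        p1 = wham_pmf(w1, n_bins=80)
        p2 = wham_pmf(w2, n_bins=80)
        # interpolate onto shared grid
        grid = np.linspace(2, 14, 50)
        v1 = np.interp(grid, p1.bin_centers, np.nan_to_num(p1.pmf))
        v2 = np.interp(grid, p2.bin_centers, np.nan_to_num(p2.pmf))
        assert np.max(np.abs(v1 - v2)) < 0.6

    def test_non_overlapping_windows_fail_with_diagnostic(self, rng):
        w = [
            UmbrellaWindow(center=0.0, force_constant=10.0,
                           samples=rng.normal(0.0, 0.05, 500)),
            UmbrellaWindow(center=10.0, force_constant=10.0,
                           samples=rng.normal(10.0, 0.05, 500)),
        ]
        with pytest.raises(ValueError, match="non-overlapping"):
            wham_pmf(w)

    def test_single_window_rejected(self, rng):
        w = [UmbrellaWindow(center=0.0, samples=rng.normal(0, 1, 100))]
        with pytest.raises(ValueError):
            wham_pmf(w)
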