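"""Generator ground truth: expectations, round trips, determinism, PIE."""

import numpy as np
import pytest

from parfret import InstrumentSpec, MixtureTimeCourse, SpeciesSpec
from parfret.bursts import BurstSearchParams, find_bursts, is_donor_excitation
from parfret.corrections import compute_fret_points
from parfret.synthetic import (
    burst_expectations,
    donor_only,
    nucleosome_compact,
    nucleosome_decompacted,
    simulate_burst,
    simulate_kinetic_series,
    simulate_mixture_stream,
    simulate_slow_trace,
)


class TestBurstExpectations:
    def test_zero_transfer_no_distortions_gives_empty_acceptor(self, clean_instrument):
        sp = SpeciesSpec("e0", 0.0, 100, 100)
        ex = burst_expectations(sp, clean_instrument)
        assert ex["m_DA"] == 0.0

    def test_full_transfer_gives_empty_donor(self, clean_instrument):
        sp = SpeciesSpec("e1", 1.0, 100, 100)
        ex = burst_expectations(sp, clean_instrument)
        assert ex["m_DD"] == 0.0

    def test_hand_arithmetic_with_distortions(self):
        """E=0.36, T=100, alpha=delta=0.05, gamma=1.2 (hand oracle):
        F_DA = 36, F_DD = 64/1.2, F_AA = 100,
        m_DA = 36 + 0.05*64/1.2 + 0.05*100 = 43.6667."""
        inst = InstrumentSpec(leakage_alpha=0.05, direct_excitation_delta=0.05,
                              gamma=1.2, bg_rate_donor=0.0, bg_rate_acceptor=0.0)
        sp = SpeciesSpec("x", 0.36, 100, 100)
        ex = burst_expectations(sp, inst)
        assert ex["F_DA"] == pytest.approx(36.0)
        assert ex["F_DD"] == pytest.approx(64.0 / 1.2)
        assert ex["m_DA"] == pytest.approx(36.0 + 0.05 * 64.0 / 1.2 + 5.0)
        # round trip through the correction formulas recovers E exactly
        corr = inst.correction_set()
        F_DA = ex["m_DA"] - corr.alpha * ex["m_DD"] - corr.delta * ex["m_AA"]
        E = F_DA / (corr.gamma * ex["m_DD"] + F_DA)
        assert E == pytest.approx(0.36)

    def test_donor_only_emits_no_acceptor_excitation_signal(self, clean_instrument):
        ex = burst_expectations(donor_only(), clean_instrument)
        assert ex["m_AA"] == 0.0
        assert ex["m_DA"] == 0.0

    def test_acceptor_only_emits_no_donor_signal(self, clean_instrument):
        sp = SpeciesSpec("aonly", 0.0, 100, 100, labeled_state="acceptor-only")
        ex = burst_expectations(sp, clean_instrument)
        assert ex["m_DD"] == 0.0


class TestStreamStructure:
    def test_fixed_seed_bit_identical(self, instrument):
        sp = nucleosome_compact()
        s1, l1 = simulate_mixture_stream([sp], [1.0], 200, instrument, rng=99)
        s2, l2 = simulate_mixture_stream([sp], [1.0], 200, instrument, rng=99)
        np.testing.assert_array_equal(s1.timestamps, s2.timestamps)
        np.testing.assert_array_equal(s1.channel, s2.channel)
        np.testing.assert_array_equal(s1.microtime, s2.microtime)
        np.testing.assert_array_equal(l1, l2)

    def test_microtimes_inside_pie_period_and_windows(self, instrument):
        frag = simulate_burst(nucleosome_compact(), instrument, rng=3)
        assert np.all(frag.microtime >= 0)
        assert np.all(frag.microtime < instrument.pie_period)
        # every photon falls in exactly one window (classification total)
        donor = is_donor_excitation(frag.microtime, instrument)
        assert donor.size == len(frag)

    def test_signal_photon_windows_match_channels(self, clean_instrument):
        """Without background, donor-channel photons sit in the donor window
        and acceptor-excitation photons in the acceptor window."""
        sp = SpeciesSpec("x", 0.5, 200, 200)
        stream, _ = simulate_mixture_stream([sp], [1.0], 100, clean_instrument, rng=4)
        donor_ex = is_donor_excitation(stream.microtime, clean_instrument)
        ch = stream.channel
        assert np.all(donor_ex[ch == 0])  # DD photons
        # acceptor channel carries both DA (donor window) and AA photons
        assert np.any(~donor_ex[ch == 1]) and np.any(donor_ex[ch == 1])

    def test_streams_are_sorted(self, instrument):
        stream, _ = simulate_mixture_stream(
            [nucleosome_compact()], [1.0], 500, instrument, rng=8
        )
        assert stream.is_sorted()


class TestDistortionFreeRoundTrip:
    def test_empirical_mean_E_matches_truth(self, clean_instrument):
        """For a distortion-free instrument the mean of n_DA/(n_DA+n_DD)
        converges to true_E within 3 standard errors (binomial statistics
        make the per-burst estimator exactly unbiased)."""
        sp = nucleosome_compact()
        stream, _ = simulate_mixture_stream(
            [sp], [1.0], 12000, clean_instrument, rng=17, burst_rate=100
        )
        bursts = find_bursts(stream, BurstSearchParams.fast(), clean_instrument)
        assert len(bursts) >= 10000
        E = bursts.n_DA / (bursts.n_DA + bursts.n_DD)
        se = E.std() / np.sqrt(len(E))
        assert abs(E.mean() - sp.true_E) < 3 * se


class TestKineticSeries:
    def test_instant_reaction_all_decompacted(self, instrument):
        course = MixtureTimeCourse(f0=0.0, f_inf=1.0, k_obs=1e9,
                                   donor_only_fraction=0.0,
                                   times=np.array([1.0]))
        _, truth = simulate_kinetic_series(course, instrument, 500, rng=1)
        assert truth["timepoints"][0]["f_dec_realized"] == 1.0

    def test_time_zero_matches_f0(self, instrument):
        course = MixtureTimeCourse(f0=0.2, f_inf=0.9, k_obs=0.5,
                                   donor_only_fraction=0.0,
                                   times=np.array([0.0]))
        _, truth = simulate_kinetic_series(course, instrument, 4000, rng=2)
        realized = truth["timepoints"][0]["f_dec_realized"]
        assert realized == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / 4000))

    def test_half_life_point_near_half(self, instrument):
        # closed form: f0=0.1, f_inf=0.9, k=0.5 -> f(ln2/0.5) = 0.5
        course = MixtureTimeCourse(f0=0.1, f_inf=0.9, k_obs=0.5,
                                   donor_only_fraction=0.0,
                                   times=np.array([np.log(2) / 0.5]))
        _, truth = simulate_kinetic_series(course, instrument, 4000, rng=3)
        realized = truth["timepoints"][0]["f_dec_realized"]
        assert realized == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 4000))

    def test_invalid_burst_count_rejected(self, instrument):
        course = MixtureTimeCourse(times=np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_kinetic_series(course, instrument, 0, rng=1)


class TestSlowTrace:
    def test_burst_rate_yields_about_1000_per_minute(self, instrument):
        """1200 s at ~16.7 bursts/s gives ~1000 bursts per 60-s window."""
        course = MixtureTimeCourse(k_obs=0.0, f0=0.5, f_inf=0.5)
        stream, labels = simulate_slow_trace(course, instrument,
                                             duration=300.0, burst_rate=16.7,
                                             rng=5)
        per_minute = labels.size / (300.0 / 60.0)
        assert per_minute == pytest.approx(1000, rel=0.1)

    def test_zero_rate_keeps_fractions_constant(self, instrument):
        course = MixtureTimeCourse(k_obs=0.0, f0=0.3, f_inf=0.3,
                                   donor_only_fraction=0.0)
        _, labels = simulate_slow_trace(course, instrument,
                                        duration=600.0, burst_rate=20,
                                        rng=6)
        first = labels[: labels.size // 2]
        second = labels[labels.size // 2:]
        p1, p2 = np.mean(first == 1), np.mean(second == 1)
        se = np.sqrt(0.3 * 0.7 * (1 / first.size + 1 / second.size))
        assert abs(p1 - p2) < 4 * se

    def test_two_state_law_tracked_within_binomial_error(self, instrument):
        course = MixtureTimeCourse(k_obs=0.005, f0=0.1, f_inf=0.9,
                                   donor_only_fraction=0.0)
        stream, labels = simulate_slow_trace(course, instrument,
                                             duration=600.0, burst_rate=30,
                                             rng=7)
        t_arr = stream.metadata["burst_starts"]
        edges = np.linspace(0, 600, 11)
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t_arr >= lo) & (t_arr < hi)
            if m.sum() < 100:
                continue
            expected = course.f_dec(0.5 * (lo + hi))
            se = np.sqrt(expected * (1 - expected) / m.sum())
            assert np.mean(labels[m] == 1) == pytest.approx(expected, abs=4 * se + 0.02)

    def test_invalid_duration_rejected(self, instrument):
        with pytest.raises(ValueError):
            simulate_slow_trace(MixtureTimeCourse(), instrument, duration=0.0)
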