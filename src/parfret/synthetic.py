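"""Synthetic photon streams with the statistical structure the analysis assumes.

The generator is the inverse model of the correction chain in
:mod:`parfret.corrections`: for each simulated burst the *corrected* signal
expectations are fixed by the species' true transfer efficiency and
brightness, the instrument's distortions (leakage, direct excitation,
gamma, background) are applied forward, and photon counts are drawn from
Poisson distributions around the distorted expectations. Applying the
matching :class:`~parfret.corrections.CorrectionSet` therefore recovers
the ground truth in expectation — the property every recovery test leans on.

No optics are simulated: diffusion through the confocal volume only sets
the burst-size distribution (lognormal) and the burst envelope (uniform
photon times over a lognormal duration), which is all that matters to the
downstream count statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import two_state_fraction
from .stream import CHANNEL_ACCEPTOR, CHANNEL_DONOR, InstrumentSpec, PhotonStream

#: lognormal spread (sigma of log) of the per-burst size factor
BURST_SIZE_SIGMA = 0.45
#: lognormal spread of the burst duration
BURST_DURATION_SIGMA = 0.3


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground truth for one molecular species.

    ``true_E`` is the *corrected* transfer efficiency the analysis should
    recover; ``brightness_D_ex`` is the median corrected donor-excitation
    signal per burst (gamma-weighted, i.e. gamma*F_DD + F_DA) and
    ``brightness_A_ex`` the median acceptor-excitation signal (F_AA).
    """

    name: str
    true_E: float
    brightness_D_ex: float = 100.0
    brightness_A_ex: float = 100.0
    labeled_state: str = "double"  # double | donor-only | acceptor-only

    def __post_init__(self) -> None:
        if not 0 <= self.true_E <= 1:
            raise ValueError("true_E must lie in [0, 1]")
        if self.brightness_D_ex <= 0 or self.brightness_A_ex <= 0:
            raise ValueError("brightnesses must be positive")
        if self.labeled_state not in ("double", "donor-only", "acceptor-only"):
            raise ValueError(f"unknown labeled_state {self.labeled_state!r}")


# Species with the measured mean transfer efficiencies of the system this
# package was built around: 197-bp Widom-601 nucleosomes labeled at the
# linker-DNA termini, at 300 mM ionic strength unless noted.
def nucleosome_compact(**kw) -> SpeciesSpec:
    """Compact nucleosome, <E> = 0.36."""
    return SpeciesSpec("compact", 0.36, **kw)


def nucleosome_decompacted(**kw) -> SpeciesSpec:
    """Decompacted nucleosome (open linker arms), <E> = 0.053."""
    return SpeciesSpec("decompacted", 0.053, **kw)


def free_dna(**kw) -> SpeciesSpec:
    """Histone-free 197-bp Widom DNA, <E> = 0.035."""
    return SpeciesSpec("free_dna", 0.035, **kw)


def nucleosome_low_salt(**kw) -> SpeciesSpec:
    """Nucleosome at low ionic strength (single peak), <E> = 0.089."""
    return SpeciesSpec("low_salt", 0.089, **kw)


def donor_only(**kw) -> SpeciesSpec:
    """Molecules lacking an active acceptor; removed by the S gate."""
    kw.setdefault("brightness_A_ex", 1e-9)
    return SpeciesSpec("donor_only", 0.0, labeled_state="donor-only", **kw)


@dataclass
class MixtureTimeCourse:
    """Two-state reaction mixture with a constant donor-only contaminant.

    The decompacted fraction among FRET-active molecules follows the
    pseudo-first-order two-state law
    ``f_dec(t) = f_inf - (f_inf - f0) * exp(-k_obs * t)``.
    """

    compact: SpeciesSpec = field(default_factory=nucleosome_compact)
    decompacted: SpeciesSpec = field(default_factory=nucleosome_decompacted)
    f0: float = 0.1
    f_inf: float = 0.9
    k_obs: float = 0.42  # s^-1
    donor_only_fraction: float = 0.15
    contaminant: SpeciesSpec = field(default_factory=donor_only)
    times: np.ndarray | None = None  # reaction times, s

    def __post_init__(self) -> None:
        for name in ("f0", "f_inf", "donor_only_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.k_obs < 0:
            raise ValueError("k_obs must be non-negative")
        if self.times is not None:
            t = np.asarray(self.times, dtype=np.float64)
            if np.any(t < 0) or np.any(np.diff(t) < 0):
                raise ValueError("times must be non-negative and sorted")
            self.times = t

    @property
    def species(self) -> list[SpeciesSpec]:
        return [self.compact, self.decompacted, self.contaminant]

    def f_dec(self, t) -> np.ndarray:
        """Decompacted fraction among FRET-active molecules at time t."""
        return two_state_fraction(t, self.k_obs, self.f0, self.f_inf)


def _as_rng(rng, instrument: InstrumentSpec | None = None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None and instrument is not None and instrument.seed is not None:
        rng = instrument.seed
    return np.random.default_rng(rng)


def burst_expectations(species: SpeciesSpec, instrument: InstrumentSpec, scale: float = 1.0) -> dict:
    """Corrected signals and raw (distorted, background-free) channel means
    for one burst of median size times ``scale``.

    The raw donor-excitation acceptor expectation is the gamma-weighted
    FRET signal plus leakage and direct excitation:
    ``m_DA = F_DA + alpha*F_DD + delta*F_AA``.
    """
    g = instrument.gamma
    if species.labeled_state == "donor-only":
        T = species.brightness_D_ex * scale
        F_DD, F_DA, F_AA = T / g, 0.0, 0.0
    elif species.labeled_state == "acceptor-only":
        F_DD, F_DA = 0.0, 0.0
        F_AA = species.brightness_A_ex * scale
    else:
        T = species.brightness_D_ex * scale
        F_DA = species.true_E * T
        F_DD = (1.0 - species.true_E) * T / g
        F_AA = species.brightness_A_ex * scale
    m_DD = F_DD
    m_DA = F_DA + instrument.leakage_alpha * F_DD + instrument.direct_excitation_delta * F_AA
    m_AA = F_AA
    out = {"F_DD": F_DD, "F_DA": F_DA, "F_AA": F_AA, "m_DD": m_DD, "m_DA": m_DA, "m_AA": m_AA}
    if not all(np.isfinite(v) for v in out.values()):
        raise ValueError("non-finite channel expectation")
    return out


def _species_arrays(species_list, labels, instrument, scale, rng):
    """Per-burst Poisson signal counts for a label vector (vectorized)."""
    n = labels.size
    m_DD = np.empty(n)
    m_DA = np.empty(n)
    m_AA = np.empty(n)
    for k, sp in enumerate(species_list):
        mask = labels == k
        if not mask.any():
            continue
        ex = burst_expectations(sp, instrument, 1.0)
        m_DD[mask] = ex["m_DD"]
        m_DA[mask] = ex["m_DA"]
        m_AA[mask] = ex["m_AA"]
    m_DD, m_DA, m_AA = m_DD * scale, m_DA * scale, m_AA * scale
    return rng.poisson(m_DD), rng.poisson(m_DA), rng.poisson(m_AA)


def _assemble_stream(starts, durations, n_DD, n_DA, n_AA, instrument, rng,
                     total_duration, metadata) -> PhotonStream:
    """Scatter per-burst counts into photons, add background, sort, pack."""
    split, period = instrument.microtime_split, instrument.pie_period

    def scatter(counts, channel_id, mt_lo, mt_hi):
        total = int(counts.sum())
        t = np.repeat(starts, counts) + rng.random(total) * np.repeat(durations, counts)
        mt = mt_lo + rng.random(total) * (mt_hi - mt_lo)
        ch = np.full(total, channel_id, dtype=np.uint8)
        return t, ch, mt

    t_dd, ch_dd, mt_dd = scatter(n_DD, CHANNEL_DONOR, split, period)
    t_da, ch_da, mt_da = scatter(n_DA, CHANNEL_ACCEPTOR, split, period)
    t_aa, ch_aa, mt_aa = scatter(n_AA, CHANNEL_ACCEPTOR, 0.0, split)

    # uncorrelated background, uniform in time and over the PIE period
    parts_t = [t_dd, t_da, t_aa]
    parts_ch = [ch_dd, ch_da, ch_aa]
    parts_mt = [mt_dd, mt_da, mt_aa]
    for rate, channel_id in (
        (instrument.bg_rate_donor, CHANNEL_DONOR),
        (instrument.bg_rate_acceptor, CHANNEL_ACCEPTOR),
    ):
        nbg = rng.poisson(rate * total_duration)
        parts_t.append(rng.random(nbg) * total_duration)
        parts_ch.append(np.full(nbg, channel_id, dtype=np.uint8))
        parts_mt.append(rng.random(nbg) * period)

    t = np.concatenate(parts_t)
    ch = np.concatenate(parts_ch)
    mt = np.concatenate(parts_mt)
    ticks = np.round(t * instrument.clock_rate).astype(np.int64)
    order = np.argsort(ticks, kind="stable")
    return PhotonStream(
        timestamps=ticks[order],
        channel=ch[order],
        microtime=mt[order],
        clock_rate=instrument.clock_rate,
        metadata=metadata,
    )


def simulate_burst(species: SpeciesSpec, instrument: InstrumentSpec, rng=None,
                   t_start: float = 0.0) -> PhotonStream:
    """One burst (plus background over its duration) as a stream fragment."""
    rng = _as_rng(rng, instrument)
    scale = rng.lognormal(0.0, BURST_SIZE_SIGMA)
    dur = rng.lognormal(np.log(instrument.mean_burst_duration * 1e-3), BURST_DURATION_SIGMA)
    n_DD, n_DA, n_AA = _species_arrays([species], np.zeros(1, dtype=np.intp),
                                       instrument, np.array([scale]), rng)
    frag = _assemble_stream(
        np.array([t_start]), np.array([dur]), n_DD, n_DA, n_AA, instrument, rng,
        total_duration=t_start + dur,
        metadata={"species": species.name, "true_E": species.true_E},
    )
    return frag


def simulate_mixture_stream(species_list, probabilities, n_bursts: int,
                            instrument: InstrumentSpec, rng=None,
                            burst_rate: float = 100.0):
    """A stream of ``n_bursts`` bursts drawn i.i.d. from a species mixture.

    Burst arrivals are Poisson (exponential gaps with mean ``1/burst_rate``).
    Returns ``(stream, labels)`` where ``labels[i]`` indexes
    ``species_list`` for the i-th generated burst (ground truth).
    """
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    p = np.asarray(probabilities, dtype=np.float64)
    if p.size != len(species_list) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be a distribution over species_list")
    rng = _as_rng(rng, instrument)

    labels = rng.choice(len(species_list), size=n_bursts, p=p)
    gaps = rng.exponential(1.0 / burst_rate, n_bursts)
    durations = rng.lognormal(np.log(instrument.mean_burst_duration * 1e-3),
                              BURST_DURATION_SIGMA, n_bursts)
    starts = np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    scale = rng.lognormal(0.0, BURST_SIZE_SIGMA, n_bursts)
    n_DD, n_DA, n_AA = _species_arrays(species_list, labels, instrument, scale, rng)
    total_duration = float(starts[-1] + durations[-1] + rng.exponential(1.0 / burst_rate))
    stream = _assemble_stream(
        starts, durations, n_DD, n_DA, n_AA, instrument, rng, total_duration,
        metadata={"species": [sp.name for sp in species_list], "n_bursts": n_bursts},
    )
    return stream, labels


def simulate_kinetic_series(course: MixtureTimeCourse, instrument: InstrumentSpec,
                            bursts_per_timepoint: int = 3000, rng=None,
                            burst_rate: float = 100.0):
    """One stream per reaction time point of a droplet-mixer measurement.

    At each time ``t`` species assignments are independent draws with
    ``P(decompacted | FRET-active) = f_dec(t)`` and a constant donor-only
    contaminant fraction. Returns ``(streams, truth)`` where ``truth`` is a
    ground-truth record (per-timepoint true and realized fractions) fit for
    a sidecar file.
    """
    if bursts_per_timepoint < 1:
        raise ValueError("bursts_per_timepoint must be >= 1")
    if course.times is None:
        raise ValueError("course.times must be set")
    rng = _as_rng(rng, instrument)
    species_list = [course.compact, course.decompacted, course.contaminant]

    streams, records = [], []
    for t in course.times:
        fdec = float(course.f_dec(t))
        d = course.donor_only_fraction
        p = [(1 - d) * (1 - fdec), (1 - d) * fdec, d]
        stream, labels = simulate_mixture_stream(
            species_list, p, bursts_per_timepoint, instrument, rng, burst_rate
        )
        realized = float(np.mean(labels[labels != 2] == 1)) if np.any(labels != 2) else np.nan
        stream.metadata.update({"time_s": float(t), "f_dec_true": fdec})
        streams.append(stream)
        records.append(
            {"time_s": float(t), "f_dec_true": fdec, "f_dec_realized": realized,
             "n_bursts": bursts_per_timepoint}
        )
    truth = {
        "k_obs": course.k_obs, "f0": course.f0, "f_inf": course.f_inf,
        "donor_only_fraction": course.donor_only_fraction,
        "E_compact": course.compact.true_E, "E_decompacted": course.decompacted.true_E,
        "timepoints": records,
    }
    return streams, truth


def simulate_slow_trace(course: MixtureTimeCourse, instrument: InstrumentSpec,
                        duration: float = 1200.0, burst_rate: float = 16.7,
                        rng=None, start_time: float = 0.0):
    """One continuous manual-mixing trace with continuously evolving fractions.

    Burst arrivals are Poisson at ``burst_rate``; each burst's species is
    drawn with the decompacted probability evaluated at its own arrival
    time, so per-window fractions track the two-state law. Default length
    and rate emulate a 20-minute recording with ~1000 bursts per one-minute
    segment. ``start_time`` is the reaction time at which the recording
    begins (the manual-mixing dead time, ~5 s): the two-state law is
    evaluated at ``start_time + t_trace``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(rng, instrument)

    # Poisson arrivals over [0, duration]
    n_exp = rng.poisson(burst_rate * duration)
    starts = np.sort(rng.random(n_exp) * duration)
    n = starts.size
    fdec = course.f_dec(start_time + starts)
    d = course.donor_only_fraction
    u = rng.random(n)
    labels = np.where(u < d, 2, np.where(rng.random(n) < fdec, 1, 0))

    durations = rng.lognormal(np.log(instrument.mean_burst_duration * 1e-3),
                              BURST_DURATION_SIGMA, n)
    scale = rng.lognormal(0.0, BURST_SIZE_SIGMA, n)
    species_list = [course.compact, course.decompacted, course.contaminant]
    n_DD, n_DA, n_AA = _species_arrays(species_list, labels, instrument, scale, rng)
    stream = _assemble_stream(
        starts, durations, n_DD, n_DA, n_AA, instrument, rng, duration,
        metadata={
            "mode": "manual", "duration_s": duration, "burst_rate": burst_rate,
            "k_obs": course.k_obs, "f0": course.f0, "f_inf": course.f_inf,
            "donor_only_fraction": course.donor_only_fraction,
        },
    )
    # ground truth for recovery tests: per-burst arrival times and labels
    stream.metadata["burst_starts"] = starts
    stream.metadata["burst_labels"] = labels
    return stream, labels
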