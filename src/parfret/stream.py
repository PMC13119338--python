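"""Photon streams and the confocal/PIE instrument model.

A :class:`PhotonStream` is the raw observable of a diffusion-based
single-molecule FRET experiment: a time-ordered table of detected photons,
each carrying a macroscopic timestamp (integer clock ticks), a spectral
detection channel (donor or acceptor), and a microtime — the arrival time
within the pulsed-interleaved-excitation (PIE) period, which encodes which
laser excited the molecule.

Timestamps are kept as int64 clock ticks with an explicit clock rate to
avoid floating-point drift during binning; conversion to seconds happens
only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Spectral detection channels. The instrument's four physical channels
#: (two polarizations per color) collapse to two spectral channels here;
#: polarization is not used by this analysis.
CHANNEL_DONOR = 0
CHANNEL_ACCEPTOR = 1

DEFAULT_CLOCK_RATE = 1e8  # Hz, i.e. 10 ns timestamp resolution


@dataclass
class PhotonStream:
    """Time-ordered photon records.

    Parameters
    ----------
    timestamps : ndarray of int64
        Macroscopic arrival times in clock ticks, sorted ascending.
    channel : ndarray of uint8
        Spectral channel per photon (``CHANNEL_DONOR`` / ``CHANNEL_ACCEPTOR``).
    microtime : ndarray of float64
        Arrival time within the PIE period, in ns.
    clock_rate : float
        Ticks per second for `timestamps`.
    metadata : dict
        Free-form provenance (seed, ground truth, source file, ...).
    """

    timestamps: np.ndarray
    channel: np.ndarray
    microtime: np.ndarray
    clock_rate: float = DEFAULT_CLOCK_RATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.microtime = np.asarray(self.microtime, dtype=np.float64)
        if not (len(self.timestamps) == len(self.channel) == len(self.microtime)):
            raise ValueError("timestamps, channel and microtime must have equal length")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_photons(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        """Macroscopic arrival times in seconds."""
        return self.timestamps / self.clock_rate

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] / self.clock_rate)

    def is_sorted(self) -> bool:
        return bool(np.all(np.diff(self.timestamps) >= 0))

    def sorted(self) -> "PhotonStream":
        """Return a copy sorted by timestamp (stable)."""
        order = np.argsort(self.timestamps, kind="stable")
        return replace(
            self,
            timestamps=self.timestamps[order],
            channel=self.channel[order],
            microtime=self.microtime[order],
        )

    def slice_time(self, t0_s: float, t1_s: float) -> "PhotonStream":
        """Photons with arrival time in ``[t0_s, t1_s)``."""
        lo = int(np.searchsorted(self.timestamps, round(t0_s * self.clock_rate), "left"))
        hi = int(np.searchsorted(self.timestamps, round(t1_s * self.clock_rate), "left"))
        return replace(
            self,
            timestamps=self.timestamps[lo:hi],
            channel=self.channel[lo:hi],
            microtime=self.microtime[lo:hi],
        )

    @staticmethod
    def concatenate(streams: list["PhotonStream"]) -> "PhotonStream":
        if not streams:
            raise ValueError("no streams to concatenate")
        rates = {s.clock_rate for s in streams}
        if len(rates) != 1:
            raise ValueError("streams have differing clock rates")
        return PhotonStream(
            timestamps=np.concatenate([s.timestamps for s in streams]),
            channel=np.concatenate([s.channel for s in streams]),
            microtime=np.concatenate([s.microtime for s in streams]),
            clock_rate=streams[0].clock_rate,
            metadata=dict(streams[0].metadata),
        )


@dataclass
class InstrumentSpec:
    """PIE timing, background, and spectral-distortion parameters.

    The acceptor laser pulse arrives at the start of the PIE period and the
    donor pulse follows after ``pulse_delay`` ns, so microtimes below
    ``microtime_split`` belong to acceptor excitation and microtimes at or
    above it to donor excitation.

    Parameters
    ----------
    pie_period : float
        Laser repetition period in ns (50 ns = 20 MHz).
    pulse_delay : float
        Delay of the donor pulse after the acceptor pulse, ns (~25).
    microtime_split : float or None
        Boundary between the acceptor- and donor-excitation windows, ns.
        Defaults to ``pulse_delay``.
    bg_rate_donor, bg_rate_acceptor : float
        Background count rate per detection channel, photons/s. Background
        is spectrally and temporally uncorrelated, i.e. uniform over the
        PIE period, so the per-signal-class rates follow from the window
        fractions (see :meth:`correction_set`).
    leakage_alpha : float
        Fraction of donor photons detected in the acceptor channel.
    direct_excitation_delta : float
        Acceptor direct excitation by the donor laser, referenced to the
        acceptor-excitation signal (PIE convention).
    gamma : float
        Detection-efficiency / quantum-yield correction factor.
    mean_burst_duration : float
        Median burst duration in ms used by the generator.
    seed : int or None
        Default RNG seed for generators that are not handed an explicit one.
    """

    pie_period: float = 50.0
    pulse_delay: float = 25.0
    microtime_split: float | None = None
    bg_rate_donor: float = 1500.0
    bg_rate_acceptor: float = 1500.0
    leakage_alpha: float = 0.05
    direct_excitation_delta: float = 0.05
    gamma: float = 1.0
    mean_burst_duration: float = 0.5
    seed: int | None = None
    clock_rate: float = DEFAULT_CLOCK_RATE

    def __post_init__(self) -> None:
        if self.microtime_split is None:
            self.microtime_split = self.pulse_delay
        if not (self.pie_period > self.pulse_delay > 0):
            raise ValueError("require pie_period > pulse_delay > 0")
        if not (0 < self.microtime_split < self.pie_period):
            raise ValueError("microtime_split must lie inside the PIE period")
        if self.leakage_alpha < 0 or self.direct_excitation_delta < 0:
            raise ValueError("alpha and delta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.bg_rate_donor < 0 or self.bg_rate_acceptor < 0:
            raise ValueError("background rates must be non-negative")

    @property
    def donor_window_fraction(self) -> float:
        return (self.pie_period - self.microtime_split) / self.pie_period

    @property
    def acceptor_window_fraction(self) -> float:
        return self.microtime_split / self.pie_period

    def correction_set(self):
        """The :class:`~parfret.corrections.CorrectionSet` matching this
        instrument — effective per-class background rates plus the spectral
        factors. Applying it to bursts generated with this instrument
        inverts the distortion chain exactly in expectation."""
        from .corrections import CorrectionSet

        return CorrectionSet(
            bg_rate_DD=self.bg_rate_donor * self.donor_window_fraction,
            bg_rate_DA=self.bg_rate_acceptor * self.donor_window_fraction,
            bg_rate_AA=self.bg_rate_acceptor * self.acceptor_window_fraction,
            alpha=self.leakage_alpha,
            delta=self.direct_excitation_delta,
            gamma=self.gamma,
        )
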