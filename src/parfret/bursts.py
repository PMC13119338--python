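"""Photon-burst identification by fixed-bin thresholding.

Bursts are found by binning all photons (both channels, both excitation
windows) into fixed bins anchored at t=0 of the stream; a bin is *hot* when
its total count reaches the threshold, and maximal runs of hot bins are
merged into one burst. Two parameter sets are in use: 40 photons per 500-us
bin for fast droplet-mixer data, and 60 photons per 1-ms bin for slow
manual-mixing traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stream import CHANNEL_ACCEPTOR, CHANNEL_DONOR, InstrumentSpec, PhotonStream

D_EX = "D_ex"
A_EX = "A_ex"


@dataclass(frozen=True)
class BurstSearchParams:
    """Fixed-bin burst-search settings.

    ``fast`` mode: 40 photons / 500 us bin (droplet mixer).
    ``slow`` mode: 60 photons / 1 ms bin (manual mixing, equilibrium).
    """

    bin_width: float = 0.0005  # s
    threshold: int = 40  # photons per bin, all channels
    mode: str = "fast"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.mode not in ("fast", "slow"):
            raise ValueError("mode must be 'fast' or 'slow'")

    @classmethod
    def fast(cls) -> "BurstSearchParams":
        return cls(bin_width=0.0005, threshold=40, mode="fast")

    @classmethod
    def slow(cls) -> "BurstSearchParams":
        return cls(bin_width=0.001, threshold=60, mode="slow")


@dataclass(frozen=True)
class Burst:
    """One photon burst with per-class counts.

    n_DD: donor channel under donor excitation; n_DA: acceptor channel
    under donor excitation (the FRET signal); n_AA: acceptor channel under
    acceptor excitation (the PIE stoichiometry signal).
    """

    start: float
    stop: float
    n_DD: int
    n_DA: int
    n_AA: int
    n_all: int

    @property
    def duration(self) -> float:
        return self.stop - self.start


class BurstTable:
    """Column-oriented collection of bursts (numpy-backed)."""

    def __init__(self, start, stop, n_DD, n_DA, n_AA, n_all) -> None:
        self.start = np.asarray(start, dtype=np.float64)
        self.stop = np.asarray(stop, dtype=np.float64)
        self.n_DD = np.asarray(n_DD, dtype=np.int64)
        self.n_DA = np.asarray(n_DA, dtype=np.int64)
        self.n_AA = np.asarray(n_AA, dtype=np.int64)
        self.n_all = np.asarray(n_all, dtype=np.int64)
        if np.any(self.stop <= self.start):
            raise ValueError("every burst must satisfy stop > start")

    @property
    def duration(self) -> np.ndarray:
        return self.stop - self.start

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i: int) -> Burst:
        return Burst(
            start=float(self.start[i]),
            stop=float(self.stop[i]),
            n_DD=int(self.n_DD[i]),
            n_DA=int(self.n_DA[i]),
            n_AA=int(self.n_AA[i]),
            n_all=int(self.n_all[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start": self.start,
                "stop": self.stop,
                "n_DD": self.n_DD,
                "n_DA": self.n_DA,
                "n_AA": self.n_AA,
                "n_all": self.n_all,
            }
        )

def _empty_table() -> BurstTable:
    t = BurstTable.__new__(BurstTable)
    z = np.empty(0, dtype=np.float64)
    zi = np.empty(0, dtype=np.int64)
    t.start, t.stop = z, z.copy()
    t.n_DD, t.n_DA, t.n_AA, t.n_all = zi, zi.copy(), zi.copy(), zi.copy()
    return t


def classify_pie(microtime: float, instrument: InstrumentSpec) -> str:
    """Assign a photon to its excitation window from its microtime.

    The acceptor pulse opens the period, the donor pulse follows after the
    inter-pulse delay; microtimes below the split are acceptor excitation.
    The split itself belongs to donor excitation (half-open convention,
    shared with the generator).
    """
    if not 0 <= microtime < instrument.pie_period:
        raise ValueError(
            f"microtime {microtime} ns outside PIE period [0, {instrument.pie_period})"
        )
    return A_EX if microtime < instrument.microtime_split else D_EX


def is_donor_excitation(microtime: np.ndarray, instrument: InstrumentSpec) -> np.ndarray:
    """Vectorized PIE classification; True where the donor laser excited."""
    microtime = np.asarray(microtime)
    if microtime.size and (microtime.min() < 0 or microtime.max() >= instrument.pie_period):
        raise ValueError("microtimes outside the PIE period")
    return microtime >= instrument.microtime_split


def find_bursts(
    stream: PhotonStream,
    params: BurstSearchParams,
    instrument: InstrumentSpec,
) -> BurstTable:
    """Fixed-bin threshold burst search with consecutive-bin merging.

    A bin is hot iff its total photon count (all channels, all excitation
    windows) is at least ``params.threshold``; maximal runs of hot bins
    become single bursts whose boundaries are the outer bin edges. Counts
    are split into the DD/DA/AA signal classes by channel and PIE window.
    """
    if len(stream) == 0:
        return _empty_table()
    if not stream.is_sorted():
        raise ValueError("photon timestamps must be sorted ascending")

    bin_ticks = int(round(params.bin_width * stream.clock_rate))
    if bin_ticks < 1:
        raise ValueError("bin_width below timestamp resolution")
    bins = stream.timestamps // bin_ticks

    ids, counts = np.unique(bins, return_counts=True)
    hot = ids[counts >= params.threshold]
    if hot.size == 0:
        return _empty_table()

    # runs of consecutive hot bin ids -> bursts
    breaks = np.flatnonzero(np.diff(hot) > 1)
    first = hot[np.concatenate(([0], breaks + 1))]
    last = hot[np.concatenate((breaks, [hot.size - 1]))]

    # map each photon to its burst (or -1)
    idx = np.searchsorted(first, bins, side="right") - 1
    in_burst = (idx >= 0) & (bins <= last[np.clip(idx, 0, None)])
    idx = idx[in_burst]

    donor_ex = is_donor_excitation(stream.microtime[in_burst], instrument)
    ch = stream.channel[in_burst]
    nb = first.size
    n_all = np.bincount(idx, minlength=nb)
    n_DD = np.bincount(idx[(ch == CHANNEL_DONOR) & donor_ex], minlength=nb)
    n_DA = np.bincount(idx[(ch == CHANNEL_ACCEPTOR) & donor_ex], minlength=nb)
    n_AA = np.bincount(idx[(ch == CHANNEL_ACCEPTOR) & ~donor_ex], minlength=nb)

    w = bin_ticks / stream.clock_rate
    return BurstTable(
        start=first * w,
        stop=(last + 1) * w,
        n_DD=n_DD,
        n_DA=n_DA,
        n_AA=n_AA,
        n_all=n_all,
    )


class UnderCountWarning(UserWarning):
    """Fewer bursts than the analysis expects for stable histograms."""


def burst_qc(bursts: BurstTable, min_bursts: int = 3000) -> BurstTable:
    """Pass bursts through, warning when fewer than ``min_bursts``.

    The analysis expects at least ~3000 bursts per fast-mode time point and
    ~1000 per slow-mode one-minute window; a shortfall degrades histogram
    fits but is not fatal, hence a warning rather than an error.
    """
    if len(bursts) < min_bursts:
        warnings.warn(
            f"only {len(bursts)} bursts (expected >= {min_bursts})",
            UnderCountWarning,
            stacklevel=2,
        )
    return bursts
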