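"""Run configuration: validated settings with mode-dependent defaults.

Defaults mirror the measurement settings the pipeline was built for:
burst search at 40 photons / 500 us (droplet mode) or 60 photons / 1 ms
(manual mode), stoichiometry gates 0.2-0.8 (0.25-0.75 for the
intermolecular experiment), droplet velocity 0.6 mm/s, 5 s manual-mixing
dead time, 20 MHz PIE with ~25 ns pulse delay.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .bursts import BurstSearchParams
from .corrections import CorrectionSet
from .kinetics import TimepointMap
from .stream import InstrumentSpec


@dataclass
class RunConfig:
    mode: str = "droplet"  # droplet | manual

    # burst search (None -> mode default)
    bin_width: float | None = None
    threshold: int | None = None

    # instrument / PIE
    pie_period: float = 50.0
    pulse_delay: float = 25.0
    bg_rate_donor: float = 1500.0
    bg_rate_acceptor: float = 1500.0

    # spectral corrections
    alpha: float = 0.05
    delta: float = 0.05
    gamma: float = 1.0

    # stoichiometry gate
    s_low: float = 0.2
    s_high: float = 0.8

    # histogramming
    hist_bin_width: float = 0.025
    e_min: float = -0.1
    e_max: float = 1.1
    n_ref_stat: str = "median"  # median | mean

    # time mapping
    droplet_velocity: float = 0.6  # mm/s
    dead_time: float | None = None  # None -> 0 (droplet) or 5 s (manual)
    positions_mm: list[float] = field(default_factory=list)

    # slow-trace segmentation
    window_s: float = 60.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("droplet", "manual"):
            raise ValueError("mode must be 'droplet' or 'manual'")
        if not (0 <= self.s_low < self.s_high <= 1):
            raise ValueError("require 0 <= s_low < s_high <= 1")
        if self.n_ref_stat not in ("median", "mean"):
            raise ValueError("n_ref_stat must be 'median' or 'mean'")

    # -- mode-dependent resolved values ------------------------------------
    @property
    def resolved_bin_width(self) -> float:
        if self.bin_width is not None:
            return self.bin_width
        return 0.0005 if self.mode == "droplet" else 0.001

    @property
    def resolved_threshold(self) -> int:
        if self.threshold is not None:
            return self.threshold
        return 40 if self.mode == "droplet" else 60

    @property
    def resolved_dead_time(self) -> float:
        if self.dead_time is not None:
            return self.dead_time
        return 0.0 if self.mode == "droplet" else 5.0

    # -- converters ---------------------------------------------------------
    def burst_params(self) -> BurstSearchParams:
        return BurstSearchParams(
            bin_width=self.resolved_bin_width,
            threshold=self.resolved_threshold,
            mode="fast" if self.mode == "droplet" else "slow",
        )

    def instrument(self) -> InstrumentSpec:
        return InstrumentSpec(
            pie_period=self.pie_period,
            pulse_delay=self.pulse_delay,
            bg_rate_donor=self.bg_rate_donor,
            bg_rate_acceptor=self.bg_rate_acceptor,
            leakage_alpha=self.alpha,
            direct_excitation_delta=self.delta,
            gamma=self.gamma,
            seed=self.seed,
        )

    def correction_set(self) -> CorrectionSet:
        return self.instrument().correction_set()

    def timepoint_map(self) -> TimepointMap:
        return TimepointMap(
            positions=self.positions_mm,
            droplet_velocity=self.droplet_velocity,
            dead_time=self.resolved_dead_time,
        )

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
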