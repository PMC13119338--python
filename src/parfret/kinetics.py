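"""Two-state pseudo-first-order kinetics of nucleosome decompaction.

Under pseudo-first-order conditions (PAR in large excess over nucleosome)
the compact <-> decompacted interconversion relaxes mono-exponentially:

    f_dec(t) = f_inf - (f_inf - f0) * exp(-k_obs * t)

with observed rate ``k_obs``, initial decompacted fraction ``f0`` and
equilibrium fraction ``f_inf``. Fast (droplet-mixer) series map channel
positions to reaction times through the droplet velocity; slow
(manual-mixing) traces are segmented into one-minute windows that each
yield a histogram time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .bursts import BurstSearchParams, BurstTable, find_bursts
from .stream import InstrumentSpec, PhotonStream


@dataclass(frozen=True)
class TimepointMap:
    """Observation-channel positions -> reaction times.

    ``time = dead_time + position / droplet_velocity``. The droplet mixer
    covers a few milliseconds up to ~60 s at the 0.6 mm/s default velocity;
    manual mixing adds a ~5 s dead time instead.
    """

    positions: np.ndarray  # mm
    droplet_velocity: float = 0.6  # mm/s
    dead_time: float = 0.0  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.float64))
        if self.droplet_velocity <= 0:
            raise ValueError("droplet_velocity must be positive")
        if np.any(self.positions < 0):
            raise ValueError("positions must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("mapped times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.dead_time + self.positions / self.droplet_velocity


def position_to_time(tmap: TimepointMap, position: float) -> float:
    """Reaction time (s) of a measurement position (mm) along the channel."""
    if position < 0:
        raise ValueError("position must be non-negative")
    return tmap.dead_time + position / tmap.droplet_velocity


def two_state_fraction(t, k_obs: float, f0: float, f_inf: float):
    """f(t) = f_inf - (f_inf - f0) * exp(-k_obs * t)."""
    t = np.asarray(t, dtype=np.float64)
    out = f_inf - (f_inf - f0) * np.exp(-k_obs * t)
    return out if out.ndim else float(out)


@dataclass
class KineticSeries:
    """Time-resolved decompacted fractions with uncertainties."""

    times: np.ndarray  # s
    f_dec: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)  # PAR length / conc / ionic strength

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.f_dec = np.asarray(self.f_dec, dtype=np.float64)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any((self.f_dec < -1e-9) | (self.f_dec > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class KineticFit:
    """Fitted two-state parameters with uncertainties."""

    k_obs: float
    f0: float
    f_inf: float
    stderr: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    flag: str | None = None
    metadata: dict = field(default_factory=dict)
    redchi: float | None = None

    def confidence_interval(self, name: str = "k_obs") -> tuple[float, float]:
        return self.ci95.get(name, (np.nan, np.nan))


def fit_kinetics(series: KineticSeries) -> KineticFit:
    """Weighted least-squares fit of the two-state law to a fraction series.

    Weights come from the per-timepoint fraction uncertainties (uniform if
    absent). Parameters are bounded (k_obs >= 0, fractions in [0, 1]) and
    95% confidence intervals are derived from the covariance of the
    weighted fit. A series with no usable variation is reported with
    k_obs = 0 and a flag rather than failing.
    """
    t, f = series.times, series.f_dec
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    sigma = series.sigma
    if sigma is None:
        sigma = np.full_like(f, 0.02)
    sigma = np.clip(sigma, 1e-4, None)

    if np.ptp(f) < 1e-12:
        return KineticFit(
            k_obs=0.0, f0=float(f[0]), f_inf=float(f[-1]),
            flag="constant_series", metadata=dict(series.metadata),
        )

    params = lmfit.Parameters()
    # initial rate guess from the time at which f crosses halfway
    fmid = 0.5 * (f[0] + f[-1])
    icross = int(np.argmin(np.abs(f - fmid)))
    t_half = max(t[icross], t[t > 0].min() if np.any(t > 0) else 1.0)
    params.add("k_obs", value=np.log(2.0) / t_half, min=0.0, max=1e4)
    params.add("f0", value=float(np.clip(f[np.argmin(t)], 0, 1)), min=0.0, max=1.0)
    params.add("f_inf", value=float(np.clip(f[np.argmax(t)], 0, 1)), min=0.0, max=1.0)

    def residual(p):
        return (two_state_fraction(t, p["k_obs"].value, p["f0"].value, p["f_inf"].value) - f) / sigma

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"kinetic fit failed: {result.message}")

    # 95% CIs from the weighted-fit covariance with the small-sample
    # Student-t quantile (n - 3 fitted parameters degrees of freedom)
    from scipy.stats import t as t_dist

    dof = max(t.size - 3, 1)
    crit = float(t_dist.ppf(0.975, dof))
    stderr, ci95 = {}, {}
    for name in ("k_obs", "f0", "f_inf"):
        p = result.params[name]
        se = p.stderr if p.stderr is not None else np.nan
        stderr[name] = se
        ci95[name] = (p.value - crit * se, p.value + crit * se) if np.isfinite(se) else (np.nan, np.nan)

    fit = KineticFit(
        k_obs=float(result.params["k_obs"].value),
        f0=float(result.params["f0"].value),
        f_inf=float(result.params["f_inf"].value),
        stderr=stderr,
        ci95=ci95,
        metadata=dict(series.metadata),
        redchi=float(result.redchi),
    )
    if fit.k_obs < 1e-10:
        fit.flag = "zero_rate"
    return fit


class PartialWindowNotice(UserWarning):
    """A trailing partial segment was dropped from a slow trace."""


def segment_trace(stream: PhotonStream, instrument: InstrumentSpec,
                  window: float = 60.0,
                  params: BurstSearchParams | None = None,
                  duration: float | None = None) -> list[tuple[float, BurstTable]]:
    """Cut a slow manual-mixing trace into consecutive windows of bursts.

    Each non-overlapping ``window``-second interval is burst-searched in
    slow mode (60 photons per 1-ms bin) and reported with its midpoint as
    the reaction time (relative to the trace start; add the mixing dead
    time externally). A trailing partial window is dropped with a notice.

    The recording length is taken from ``duration``, falling back to the
    stream's ``duration_s`` metadata and finally to the last photon's
    arrival time.
    """
    if params is None:
        params = BurstSearchParams.slow()
    if duration is None:
        duration = float(stream.metadata.get("duration_s", stream.duration_s))
    if duration < window:
        raise ValueError(f"trace ({duration:.1f} s) shorter than one window ({window} s)")
    n_win = int(duration // window)
    if duration - n_win * window > 1e-9:
        warnings.warn(
            f"dropping trailing partial window of {duration - n_win * window:.1f} s",
            PartialWindowNotice, stacklevel=2,
        )
    out = []
    for i in range(n_win):
        t0, t1 = i * window, (i + 1) * window
        sub = stream.slice_time(t0, t1)
        bursts = find_bursts(sub, params, instrument)
        out.append((0.5 * (t0 + t1), bursts))
    return out


def summarize_conditions(fits: list[KineticFit]) -> pd.DataFrame:
    """Long-format condition table: one row per fit.

    Columns carry the experimental condition metadata (PAR length, PAR
    chain concentration, ionic strength) next to (k_obs, f_inf) and their
    standard errors. No interpolation or modeling across conditions.
    """
    rows = []
    for fit in fits:
        row = {
            "par_length": fit.metadata.get("par_length"),
            "par_concentration_nM": fit.metadata.get("par_concentration_nM"),
            "ionic_strength_mM": fit.metadata.get("ionic_strength_mM"),
            "k_obs": fit.k_obs,
            "k_obs_stderr": fit.stderr.get("k_obs", np.nan),
            "f_inf": fit.f_inf,
            "f_inf_stderr": fit.stderr.get("f_inf", np.nan),
            "flag": fit.flag,
        }
        rows.append(row)
    columns = ["par_length", "par_concentration_nM", "ionic_strength_mM",
               "k_obs", "k_obs_stderr", "f_inf", "f_inf_stderr", "flag"]
    return pd.DataFrame(rows, columns=columns)
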