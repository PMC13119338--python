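"""Raw burst counts -> corrected transfer efficiency and stoichiometry.

Implements the accepted standard correction chain for PIE/ALEX data:
background subtraction per signal class, donor->acceptor leakage (alpha),
acceptor direct excitation referenced to the acceptor-excitation signal
(delta), and the gamma factor for unequal quantum yields and detection
efficiencies:

    F_DD = n_DD - bg_DD * T
    F_AA = n_AA - bg_AA * T
    F_DA = n_DA - bg_DA * T - alpha * F_DD - delta * F_AA

    E = F_DA / (gamma * F_DD + F_DA)
    S = (gamma * F_DD + F_DA) / (gamma * F_DD + F_DA + F_AA)

With alpha = delta = background = 0 and gamma = 1 this reduces exactly to
E = n_A / (n_A + n_D). Negative corrected counts are clamped to zero and
flagged rather than dropped, so burst counts stay usable for population
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst, BurstTable


@dataclass(frozen=True)
class CorrectionSet:
    """Background rates (photons/s per signal class) and spectral factors."""

    bg_rate_DD: float = 0.0
    bg_rate_DA: float = 0.0
    bg_rate_AA: float = 0.0
    alpha: float = 0.05
    delta: float = 0.05
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.bg_rate_DD, self.bg_rate_DA, self.bg_rate_AA) < 0:
            raise ValueError("background rates must be non-negative")
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def identity(cls) -> "CorrectionSet":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 1.0)


def correct_counts(burst, corr: CorrectionSet, duration=None, clamp: bool = True):
    """Apply the correction chain to raw counts.

    Accepts a single :class:`Burst`, a :class:`BurstTable`, or raw arrays
    (pass ``n_DD, n_DA, n_AA`` as a tuple plus ``duration``). Returns
    ``(F_DD, F_DA, F_AA, clamped)`` where ``clamped`` marks bursts on which
    a corrected count came out negative. With ``clamp=True`` (default)
    negative values are clipped to zero — appropriate for stoichiometry and
    count reporting; with ``clamp=False`` they are returned as-is, which is
    what the transfer-efficiency histogram needs: per-burst corrected E
    legitimately scatters slightly below 0 by shot noise, and truncating it
    would pile bursts up at E = 0 and skew the low-E peak.
    """
    if isinstance(burst, Burst):
        n_DD, n_DA, n_AA = burst.n_DD, burst.n_DA, burst.n_AA
        duration = burst.duration
    elif isinstance(burst, BurstTable):
        n_DD, n_DA, n_AA = burst.n_DD, burst.n_DA, burst.n_AA
        duration = burst.duration
    else:
        n_DD, n_DA, n_AA = burst
        if duration is None:
            raise ValueError("duration required with raw count arrays")

    n_DD = np.asarray(n_DD, dtype=np.float64)
    n_DA = np.asarray(n_DA, dtype=np.float64)
    n_AA = np.asarray(n_AA, dtype=np.float64)
    duration = np.asarray(duration, dtype=np.float64)
    if np.any(duration <= 0):
        raise ValueError("burst duration must be positive")

    F_DD = n_DD - corr.bg_rate_DD * duration
    F_AA = n_AA - corr.bg_rate_AA * duration
    F_DA = n_DA - corr.bg_rate_DA * duration - corr.alpha * F_DD - corr.delta * F_AA
    clamped = (F_DD < 0) | (F_AA < 0) | (F_DA < 0)
    if clamp:
        F_DD = np.clip(F_DD, 0.0, None)
        F_AA = np.clip(F_AA, 0.0, None)
        F_DA = np.clip(F_DA, 0.0, None)
    return F_DD, F_DA, F_AA, clamped


def transfer_efficiency(F_DD, F_DA, gamma: float = 1.0):
    """Corrected transfer efficiency E = F_DA / (gamma*F_DD + F_DA).

    Zero-denominator points are returned as NaN (excluded downstream).
    """
    F_DD = np.asarray(F_DD, dtype=np.float64)
    F_DA = np.asarray(F_DA, dtype=np.float64)
    denom = gamma * F_DD + F_DA
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(denom > 0, F_DA / denom, np.nan)
    return E if E.ndim else float(E)


def stoichiometry(F_DD, F_DA, F_AA, gamma: float = 1.0):
    """Stoichiometry ratio S = (gamma*F_DD + F_DA) / (gamma*F_DD + F_DA + F_AA).

    S ~ 1 for donor-only molecules, ~ 0 for acceptor-only, ~ 0.5 for
    doubly labeled molecules under balanced excitation. Zero-denominator
    points are NaN.
    """
    F_DD = np.asarray(F_DD, dtype=np.float64)
    F_DA = np.asarray(F_DA, dtype=np.float64)
    F_AA = np.asarray(F_AA, dtype=np.float64)
    dex = gamma * F_DD + F_DA
    denom = dex + F_AA
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, dex / denom, np.nan)
    return S if S.ndim else float(S)


def compute_fret_points(bursts: BurstTable, corr: CorrectionSet) -> pd.DataFrame:
    """Corrected (E, S) per burst.

    Returns a DataFrame with columns ``E``, ``S``, ``n_dex`` (corrected
    donor-excitation photons, the statistic entering the shot-noise width),
    ``n_total``, ``clamped`` and ``valid`` (finite E and S), indexed like
    the burst table.
    """
    Fu_DD, Fu_DA, Fu_AA, clamped = correct_counts(bursts, corr, clamp=False)
    F_DD, F_DA, F_AA = (np.clip(F, 0.0, None) for F in (Fu_DD, Fu_DA, Fu_AA))
    # E from unclamped signals: shot noise scatters corrected E slightly
    # outside [0, 1] and truncating would skew the low-E peak
    E = transfer_efficiency(Fu_DD, Fu_DA, corr.gamma)
    S = stoichiometry(F_DD, F_DA, F_AA, corr.gamma)
    n_dex = F_DD + F_DA
    return pd.DataFrame(
        {
            "E": np.atleast_1d(E),
            "S": np.atleast_1d(S),
            "n_dex": np.atleast_1d(n_dex),
            "n_total": np.atleast_1d(n_dex + F_AA),
            "n_aa": np.atleast_1d(F_AA),
            "start": bursts.start,
            "duration": bursts.duration,
            "clamped": np.atleast_1d(clamped),
            "valid": np.isfinite(np.atleast_1d(E)) & np.isfinite(np.atleast_1d(S)),
        }
    )


def gate_stoichiometry(points: pd.DataFrame, s_low: float = 0.2, s_high: float = 0.8) -> pd.DataFrame:
    """Keep FRET-active bursts with S strictly inside ``(s_low, s_high)``.

    This removes donor-only (S ~ 1) and acceptor-only (S ~ 0) molecules
    before histogramming. Gates in use: 0.2 < S < 0.8 for the nucleosome
    measurements, 0.25 < S < 0.75 for the intermolecular-FRET experiment.
    """
    if not (0 <= s_low < s_high <= 1):
        raise ValueError("require 0 <= s_low < s_high <= 1")
    mask = points["valid"] & (points["S"] > s_low) & (points["S"] < s_high)
    return points.loc[mask]
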