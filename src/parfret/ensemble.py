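"""Trajectory-side analysis: Förster efficiencies, contacts, WHAM PMFs.

These operations consume pre-extracted per-frame quantities (dye-dye
distances, bead coordinates, umbrella-sampling reaction-coordinate series)
as plain arrays or delimited text, keeping the module agnostic of the
simulation engine that produced them.

Note on the distance-to-efficiency conversion: the Förster equation is
implemented in its standard sixth-power form

    E(r) = 1 / (1 + (r / R0)**6)

with R0 = 5.4 nm for the Alexa 488 / Alexa 594 pair. Ensemble efficiencies
are averages of per-frame E values (the dynamics are fast on the photon
timescale), not the efficiency of the mean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

KB_KJ_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K


@dataclass(frozen=True)
class ForsterModel:
    """Förster radius of the dye pair, nm."""

    R0: float = 5.4

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


@dataclass
class DistanceSeries:
    """Per-frame dye-dye distances, nm."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.size == 0:
            raise ValueError("empty distance series")
        if np.any(self.r <= 0):
            raise ValueError("distances must be positive")


def forster_efficiency(r, model: ForsterModel = ForsterModel()):
    """E(r) = 1 / (1 + (r/R0)^6); strictly decreasing in r."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = 1.0 / (1.0 + (r / model.R0) ** 6)
    return out if out.ndim else float(out)


def mean_efficiency(series: DistanceSeries, model: ForsterModel = ForsterModel()) -> float:
    """Ensemble-average efficiency <E> = mean over frames of E(r_frame)."""
    return float(np.mean(forster_efficiency(series.r, model)))


@dataclass(frozen=True)
class ContactParams:
    """Intermolecular contact definition: pair distance strictly below cutoff."""

    cutoff: float = 1.2  # nm
    group_A: tuple = ()
    group_B: tuple = ()

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if set(self.group_A) & set(self.group_B):
            raise ValueError("contact groups must be disjoint")


def count_contacts(coords: np.ndarray, params: ContactParams) -> int:
    """Number of (a in A, b in B) bead pairs closer than the cutoff.

    ``coords`` holds one frame of bead coordinates, shape (n_beads, 3);
    the groups index into it. Strict inequality at the cutoff.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if len(params.group_A) == 0 or len(params.group_B) == 0:
        return 0
    a = coords[list(params.group_A)]
    b = coords[list(params.group_B)]
    return int(np.count_nonzero(cdist(a, b) < params.cutoff))


class NoContactWarning(UserWarning):
    pass


def contact_lifetime(contact_timeseries, frame_dt: float = 1.0) -> float:
    """Mean duration of maximal runs of continuous contact.

    Runs touching the series boundaries are included. Returns 0 (with a
    warning) when the series holds no contact at all.
    """
    c = np.asarray(contact_timeseries, dtype=bool)
    if c.size == 0:
        raise ValueError("empty contact series")
    if not c.any():
        warnings.warn("no contacts in series", NoContactWarning, stacklevel=2)
        return 0.0
    padded = np.concatenate(([False], c, [False])).astype(np.int8)
    d = np.diff(padded)
    run_lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return float(run_lengths.mean() * frame_dt)


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling replica: harmonic bias and its samples.

    Bias potential ``u(x) = 0.5 * force_constant * (x - center)**2``,
    with the layout used for PAR dissociation: 16 equally spaced replicas
    over 0-16 nm at 10 kJ/mol/nm^2.
    """

    center: float  # nm
    force_constant: float = 10.0  # kJ/mol/nm^2
    samples: np.ndarray = None

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")

    def bias(self, x) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x, dtype=np.float64) - self.center) ** 2


@dataclass
class PMFProfile:
    """Potential of mean force on a binned reaction coordinate, kJ/mol."""

    bin_centers: np.ndarray
    pmf: np.ndarray  # kJ/mol, minimum at 0
    counts: np.ndarray  # pooled samples per bin
    window_free_energies: np.ndarray  # kJ/mol, per window
    n_iterations: int


def wham_pmf(windows: list[UmbrellaWindow], n_bins: int = 200,
             temperature: float = 300.0, tolerance: float = 1e-7,
             max_iterations: int = 100000) -> PMFProfile:
    """Weighted histogram analysis of umbrella-sampling windows.

    Standard self-consistent WHAM iteration: the unbiased probability on
    bin b and the per-window free-energy offsets f_i satisfy

        P(b) = sum_i H_ib / sum_i N_i exp[(f_i - u_i(x_b)) / kT]
        exp(-f_i / kT) = sum_b P(b) exp(-u_i(x_b) / kT)

    iterated until the largest change of any f_i falls below ``tolerance``
    (kJ/mol). The returned PMF is -kT ln P with its minimum shifted to 0.
    Fails loudly on non-overlapping windows or non-convergence.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    kT = KB_KJ_MOL_K * temperature

    # overlap diagnostic: sampled ranges of center-adjacent windows must touch
    order = np.argsort([w.center for w in windows])
    for i, j in zip(order[:-1], order[1:]):
        if windows[i].samples.max() < windows[j].samples.min():
            raise ValueError(
                "non-overlapping windows: samples of the window at "
                f"{windows[i].center} end ({windows[i].samples.max():.3f}) below the "
                f"start of the window at {windows[j].center} "
                f"({windows[j].samples.min():.3f})"
            )

    all_samples = np.concatenate([w.samples for w in windows])
    lo, hi = all_samples.min(), all_samples.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    H = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows]).astype(float)
    N = H.sum(axis=1)
    pooled = H.sum(axis=0)
    bias = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bins)
    boltz = np.exp(-bias / kT)

    f = np.zeros(len(windows))  # free-energy offsets, kJ/mol
    for it in range(1, max_iterations + 1):
        denom = (N * np.exp(f / kT)) @ boltz  # sum_i N_i exp((f_i - u_ib)/kT)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, pooled / denom, 0.0)
        z = boltz @ P  # exp(-f_i/kT)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge within {max_iterations} iterations "
            f"(last offset change {delta:.2e} kJ/mol)"
        )

    with np.errstate(divide="ignore"):
        pmf = -kT * np.log(np.where(P > 0, P, np.nan))
    pmf -= np.nanmin(pmf)
    return PMFProfile(
        bin_centers=centers, pmf=pmf, counts=pooled,
        window_free_energies=f, n_iterations=it,
    )
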