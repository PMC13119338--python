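"""End-to-end analysis: photon streams -> bursts -> (E, S) -> histograms ->
global fit -> two-state kinetics.

The functions here chain the module operations the way a measurement is
actually analyzed: burst search in the mode-appropriate settings,
correction and stoichiometry gating, one global shot-noise-constrained
histogram fit across all time points (shared peak positions), per-timepoint
compact fractions, and a weighted two-state kinetic fit of the decompacted
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstSearchParams, BurstTable, burst_qc, find_bursts
from .corrections import CorrectionSet, compute_fret_points, gate_stoichiometry
from .histogram import (
    EfficiencyHistogram,
    HistogramFitResult,
    build_histogram,
    fit_global,
    make_sigma_model,
)
from .kinetics import KineticFit, KineticSeries, fit_kinetics, segment_trace
from .stream import InstrumentSpec, PhotonStream


@dataclass
class PipelineResult:
    times: np.ndarray
    histograms: list[EfficiencyHistogram]
    hist_fit: HistogramFitResult
    series: KineticSeries
    kinetic_fit: KineticFit
    n_bursts: list[int] = field(default_factory=list)

    @property
    def k_obs(self) -> float:
        return self.kinetic_fit.k_obs


def _n_ref(values: np.ndarray, stat: str) -> float:
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v) & (v >= 1)]
    if v.size == 0:
        return 1.0
    return float(np.median(v) if stat == "median" else np.mean(v))


def bursts_to_fractions(
    burst_tables: list[BurstTable],
    times,
    corr: CorrectionSet,
    *,
    gate: tuple[float, float] = (0.2, 0.8),
    hist_bin_width: float = 0.025,
    e_range: tuple[float, float] = (-0.1, 1.1),
    n_ref_stat: str = "median",
    min_bursts: int = 3000,
    n_components: int = 2,
):
    """Shared tail of the pipeline from burst tables onward."""
    times = np.asarray(times, dtype=np.float64)
    histograms, gated_sizes = [], []
    n_dex_all, n_aa_all, dur_all = [], [], []
    for t, bursts in zip(times, burst_tables):
        burst_qc(bursts, min_bursts=min_bursts)
        points = gate_stoichiometry(compute_fret_points(bursts, corr), *gate)
        histograms.append(
            build_histogram(points["E"], hist_bin_width, e_range, timepoint=float(t))
        )
        gated_sizes.append(len(points))
        n_dex_all.append(points["n_dex"].to_numpy())
        n_aa_all.append(points["n_aa"].to_numpy())
        dur_all.append(points["duration"].to_numpy())

    n_ref = _n_ref(np.concatenate(n_dex_all), n_ref_stat)
    # peak widths: counting noise of the corrected E at the dataset's
    # typical acceptor-excitation signal and burst duration
    sigma_model = make_sigma_model(
        corr,
        n_aa_ref=float(np.median(np.concatenate(n_aa_all))) if gated_sizes else 0.0,
        duration_ref=float(np.median(np.concatenate(dur_all))) if gated_sizes else 0.0,
    )
    hist_fit = fit_global(histograms, n_ref=n_ref, n_components=n_components,
                          sigma_model=sigma_model)

    f_compact = hist_fit.fraction_compact_series
    f_dec = 1.0 - f_compact
    sigma = np.array(
        [hist_fit.fraction_sigma[tp] for tp in hist_fit.timepoints], dtype=np.float64
    )
    # binomial floor: the mixture-sampling shot noise of n gated bursts
    n_gated = np.maximum(np.asarray(gated_sizes, dtype=np.float64), 1.0)
    floor = np.sqrt(np.clip(f_dec * (1 - f_dec), 1e-4, None) / n_gated)
    sigma = np.where(np.isfinite(sigma), np.maximum(sigma, floor), floor)
    return histograms, hist_fit, f_dec, sigma, gated_sizes


def analyze_kinetic_series(
    streams: list[PhotonStream],
    times,
    instrument: InstrumentSpec,
    *,
    params: BurstSearchParams | None = None,
    corr: CorrectionSet | None = None,
    gate: tuple[float, float] = (0.2, 0.8),
    hist_bin_width: float = 0.025,
    e_range: tuple[float, float] = (-0.1, 1.1),
    n_ref_stat: str = "median",
    min_bursts: int = 3000,
    metadata: dict | None = None,
) -> PipelineResult:
    """Full droplet-mixer analysis of one kinetic series.

    One photon stream per reaction time point; returns the global
    histogram fit and the two-state kinetic fit of the decompacted
    fraction f_dec(t) = 1 - fraction_compact(t).
    """
    if params is None:
        params = BurstSearchParams.fast()
    if corr is None:
        corr = instrument.correction_set()
    burst_tables = [find_bursts(s, params, instrument) for s in streams]
    histograms, hist_fit, f_dec, sigma, n_bursts = bursts_to_fractions(
        burst_tables, times, corr, gate=gate, hist_bin_width=hist_bin_width,
        e_range=e_range, n_ref_stat=n_ref_stat, min_bursts=min_bursts,
    )
    series = KineticSeries(times=np.asarray(times, float),
                           f_dec=np.clip(f_dec, 0, 1), sigma=sigma,
                           metadata=metadata or {})
    fit = fit_kinetics(series)
    return PipelineResult(times=series.times, histograms=histograms,
                          hist_fit=hist_fit, series=series, kinetic_fit=fit,
                          n_bursts=n_bursts)


def analyze_slow_trace(
    stream: PhotonStream,
    instrument: InstrumentSpec,
    *,
    window: float = 60.0,
    dead_time: float = 5.0,
    corr: CorrectionSet | None = None,
    gate: tuple[float, float] = (0.2, 0.8),
    hist_bin_width: float = 0.025,
    e_range: tuple[float, float] = (-0.1, 1.1),
    n_ref_stat: str = "median",
    min_bursts: int = 1000,
    metadata: dict | None = None,
) -> PipelineResult:
    """Manual-mixing analysis: segment a long trace into one-minute windows,
    analyze each window as a time point (slow-mode burst search), and fit
    the two-state law with the mixing dead time added to window midpoints."""
    if corr is None:
        corr = instrument.correction_set()
    segments = segment_trace(stream, instrument, window=window)
    times = np.array([dead_time + mid for mid, _ in segments])
    burst_tables = [b for _, b in segments]
    histograms, hist_fit, f_dec, sigma, n_bursts = bursts_to_fractions(
        burst_tables, times, corr, gate=gate, hist_bin_width=hist_bin_width,
        e_range=e_range, n_ref_stat=n_ref_stat, min_bursts=min_bursts,
    )
    series = KineticSeries(times=times, f_dec=np.clip(f_dec, 0, 1), sigma=sigma,
                           metadata=metadata or {})
    fit = fit_kinetics(series)
    return PipelineResult(times=times, histograms=histograms, hist_fit=hist_fit,
                          series=series, kinetic_fit=fit, n_bursts=n_bursts)


def fit_population_peak(
    stream: PhotonStream,
    instrument: InstrumentSpec,
    *,
    params: BurstSearchParams | None = None,
    corr: CorrectionSet | None = None,
    gate: tuple[float, float] = (0.2, 0.8),
    hist_bin_width: float = 0.025,
    e_range: tuple[float, float] = (-0.1, 1.1),
    n_ref_stat: str = "median",
    n_components: int = 1,
    min_bursts: int = 3000,
) -> HistogramFitResult:
    """Burst-search one equilibrium stream, gate, and fit its histogram.

    With ``n_components=1`` this is the single-population peak fit used
    for free-DNA or low-salt samples; with 2 it is the standard
    two-population fit."""
    if params is None:
        params = BurstSearchParams.fast()
    if corr is None:
        corr = instrument.correction_set()
    bursts = burst_qc(find_bursts(stream, params, instrument), min_bursts)
    points = gate_stoichiometry(compute_fret_points(bursts, corr), *gate)
    hist = build_histogram(points["E"], hist_bin_width, e_range, timepoint=0.0)
    n_ref = _n_ref(points["n_dex"].to_numpy(), n_ref_stat)
    sigma_model = make_sigma_model(
        corr,
        n_aa_ref=float(points["n_aa"].median()) if len(points) else 0.0,
        duration_ref=float(points["duration"].median()) if len(points) else 0.0,
    )
    return fit_global([hist], n_ref=n_ref, n_components=n_components,
                      sigma_model=sigma_model)
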