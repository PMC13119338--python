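# Methods

This note documents the models, conventions and numerical choices behind
`parfret`, and what its synthetic validation does and does not establish.

## Signal model and correction chain

A burst is the photon cluster emitted by one molecule diffusing through
the confocal volume. Under pulsed interleaved excitation (PIE) the
acceptor pulse opens each 50 ns period (20 MHz repetition) and the donor
pulse follows ~25 ns later, so a photon's microtime assigns its exciting
laser: microtimes below the split (default 25 ns) are acceptor
excitation, at or above it donor excitation (half-open convention, shared
between analysis and generator). Three signal classes result: DD (donor
channel, donor excitation), DA (acceptor channel, donor excitation — the
FRET signal) and AA (acceptor channel, acceptor excitation — the
stoichiometry signal).

Corrected signals follow the accepted standard for PIE/ALEX data:

    F_DD = n_DD − bg_DD·T
    F_AA = n_AA − bg_AA·T
    F_DA = n_DA − bg_DA·T − α·F_DD − δ·F_AA

with burst duration T, leakage α (donor emission detected in the acceptor
channel), direct excitation δ referenced to the AA signal (the natural
choice for PIE data), and

    E = F_DA / (γ·F_DD + F_DA)
    S = (γ·F_DD + F_DA) / (γ·F_DD + F_DA + F_AA)

With α = δ = background = 0 and γ = 1 this reduces exactly to
E = n_A/(n_A + n_D). Defaults α = δ = 0.05, γ = 1, 1.5 kHz background per
detection channel are conventional confocal values; the calibrated values
of any particular instrument should be supplied via `CorrectionSet`.

**Clamping.** Background or crosstalk subtraction can push a corrected
count below zero. For reported counts and for S (which must stay in
[0, 1]) negative values are clipped to zero and flagged, and the burst is
kept (dropping bursts would bias population fractions). For E, however,
the *unclamped* signals are used: per-burst corrected efficiencies
legitimately scatter slightly below 0 (and above 1) by shot noise, and
truncation would pile low-E bursts up at exactly E = 0, skewing the low
peak and the fractions derived from it by up to ~0.08. The histogram axis
therefore extends over E ∈ [−0.1, 1.1].

## Burst search

Fixed bins anchored at t = 0 of the stream (half-open, [k·w, (k+1)·w)); a
bin is hot when its total photon count across all channels and windows
reaches the threshold; maximal runs of hot bins merge into one burst with
the run's outer bin edges as boundaries. Two parameter sets are used:
40 photons per 500 µs bin (fast, droplet mixer) and 60 photons per 1 ms
bin (slow, manual mixing). A sliding-window (Lee-filter style) search is
deliberately not implemented; fixed binning is what the measurement
protocol uses. Timestamps are integer clock ticks (default 10 ns
resolution) so binning is exact.

## Histogram fitting

Transfer-efficiency histograms (default bin width 0.025) from all time
points of a series are fitted globally with two Gaussian peak functions.
Shared parameters: the two peak positions (ordered by construction,
μ_high = μ_low + Δμ with Δμ ≥ 0.02). Free per histogram: the two peak
areas (non-negative). Fixed: the peak widths, pinned to the counting-
statistics expectation.

For distortion-free data that width is the binomial shot-noise width
σ = √(E(1−E)/N) with N the reference donor-excitation photon count per
burst (dataset median by default; configurable). For corrected data the
Poisson noise of the subtracted background, leakage and direct-excitation
terms propagates into E; first-order propagation through the correction
chain gives the broadened width implemented in
`corrected_shot_noise_sigma`, which reduces exactly to the binomial form
when the distortions vanish. The pipeline uses the broadened form
(evaluated at the dataset's median AA signal and burst duration); using
the bare binomial width with nonzero α, δ and background underestimates
the low-E peak width by up to ~1.8× and biases mixture fractions.

The model is bin-integrated (Gaussian mass per bin via the normal CDF,
not the density at bin centers), keeping narrow peaks unbiased when σ is
comparable to the bin width. Residuals carry Poisson-approximate weights
√max(count, 1). Initial positions are the two most prominent modes of the
pooled histogram (deterministic; tie-broken by ordering), with a fixed
offset fallback when the pooled data show a single mode. The compact
fraction at each time point is the fractional area of the high-E peak,
area_high/(area_high + area_low); reported amplitudes are peak heights,
so the equivalent height·σ ratio gives the same fraction. Fraction
uncertainties come from the delta method on the fitted area covariance,
floored by the mixture-sampling binomial error √(f(1−f)/n_bursts).

A one-component variant serves single-population samples (free DNA,
low-ionic-strength nucleosomes). Applying the two-component fit to
strictly single-population data drives one area to ~0; its position is
then unconstrained, which is why single-population analyses should use
the one-component fit.

## Kinetics

Under pseudo-first-order conditions (PAR in large excess over the ~100 pM
nucleosome) the compact ⇌ decompacted relaxation is a single exponential:

    f_dec(t) = f_inf − (f_inf − f0)·exp(−k_obs·t)

the unique monotone two-state law with initial fraction f0 and
equilibrium fraction f_inf. k_obs is reported as observed, without
decomposition into k_on·[PAR] + k_off. The fit is weighted least squares
(weights from the per-timepoint fraction uncertainties), bounded
(k_obs ≥ 0, fractions in [0, 1]), with standard errors from the scaled
covariance and 95% intervals using the Student-t quantile at n − 3
degrees of freedom — with typically 8 time points the normal quantile
noticeably undercovers. A series with no variation returns k_obs = 0 with
a flag instead of failing.

Droplet-mixer series map measurement positions to times via
t = dead_time + position/velocity (velocity default 0.6 mm/s; positions
up to ~36 mm give reaction times up to ~60 s). Manual-mixing traces are
segmented into consecutive one-minute windows (midpoint = window time,
plus the ~5 s mixing dead time); each window is burst-searched in slow
mode and enters the same global histogram fit. Trailing partial windows
are dropped with a notice.

## Synthetic photon streams

The generator is the exact inverse of the correction chain: a species is
defined by its true corrected efficiency and its median corrected
brightness under donor and acceptor excitation; the instrument's α, δ, γ
and background are applied forward, and channel counts are drawn Poisson
around the distorted expectations. Conditional on the burst total, the
DD/DA split is then binomial, so the distortion-free per-burst estimator
n_DA/(n_DA+n_DD) is exactly unbiased — the property the round-trip tests
check.

Realism choices (these shape count statistics only — no optics, no
point-spread function, no droplet hydrodynamics):

* burst size: lognormal around the brightness (σ_ln = 0.45), emulating
  trajectory-to-trajectory variation of diffusive transits;
* burst duration: lognormal around 0.5 ms (σ_ln = 0.3); photons uniform
  within the burst envelope;
* arrivals: Poisson (exponential gaps), default 100 bursts/s in droplet
  mode and 16.7 bursts/s in manual mode (~1000 bursts per one-minute
  window over a 20-minute trace);
* background: uniform in time and over the PIE period, 1.5 kHz per
  detection channel, so the effective DD/DA/AA background rates follow
  from the window fractions;
* contaminants: a constant 15% donor-only fraction (S ≈ 1, removed by
  the stoichiometry gate);
* species truths: compact 0.36, decompacted 0.053, free DNA 0.035,
  low-salt nucleosome 0.089; kinetic series default f0 = 0.1,
  f_inf = 0.9 (the initial and equilibrium decompacted fractions are not
  separately specified by the reference measurements; these values
  reproduce a mostly-compact start and mostly-open equilibrium).

One seeded `numpy` generator drives all draws; a fixed seed gives
bit-identical streams, and ground truth (per-burst labels, realized
fractions) is returned alongside and written to sidecar files.

What the generator does **not** emulate: brightness differences between
species (compact and decompacted are equally bright, so threshold
selection cannot bias fractions — in real data a brightness contrast
would), diffusion-time/burst-duration correlations, photophysics
(blinking, bleaching within a burst), multi-molecule coincidence beyond
random arrival overlap, and polarization. Passing recovery tests
therefore validates the analysis chain under its own statistical
assumptions, not instrument-specific systematics.

## Trajectory-side analysis

* Förster conversion uses the standard sixth-power law
  E(r) = 1/(1 + (r/R0)⁶), R0 = 5.4 nm for the Alexa 488/594 pair.
  Ensemble efficiencies are averages of per-frame E (dye dynamics fast on
  the photon timescale), not E of the mean distance.
* Contacts: bead pairs strictly closer than 1.2 nm; the boundary has zero
  measure, the convention is fixed and tested.
* Contact lifetimes: mean length of maximal runs of continuous contact,
  boundary-touching runs included.
* WHAM: standard self-consistent iteration over window free-energy
  offsets (tolerance 1e−7 kJ/mol on the offsets, cap 100 000 iterations;
  failure is loud, including a non-overlap diagnostic). Defaults: 200
  bins over the sampled range, 300 K. Validated against an analytic
  harmonic potential sampled exactly under the 16-window /
  10 kJ mol⁻¹ nm⁻² umbrella layout; with 8000 samples per window the
  recovered profile agrees within 0.5 kJ/mol over the well-sampled range
  (the residual is dominated by the √N random walk of the chained window
  offsets).

## Problem sizes in the test suite

Recovery tests use 3000 generated bursts per time point (8 log-spaced
points from 0.01 to 20 s), 10–24k bursts for peak-position recovery, and
a 20-minute slow trace at 16.7 bursts/s; the kinetic recovery grid runs
20 replicates of the full pipeline per (k_obs, f_inf) cell. These match
the burst counts the measurement protocol itself prescribes (≥3000 per
fast time point, ~1000 per slow window).

## Known limitations

* The Gaussian peak model ignores the residual skew of the low-E peak
  (Poisson asymmetry at ~5 FRET photons per burst); positions remain
  accurate to ≲0.005 but a full photon-distribution analysis would model
  the shape exactly.
* Fractions from the global fit assume both species share the reference
  burst-size statistic N_ref.
* The CLI's `fit-hist` treats each FRET-point table as one time point; it
  does not parse time metadata from file names.
* WHAM assumes uncorrelated samples; autocorrelated trajectory data
  should be subsampled upstream.
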