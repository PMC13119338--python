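# parfret

Single-molecule FRET burst analysis and two-state kinetics for
poly(ADP-ribose)-induced nucleosome decompaction.

## The problem

Nucleosomes — DNA wrapped around a histone octamer — are opened up
("decompacted") by poly(ADP-ribose) (PAR), the highly charged polymer that
PARP1 synthesizes at DNA damage sites. The kinetics of this process can be
resolved by confocal single-molecule FRET on freely diffusing nucleosomes
whose linker-DNA termini carry a donor/acceptor dye pair: compact
nucleosomes show high transfer efficiency (⟨E⟩ ≈ 0.36), decompacted ones
low efficiency (⟨E⟩ ≈ 0.053). Fast kinetics are measured in a droplet
microfluidic mixer (positions along the observation channel map to
reaction times via the droplet velocity, ~0.6 mm/s); slow kinetics by
manual mixing and segmenting a long recording into one-minute windows.

`parfret` implements the complete analysis chain for such measurements,
plus a synthetic photon-stream generator for validation and a small
trajectory-analysis companion (Förster efficiencies, contacts, WHAM
potentials of mean force) for coarse-grained simulation output.

## The analysis

1. **Burst search** — photons are binned at fixed width (500 µs fast mode /
   1 ms slow mode); bins with ≥ 40 (fast) or ≥ 60 (slow) photons are hot,
   and consecutive hot bins merge into one burst.
2. **Corrections** — per burst, background, donor→acceptor leakage (α),
   acceptor direct excitation (δ) and the γ factor yield corrected signals,
   from which

   E = F_DA / (γ·F_DD + F_DA),  S = (γ·F_DD + F_DA) / (γ·F_DD + F_DA + F_AA)

   Pulsed interleaved excitation (20 MHz, ~25 ns inter-pulse delay)
   assigns each photon to its excitation window; the stoichiometry gate
   (0.2 < S < 0.8, or 0.25 < S < 0.75) removes donor-only and
   acceptor-only molecules.
3. **Global histogram fit** — transfer-efficiency histograms of all time
   points are fitted together with two Gaussian peaks; positions are
   shared, widths are pinned to the counting-statistics (shot-noise)
   expectation σ(E, N), and only per-timepoint areas are free. The compact
   fraction is the fractional area of the high-E peak.
4. **Kinetics** — the decompacted fraction follows the pseudo-first-order
   two-state law f(t) = f_inf − (f_inf − f0)·e^(−k_obs·t), fitted by
   weighted least squares with Student-t confidence intervals.

## Worked example

```python
import numpy as np
import parfret as pf

instrument = pf.InstrumentSpec()                 # 20 MHz PIE, standard distortions
course = pf.MixtureTimeCourse(k_obs=0.42, f0=0.1, f_inf=0.9,
                              times=np.geomspace(0.01, 20, 8))
streams, truth = pf.simulate_kinetic_series(course, instrument,
                                            bursts_per_timepoint=3000, rng=1)
result = pf.analyze_kinetic_series(streams, course.times, instrument,
                                   min_bursts=1000)
print(f"k_obs = {result.k_obs:.3f} /s")
print(f"peaks: compact {result.hist_fit.mu_high:.3f}, "
      f"decompacted {result.hist_fit.mu_low:.3f}")
print("f_dec(t) =", np.round(result.series.f_dec, 3))
```

prints

```
k_obs = 0.399 /s
peaks: compact 0.358, decompacted 0.052
f_dec(t) = [0.106 0.115 0.133 0.168 0.316 0.586 0.86  0.908]
```

i.e. from two million synthetic photons the pipeline recovers the
generator's 0.42 s⁻¹ decompaction rate within its uncertainty, the two
peak positions within 0.01, and the time course of the decompacted
fraction.

The same pipeline is available from the shell:

```sh
parfret run-all --seed 1 --out results/demo       # simulate + analyze
parfret --show-config                             # measurement defaults
```

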