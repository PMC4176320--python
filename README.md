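# rcr-kinetics

Kinetics of template switching in rolling circle amplification (RCA).

A strand-displacing polymerase such as phi29 traversing a nicked circular
template should, on paper, produce only long single-stranded concatamers.
In practice RCA reactions accumulate mostly *double-stranded* DNA unless
single-stranded-binding (SSB) protein is added. This package implements a
kinetic model that explains the conversion: at a random time the polymerase
*switches* from the circle onto the strand it has displaced and fills it in
to duplex form, terminating when the fill-in catches up with the point of
initiation. SSB coating the displaced strand blocks the switch.

It is a library for anyone modeling, simulating or fitting RCA time
courses: the closed-form ss/dsDNA mass curves, an exact per-template
stochastic simulator, a synthetic generator for the two-channel gel
densitometry readout, and a Levenberg–Marquardt fitter for the switching
rate.

## Model

Switch times are exponential with rate constant λ (events s⁻¹ template⁻¹),
so the switched fraction follows the CDF `1 − e^{−λt}`. A template that
switches at time τ terminates at 2τ (equal polymerase rate on both
strands), and each consumed nucleotide of ssDNA pairs with one incorporated
nucleotide, doubling the mass that appears as duplex. With amplitude
`A = 2 n₀ φ` (initial template concentration × elongation rate × 2 — the
single identifiable production-scale parameter), the population masses are

    N_ds(t) = (A/λ) (1 − e^{−λt/2})²
    N_ss(t) = (A/λ) e^{−λt/2} (1 − e^{−λt/2})
    N_ss + N_ds = (A/λ) (1 − e^{−λt/2})

ssDNA peaks at `t* = 2 ln2 / λ` and decays to zero; dsDNA saturates at the
termination plateau `A/λ`. At the fitted rate λ = 1.95 × 10⁻⁵ s⁻¹ the
template half-life before switching is `ln2/λ` = 35,546 s ≈ 9.9 h and the
ssDNA peak falls at ≈ 19.7 h.

## Worked example

`examples/generate_and_fit.py` generates one noisy synthetic time course
at a 9.9 h half-life (10% multiplicative channel noise, ssDNA obtained by
subtracting the agarose ds channel from the denaturing-PAGE total channel)
and fits the switching rate from the ssDNA points alone:

```
true  lam = 1.945e-05 /s  (half-life 9.9 h)
fitted lam = 1.622e-05 +/- 5.6e-06 /s  (half-life 11.9 h)
fitted amplitude = 7.611e-04 mass units/s
converged: True in 13 evaluations
```

The single noisy replicate recovers the rate within its reported
uncertainty; the dsDNA curve predicted from the same fitted pair (never
itself fitted) tracks the ds observations, which is the model-adequacy
check. `examples/recovery_study.py` repeats this 50 times and prints the
ensemble statistics:

```
"mean_lam_hat_per_s": 1.9192856292628555e-05,
"relative_bias": -0.013148408514482061,
"coverage_2sd": 0.9,
```

i.e. the ss-only fit is unbiased for the rate (−1.3% bias) and the robust
±2 sd intervals cover the truth in ~90% of replicates. The other examples
print the closed-form curves and the simulator-versus-theory comparison.

A thin CLI wraps the same pipeline for shell use:

```sh
rcr generate --seed 1 -o run.csv
rcr fit run.csv -o fit.json --prediction-csv curves.csv
rcr validate --n-templates 100000
rcr recover --half-life-h 9.9 --n-replicates 50
```

## Layout

- `src/rcr/model.py` — closed forms, derived quantities, `predict`
- `src/rcr/simulator.py` — per-template event-driven Monte Carlo
- `src/rcr/synth.py` — two-channel synthetic densitometry generator
- `src/rcr/fitting.py` — LM estimation of (λ, A) with robust uncertainty
- `src/rcr/experiments.py` — simulator validation and recovery pipelines
- `src/rcr/io.py`, `src/rcr/cli.py` — CSV dialect and the `rcr` CLI
- `docs/methods.md` — model assumptions, noise model, numerical choices
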