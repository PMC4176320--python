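# Methods

## The switching model

The model describes a fixed pool of `n0` nicked circular templates, each
carrying one strand-displacing polymerase that elongates at a constant
rate `phi` (mass units per second per template). Three assumptions carry
all of the structure:

1. **Exponential switching.** Each polymerase leaves its circle for the
   displaced strand after an exponentially distributed waiting time with
   hazard `lam` (events s⁻¹ template⁻¹). Switching is irreversible and
   happens at most once per template — this is what makes the switched
   fraction a single-exponential CDF; no switch-back or re-priming is
   modeled.
2. **Equal rate on both strands.** The polymerase elongates at the same
   `phi` during strand displacement and during fill-in, so a template that
   switches at time `tau` terminates at exactly `2*tau`, when the fill-in
   reaches the initiation point and the polymerase falls off. No new
   polymerase loads afterwards.
3. **Mass doubling on fill-in.** Converting one nucleotide of displaced
   ssDNA to duplex incorporates one new nucleotide, so duplex mass grows
   at `2*phi` per filling template and a terminated template has produced
   `2*phi*tau` mass units of dsDNA.

Integrating the per-template bookkeeping over the switch-time distribution
gives the population masses in terms of `A = 2*n0*phi`:

    N_ds(t) = (A/lam) (1 - e^{-lam t/2})^2
    N_ss(t) = (A/lam) e^{-lam t/2} (1 - e^{-lam t/2})

Only the product `n0*phi` is identifiable from mass data, so the public
parameterization is `(lam, amplitude)`; `n0` and `phi` are accepted as
metadata through a convenience constructor. SSB protein is modeled as
binary switching suppression (`lam = 0` / switch times at infinity), not
as a binding isotherm; sub-saturating SSB is out of scope.

The ssDNA expression above is the form forced by the rate balance
(ss production = total production − ds production) and by the requirement
that `N_ss` stay non-negative and decay to zero; a published version of
this expression circulates with a sign error in the second exponent that
makes it diverge, and the corrected form is what this package implements.

Derived quantities: template half-life before switching `ln2/lam`
(35,546 s ≈ 9.87 h at the reference rate 1.95e-5 s⁻¹, conventionally
rounded to 9.9 h), ssDNA peak time `2 ln2/lam` (≈19.7 h), termination
plateau `A/lam`.

## Units

Seconds and per-second throughout the library; hours at the file/CLI
interface, converted explicitly. Mass units are arbitrary (gel band
intensity or ng/µl) — the amplitude carries the scale, and every fitted
quantity except `amplitude` is scale-free.

## Numerical choices

The closed forms all carry a `1/lam` prefactor with a removable
singularity at `lam = 0`. They are evaluated through `expm1`, which is
cancellation-free for every `lam*t > 0`; only `lam == 0` itself takes the
analytic-limit branch (`N_ss = A t/2`, `N_ds = 0`). The small-rate limits
are verified in the tests at `lam = 1e-12` against `n0*phi*t` and
`n0*phi*lam*t²/2`.

The simulator draws all switch times from one seeded generator in
template-index order, so results are reproducible and independent of the
query-time layout; evaluation at the query times is exact given the drawn
times (no time stepping). Circle length never enters: templates are
treated as infinite-processivity concatamer producers, as the closed
forms assume.

## Synthetic data

The generator emulates the two-channel gel workflow used to quantify real
reactions: a "denaturing PAGE" channel observing `N_ss + N_ds`, an
"agarose" channel observing `N_ds`, and ssDNA computed by subtraction,
then floored at zero (subtraction first, flooring second). Each channel
is corrupted independently with multiplicative lognormal noise of mean 1
(default CV 0.10, typical of densitometry) plus additive Gaussian
background (default 1% of the plateau in the experiment pipelines).
Defaults for the study conditions: 11 sampling times at 1, 3, 6, 9, 12,
16, 20, 24, 36, 48, 72 h, plateau scaled to 50 ng/µl, truth taken from a
stochastic population of 10,000 templates.

What this does *not* emulate: gel images themselves, digestion-fragment
length distributions, ethidium-bromide ss/ds staining bias (the ds channel
is defined as unbiased, as in the denaturing-PAGE-corrected
quantification), pipetting or lane-loading correlations between channels,
and any SSB dose–response. Passing the recovery tests therefore shows the
estimator is sound under this noise law, not that real gels obey it.

A structural feature the generator does reproduce: at late times the true
ssDNA signal is near zero while both channels remain noisy, so the
subtraction-derived ssDNA points have mean ≈ 0 with inflated variance —
the late points are the least reliable ones entering the fit.

## Fitting

`(log lam, log A)` are estimated by Levenberg–Marquardt (scipy
`least_squares`, analytic Jacobians) on the ssDNA points only, matching
how such data are fitted in practice; the dsDNA curve is then predicted
from the same pair as a model check. Joint ss+ds fitting is available as
a sensitivity option. Log parameterization enforces positivity without
constrained solvers; weights are uniform by default (a relative-error
option exists). The starting point inverts the peak relation
`t* = 2 ln2/lam` at the observed ssDNA maximum, falling back to
`lam0 = ln2/median(t)` when the maximum sits on the grid boundary (the
no-switching regime). Convergence tolerances default to 1e-12; points at
`t = 0` are retained (exactly fit by construction).

**Uncertainty.** The reported standard deviations are HC3
heteroscedasticity-robust (leverage-corrected sandwich) asymptotic errors,
delta-transformed from the log scale, and intervals are multiplicative
(symmetric in `log lam`). The classical homoskedastic `s²(JᵀJ)⁻¹` form is
available via `FitConfig(uncertainty="homoskedastic")` but is knowingly
anti-conservative here: the subtraction channel's noise variance grows
with the *total* signal while the ssDNA signal shrinks, and under the
default scenario the homoskedastic ±2 sd intervals cover the truth in only
~72% of replicates versus ~89–90% for HC3. A wild bootstrap was evaluated
and rejected (coverage ~0.76–0.80, narrower than HC3).

**Achievable precision.** Under the default scenario (11 points, CV 0.10,
50 replicates) the ss-only fit recovers the rate with ≈1–5% bias and
≈23–25% relative RMSE. That dispersion is a property of the scenario, not
the optimizer: re-fitting the same replicates weighted by the *true*
per-point noise sd — the information-theoretic best case — still gives
18.6% RMSE, because the late-time ssDNA points carry almost no signal.

## Problem sizes

The test suite and pipelines use populations of 10³–10⁵ templates,
10⁵–10⁶ Monte-Carlo draws for distributional oracles, and 50-replicate
recovery ensembles; the full suite runs in a few seconds. These sizes put
Monte-Carlo standard errors well below the tolerances being asserted
(population means sit within 3 SE bands at n = 10⁵).

## Known limitations

- Binary SSB semantics; no dose–response.
- No nucleotide-pool depletion: termination is purely geometric (fill-in
  catching up), so the plateau reflects switching alone.
- One switching event per template; the alternative hairpin "double-back"
  duplex-formation mechanism is not modeled.
- The noise law is a modeling choice; real densitometry may have
  channel-correlated errors the generator deliberately omits.
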