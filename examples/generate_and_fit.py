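"""Generate one noisy synthetic time course and fit the switching rate.

Emulates the two-channel gel quantification (total DNA from denaturing
PAGE, dsDNA from agarose; ssDNA by subtraction) at 10% multiplicative
channel noise, then runs the ss-only Levenberg-Marquardt fit and predicts
the withheld dsDNA curve from the same fitted parameter pair.
"""

import math

from rcr import FitConfig, ModelParams, NoiseModel, fit, generate, predict_with_fit

lam_true = math.log(2) / (9.9 * 3600.0)  # 9.9 h half-life
params = ModelParams(lam=lam_true, amplitude=50.0 * lam_true)

table = generate(params, noise=NoiseModel(cv_multiplicative=0.10, seed=42))
result = fit(table, FitConfig(channels="ss_only"))

print(f"true  lam = {lam_true:.3e} /s  (half-life {9.9:.1f} h)")
print(f"fitted lam = {result.lam_hat:.3e} +/- {result.lam_sd:.1e} /s"
      f"  (half-life {result.half_life_h:.1f} h)")
print(f"fitted amplitude = {result.amplitude_hat:.3e} mass units/s")
print(f"converged: {result.converged} in {result.n_iter} evaluations")

pred = predict_with_fit(result, table.times_s)
print()
print("time_h   ds_observed   ds_predicted")
for h, obs, mod in zip(table.times_h, table.ds_dna, pred.ds_mass):
    print(f"{h:6.1f} {obs:12.2f} {mod:14.2f}")
print()
print("The ds curve was never fitted: it follows from the ss-only estimate,")
print("so tracking the ds observations is a genuine model check.")
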