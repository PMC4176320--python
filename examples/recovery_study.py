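"""Replicate-level recovery of the switching rate from synthetic data.

Runs 50 independent generate-corrupt-fit replicates at the study
conditions (9.9 h half-life, 10^4 simulated templates, 11 sampling times
over 1-72 h, 10% channel noise) and summarizes bias, dispersion and the
calibration of the reported +/- 2 sd intervals.
"""

import json

from rcr import recovery_experiment

report = recovery_experiment(n_replicates=50, seed=0)
print(json.dumps(report.summary(), indent=2))
print()
print("relative_bias near zero means the ss-only fit is unbiased for the")
print("rate; coverage_2sd near 0.9-0.95 means the robust standard errors")
print("are honestly calibrated under the heteroscedastic subtraction noise.")
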