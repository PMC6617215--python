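"""Validate the pipeline on synthetic cohorts with known truth.

Two canned experiments:
* parameter recovery — simulate under the exponential shape and check the
  fitted slope's sign and spread;
* discrimination — run the full posterior assessment on cohorts simulated
  under a dose-responsive truth and under a flat truth.
"""

from esynthesis import (
    SyntheticConfig,
    discrimination_experiment,
    parameter_recovery_experiment,
)

DOSES = (0.0, 10.0, 31.67, 60.0, 86.67)
SIZES = (137_568, 99_922, 32_077, 10_656, 17_059)
THETA = (1.01266e-3, 4.17805e-3)  # published exponential parameters

recovery = parameter_recovery_experiment(
    SyntheticConfig("exponential", THETA, DOSES, (100_000,) * 5, seed=11, replicates=200)
)
print("parameter recovery (exponential truth, n_i = 1e5, 200 replicates):")
print(f"  converged          : {recovery['n_converged']}/{recovery['replicates']}")
print(f"  slope sign correct : {recovery['sign_recovery_beta']:.1%}")
print(f"  bias (alpha, beta) : {recovery['bias'][0]:+.2e}, {recovery['bias'][1]:+.2e}")
print(f"  rmse (alpha, beta) : {recovery['rmse'][0]:.2e}, {recovery['rmse'][1]:.2e}")

report = discrimination_experiment(
    SyntheticConfig("exponential", THETA, DOSES, SIZES, seed=101, replicates=200),
    SyntheticConfig("constant", (1.195e-3,), DOSES, SIZES, seed=102, replicates=200),
    prior=0.5,
)
print("\ndiscrimination at prior 0.5 (200 replicates each):")
for key in ("dr_truth", "flat_truth"):
    r = report[key]
    print(f"  {r['truth']:<12} mean posterior {r['mean_posterior']:.3f}   "
          f"fraction > 0.5: {r['fraction_above_half']:.2f}")

# Under the dose-responsive truth the posterior is near 1 in almost every
# replicate.  Under the flat truth it stays well below that but not below
# the prior on average: the fitted dose-response model nests the constant
# null, so its plug-in likelihood is anti-conservative.  The trend test,
# reported alongside every assessment, is the guard for that case.
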