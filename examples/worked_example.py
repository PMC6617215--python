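"""Reproduce the paracetamol-asthma dose-response analysis end to end.

Builds nothing: the five-group cohort table ships with the package.
Computes the flat-model ("no dose-response") likelihood, the exponential
dose-response likelihood at the published parameters, and the posterior
probability of dose-responsiveness at the equipoise prior 0.5.
"""

from esynthesis import reproduce_paracetamol_example

report = reproduce_paracetamol_example()

print(f"flat-model rate k~            = {report.k_tilde:.4e}")
print(f"ln P(data | no dose-response) = {report.loglik_null:.4f}")
print(f"   P(data | no dose-response) = {report.lik_null:.3e}")
print(f"ln P(data | exponential DR)   = {report.loglik_exp:.4f}")
print(f"   P(data | exponential DR)   = {report.lik_exp:.3e}")
print(f"P(DR | data) at prior 0.5     = {report.posterior_at_half:.5f}"
      f"  (displays as {report.posterior_at_half_rounded:.2f})")
print()
print("comparison with the published values:")
for entry in report.comparison:
    line = (f"  {entry['quantity']:26s} computed {entry['computed']:.6g}"
            f"  reference {entry['reference']:.6g}"
            f"  |dev| {entry['abs_deviation']:.2g}")
    if "note" in entry:
        line += "  [flagged]"
    print(line)

# The log Bayes factor of ~7.3 nats means the dose-responsive model explains
# the observed counts ~1400 times better than a constant rate, which at an
# even prior pushes the posterior to ~0.999.
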