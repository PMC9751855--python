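"""Calibrate the synthetic generator to published impairment rates,
generate a cohort at the study's group sizes, and classify it.

Prints the per-domain impairment rates of the generated cohort next to the
calibration targets: with 56 + 37 children the empirical rates scatter
around the targets with binomial noise, which is exactly the sampling
situation the downstream statistics face.
"""

from comorbmap import (
    Group, build_impairment_matrix, calibrate_loadings, generate_cohort,
)
from comorbmap.reference import reference_rates

targets = reference_rates()
calibration = calibrate_loadings(targets)
print(f"latent shift between groups: {calibration.latent_shift:.3f} SD")
print(f"Touwen per-domain base rate: {calibration.touwen_base_rate:.4f}, "
      f"probit slope: {calibration.loadings['MND']:.3f}\n")

config = calibration.to_config(seed=1)  # defaults: 56 EPT + 37 term-born
cohort = generate_cohort(config)
matrix = build_impairment_matrix(cohort)

ept, term = matrix.rates(Group.EPT), matrix.rates(Group.TERM)
print(f"{'domain':8} {'EPT rate':>9} {'target':>7}   {'term rate':>9} {'target':>7}")
for domain, (te, tt) in targets.items():
    print(f"{domain:8} {ept[domain]:9.2f} {te:7.2f}   {term[domain]:9.2f} {tt:7.2f}")
print("\nEach row is one test domain; rates are fractions of assessed "
      "children classified impaired (>1 SD below norms).")
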