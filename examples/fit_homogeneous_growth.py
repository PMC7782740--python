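"""Fit the logistic growth model to synthetic homogeneous spheroid curves.

Generates 12 noisy PC3-parental growth curves (daily volumes to day 15,
5% multiplicative noise), fits (r, K, V0) by least squares on log volume
and prints the estimates with parametric-bootstrap 95% CIs.  The recovered
values should bracket the generating parameters r=0.293 day^-1,
K=0.843 mm^3, V0=0.040 mm^3.
"""

import ecospheroid as es
from ecospheroid import presets

truth = presets.PC3_PARENTAL
curves = es.gen_homogeneous(truth, es.SamplingDesign(),
                            es.NoiseModel(cv=0.05, seed=1),
                            group="pc3_parental")
fit = es.fit_logistic(curves, n_boot=200, seed=1)

print(f"generating parameters: r={truth.r} /day, K={truth.K} mm^3, "
      f"V0={truth.V0} mm^3")
for name, unit in (("r", "/day"), ("K", "mm^3"), ("V0", "mm^3")):
    est = fit.estimates[name]
    lo, hi = fit.ci_lower[name], fit.ci_upper[name]
    print(f"  {name:>2} = {est:.3f} {unit}  (95% CI {lo:.3f}-{hi:.3f})")
print("The CIs quantify how precisely 12 spheroids at 5% measurement "
      "noise pin down each growth parameter.")
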