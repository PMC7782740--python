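"""Infer the ecological interaction type of a mixed spheroid culture.

Simulates a mixed PC3 parental/radioresistant experiment with known
competitive couplings (lambda_P = lambda_RR = 0.5), then fits the
Lotka-Volterra model twice: from total volumes plus population
proportions, and from volumes alone.  The comparison shows why sparse
proportion measurements (flow-cytometry style, days 5/10/15) are needed
to identify the couplings.
"""

import ecospheroid as es
from ecospheroid import presets

truth = presets.pc3_mixed_params(lambda_P=0.5, lambda_RR=0.5)
fixed = (truth.parental, truth.radioresistant)
curves, props = es.gen_mixed(truth, es.SamplingDesign(),
                             es.NoiseModel(cv=0.05, seed=7))

both = es.fit_lotka_volterra(curves, props, fixed=fixed, n_boot=200, seed=7)
vol = es.fit_lotka_volterra(curves, None, fixed=fixed, n_boot=200, seed=7)

cls = es.classify_interaction(both.estimates["lambda_P"],
                              both.estimates["lambda_RR"])
print(f"true couplings: lambda_P = lambda_RR = 0.5 (competition)")
for name in ("lambda_P", "lambda_RR"):
    print(f"  volumes+proportions: {name} = {both.estimates[name]:+.3f} "
          f"(CI width {both.ci_width(name):.2f}); "
          f"volumes only: {vol.estimates[name]:+.3f} "
          f"(CI width {vol.ci_width(name):.2f})")
print(f"inferred interaction class: {cls.value}")
print("Volume-only CIs are several times wider: the couplings are only "
      "weakly identified without knowing the population composition.")
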