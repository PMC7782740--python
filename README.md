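# ecospheroid

Ecological modelling of mixed radiosensitive/radioresistant tumour-cell
populations in 3D spheroid culture, for quantitative radiation biologists
and mathematical oncologists. The package provides, as a tested library
with a thin command-line layer:

- **Growth models.** Logistic growth of homogeneous spheroids,
  dV/dt = rV(1 − V/K), with its closed-form solution, and a two-population
  Lotka–Volterra model of mixed parental (P) / radioresistant (RR)
  spheroids,

  ```
  dV_P/dt  = r_P  V_P  (1 − V_P/K_P  − λ_RR V_RR/K_P)
  dV_RR/dt = r_RR V_RR (1 − V_RR/K_RR − λ_P  V_P/K_RR)
  ```

  The signs of the couplings classify the ecological interaction:
  λ_P > 0 and λ_RR > 0 is competition, both negative is mutualism, and
  opposite signs antagonism.
- **Inference.** Least-squares fits of (r, K, V0) to homogeneous growth
  curves and of (λ_P, λ_RR, V_P0, V_RR0) to mixed total-volume curves
  plus sparse flow-cytometry-style proportion measurements, with
  multi-start optimisation, parametric-bootstrap CIs, and a Monte-Carlo
  identifiability study across noise levels and data modes.
- **Radiation response.** Linear-quadratic kill SF(d) = exp(−αd − βd²)
  applied per population, regrowth-time computation (grow to a trigger
  volume, irradiate, follow to an endpoint volume) and regrowth-time
  landscapes over the (λ_P, λ_RR) plane; growth-delay endpoint utilities.
- **Spatial model.** A hybrid cellular automaton of a 2D spheroid
  cross-section: two phenotypes on a lattice coupled to a quasi-steady
  oxygen reaction–diffusion field, reproducing peripheral accumulation of
  the radioresistant population and logistic-like homogeneous growth
  curves.
- **Synthetic data.** Generators for all of the above with the noise
  structure of the lab pipeline (multiplicative volume error, additive
  proportion error), so every stage is testable without external data.

## Worked example

Infer the interaction type of a mixed PC3 culture from synthetic data
with known competitive couplings:

```sh
python examples/infer_interactions.py
```

```
true couplings: lambda_P = lambda_RR = 0.5 (competition)
  volumes+proportions: lambda_P = +0.494 (CI width 0.27); volumes only: +0.828 (CI width 1.44)
  volumes+proportions: lambda_RR = +0.479 (CI width 0.11); volumes only: +0.289 (CI width 2.24)
inferred interaction class: competition
```

Both couplings are recovered near their true value 0.5 when total-volume
curves are supplemented with proportion measurements at days 5/10/15, and
the sign pattern classifies the interaction as competition; fitting
volumes alone leaves the couplings nearly unidentified (CIs an order of
magnitude wider). The other scripts in `examples/` demonstrate logistic
fitting, regrowth after 6 Gy by interaction type, the noise-level
identifiability study, and the CA model's emergent radial segregation
(each prints a short interpretation of its numbers).

The same workflows are available as subcommands of the `ecospheroid` CLI
(`fit-homogeneous`, `fit-interactions`, `regrowth-map`, `identifiability`,
`ca-run`, `synth`), each writing a provenance manifest next to its
outputs.

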