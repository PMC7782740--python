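"""Emergent spatial structure of a mixed spheroid in the hybrid CA model.

Runs a 1:1 mixed simulation on a reduced 100x100 lattice for 8 days: two
phenotypes divide into free space (with limited shoving), consume oxygen
that diffuses in from the medium, and die after prolonged hypoxia.  The
radioresistant phenotype cycles faster, consumes 17% less oxygen, and is
less hypoxia-tolerant, so it accumulates at the periphery while parental
cells persist in the oxygen-poor centre — summarised by a positive radial
segregation index.
"""

import ecospheroid as es

params = es.CAParams(grid_size=100, seed=5)
snapshots, curve = es.simulate_ca(params, days=8.0, initial_radius=10)

for st in snapshots[::2]:
    counts = st.counts()
    print(f"  day {st.time_days:4.1f}: parental {counts['parental']:5d}, "
          f"radioresistant {counts['radioresistant']:5d}, "
          f"dead {counts['dead']:5d}")
final = snapshots[-1]
seg = es.radial_segregation_index(final)
print(f"equivalent-sphere volume day 8: {curve.volumes[-1]:.2f} mm^3")
print(f"radial segregation index: {seg:+.3f} "
      "(positive = radioresistant cells peripheral)")
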