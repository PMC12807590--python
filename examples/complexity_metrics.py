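"""Aperture and sequence complexity of a small hand-built IMRT beam.

Builds a three-control-point beam — a compact square segment, a ragged
staircase, and a narrow strip — and prints the edge-area metric (EAM) of
each aperture plus the MU-weighted plan EAM and modulation complexity
score (MCS). Higher EAM means a more irregular aperture (a square scores
the isoperimetric minimum 4/pi ~ 1.27); MCS runs from 0 (heavily
modulated) to 1 (a single static open field).
"""

import numpy as np

from imrteval import Beam, ControlPoint, LeafGeometry, Plan, compute_complexity

geom = LeafGeometry.millennium120()


def cp(index, mu_weight, open_rows):
    bank_a = np.zeros(60)
    bank_b = np.zeros(60)
    for row, (left, right) in open_rows.items():
        bank_a[row], bank_b[row] = left, right
    return ControlPoint(index, mu_weight, bank_a, bank_b, (-8.0, 8.0), (-6.0, 2.0))


square = cp(0, 0.5, {r: (-2.0, 2.0) for r in range(22, 30)})  # 4 x 4 cm
staircase = cp(1, 0.3, {22 + k: (-3.0 + 0.8 * k, -0.5 + 0.8 * k) for k in range(6)})
strip = cp(2, 0.2, {25: (-4.0, 4.0)})  # 8 x 0.5 cm

plan = Plan([Beam(0.0, [square, staircase, strip], 120.0, "demo")], 50.0, 25, "EF")
plan.validate()

result = compute_complexity(plan)
print("per-aperture EAM (MU fraction):")
for rec in result.per_cp:
    print(f"  cp{rec['cp']}: EAM={rec['eam']:.3f}  area={rec['area']:.2f} cm^2 "
          f"perimeter={rec['perimeter']:.2f} cm  (mu={rec['mu']:.0f})")
print(f"plan EAM (MU-weighted): {result.eam_plan:.3f}")
print(f"plan MCS:               {result.mcs:.3f}")
print("The square aperture sits near the 4/pi floor; the staircase and the")
print("thin strip drive EAM up, and the shape changes between control points")
print("pull MCS below 1.")
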