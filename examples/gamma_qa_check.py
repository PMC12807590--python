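"""Gamma-index QA of a composed verification plane (3%/3 mm, global, 10% cut).

A jaw-locked plan's beams are composed at gantry 0 onto a 5-cm-depth
phantom plane (the standard pre-treatment verification geometry). The
plane is then compared against perturbed copies of itself to show how the
passing rate reacts to calibration-scale dose errors, and against its
10-mm-pitch detector-array decimation.
"""

import numpy as np

from imrteval import (CohortSpec, DosePlane, GammaCriteria,
                      decimate_to_detector, gamma_index, plan_to_phantom_plane)
from imrteval.synthetic import generate_geometry, generate_plan

spec = CohortSpec()
geometry = generate_geometry(np.random.default_rng(9), spec.grid)
plan = generate_plan(np.random.default_rng(123), "SJL", geometry, spec)
reference = plan_to_phantom_plane(plan, spec.dose_model, depth_cm=5.0)
print(f"verification plane: {reference.values.shape} samples, "
      f"max {reference.values.max():.1f} (arb. units)")

for scale, label in ((1.0, "identical"), (1.02, "+2% dose"), (1.05, "+5% dose")):
    evaluated = DosePlane(reference.origin, reference.spacing,
                          reference.values * scale)
    res = gamma_index(reference, evaluated, GammaCriteria())
    print(f"{label:>10}: passing rate {res.passing_rate:6.2f}% "
          f"({res.n_evaluated} points evaluated)")

detector = decimate_to_detector(reference, pitch_cm=1.0)
res = gamma_index(detector, reference, GammaCriteria())
print(f"detector-pitch reference (10 mm): passing rate {res.passing_rate:.2f}%")
print("A uniform +2% error stays inside the 3% dose tolerance (still 100%);")
print("+5% fails everywhere that distance cannot rescue a flat profile.")
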