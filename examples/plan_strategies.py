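"""Generate basic and advanced native strategies for a synthetic crystal.

The basic strategy is one full turn at the lowest safe chi; the advanced
strategy adds polyhedron-derived orientations so the symmetry images tile
reciprocal space evenly, with later sweeps cut to 192 deg where the
goniostat would shadow the detector.
"""

import warnings

from mxstrat import advanced_strategy, basic_strategy, get_detector, predicted_multiplicity, random_crystal

crystal = random_crystal("hexagonal", seed=4, point_group="622",
                         target_resolution_A=2.0)
det = get_detector("pilatus6m")

plan = basic_strategy(crystal)
print("basic:   ", [f"{s.width_deg:.0f} deg @ chi {s.chi_deg:.1f}" for s in plan.sweeps])

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    plan = advanced_strategy(crystal, det, distance_mm=250.0)
print("advanced:", [f"{s.width_deg:.0f} deg @ chi {s.chi_deg:.1f}" for s in plan.sweeps])
print(f"total {plan.total_length_deg:.0f} deg, "
      f"{plan.recentring_count} recentring(s), "
      f"max multiplicity {predicted_multiplicity(plan, '622'):.0f}")
# For 622 the advanced strategy is 360 + 192 = 552 deg; counting the 192 at
# its effective 180, the Laue group (order 24) delivers up to 72 observations
# per unique reflection.
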