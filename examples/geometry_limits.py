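"""Detector angular limits and goniostat shadowing.

Prints, for each bundled detector at its shortest usable distance, the
largest diffraction angle that still lands on the face, the highest chi that
allows a shadow-free full turn, and the best resolution at 1 A -- then the
shadow-free omega window of the largest detector at two distances.
"""

import numpy as np

from mxstrat import chi_max_shadow_free, get_detector, resolution_limit, two_theta_max
from mxstrat.geometry import per_kappa_shadow_free_widths
from mxstrat.instruments import DETECTORS, TABLE_ORDER, get_goniostat

print(f"{'Detector':<14}{'2theta_max':>11}{'chi_max':>9}{'d(A)':>7}")
for key in TABLE_ORDER:
    det = DETECTORS[key]
    tth = two_theta_max(det.narrowest_mm, 137.0)
    print(f"{det.name:<14}{tth:>11.1f}{chi_max_shadow_free(tth, 19.84):>9.1f}"
          f"{resolution_limit(tth, 1.0):>7.2f}")

gonio = get_goniostat("mini-kappa")
det = get_detector("pilatus6m")
for distance in (200.0, 100.0):
    widths = per_kappa_shadow_free_widths(np.arange(90.0, 241.0, 30.0), det,
                                          distance, gonio)
    med = np.median(list(widths.values()))
    print(f"\nPILATUS3 6M at {distance:.0f} mm: shadow-free omega window "
          f"~{med:.0f} deg per kappa setting (kappa 90-240 deg)")
# The chi_max column is what limits full-turn sweeps: beyond it the phi-axis
# mounting cone starts clipping the detector for part of each turn, and
# strategies fall back to 192 deg sweeps inside the shadow-free window.
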