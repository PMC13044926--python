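"""Phasing building blocks: minimum sweeps, interleaving and cusp filling.

Anomalous phasing compares Friedel/Bijvoet mates, so sweeps are sized by the
Dauter minimum-range rules and scheduled so compared reflections share
irradiation history.
"""

from mxstrat import Sweep, cusp_fill, interleave_schedule, min_anomalous_sweep

tth = 30.0  # 2 theta_max at a 2 A limit with 1 A radiation

for pg, alignment in [("1", "aligned"), ("2", "aligned"), ("2", "orthogonal"),
                      ("4", "aligned"), ("222", "aligned"), ("622", "aligned")]:
    w = min_anomalous_sweep(pg, alignment, tth)
    print(f"point group {pg:>3}, {alignment:<10}: minimum sweep {w:6.1f} deg")

main = Sweep(width_deg=180.0)
segments = interleave_schedule(main, wedge_deg=10.0)
print(f"\ninterleaving a 180 deg sweep in 10 deg wedges: {len(segments)} segments"
      f" alternating omega / omega+180")

fills = cusp_fill(main, tth, mode="pair")
print(f"cusp-filling pair: two {fills[0].width_deg:.0f} deg sweeps starting "
      f"{abs(fills[1].omega_start_deg - fills[0].omega_start_deg):.0f} deg apart")
# The pair mode measures both halves of the anomalous pairs lost in the main
# sweep's blind region; the aligned-evenfold minima (e.g. 90 deg for point
# group 4) put each Bijvoet comparison on a single image.
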