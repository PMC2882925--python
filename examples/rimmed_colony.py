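"""Grow the reference rimmed colony from a single planted site.

A point inoculum develops under the reference rates (N=140, P=1, S=10,
A=5, O=0.01, D=0.495, G=5) with the tuned sensitivity thresholds.  The
colony finishes growth on its own and its final cross-section shows the
three-zone anatomy: thick central navel, flat interstitial ring, thick
peripheral rim.
"""

from colonyca import builtin_config, build_inoculum, run_simulation
from colonyca import classify_trace, segment_zones

cfg = builtin_config("rimmed")
trace = run_simulation(build_inoculum(cfg.inoculum, cfg.params), cfg.params)
report = classify_trace(trace)
colony = report.colonies[0]

print(f"terminated at generation {trace.terminated_at}")
print(f"classification: {report.classification.value}")
print(f"total diameter: {colony.total_diameter} sites "
      f"(navel {colony.navel_diameter}, interstitial ring "
      f"{colony.ring_diameter}, rim {colony.rim_diameter})")
print(f"final odor level: {trace.final.odor:.1f} (arbitrary units)")
print()
print("zones of the final cross-section (left to right):")
seg = segment_zones(trace.final.thickness, cfg.params)
for zone in seg.colonies[0].zones:
    print(f"  {zone.label.value:<13} sites {zone.start:3d}-{zone.stop - 1:3d} "
          f"(width {zone.width:2d}), mean thickness {zone.mean_thickness:6.1f}")

# The navel forms first (early growth arrested by the quorum signal or
# the thickness cap), the ring stays thin because quorum blocks its
# regrowth, and the rim is built late by odor-triggered refractory cells
# that ignore the quorum and stop only at the second odor threshold.
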