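"""Planting size decides the outcome: rimmed colony or macula.

Block inocula ("drops") of increasing width are planted under the rimmed
reference parameters.  The navel always occupies the planted area, so
widening the drop squeezes the interstitial ring; once the planting
reaches the singleton colony's critical diameter (navel + ring), no room
is left for the ring and the body collapses into an undifferentiated
macula.
"""

from colonyca.experiments import scenario_inoculum_sweep

result = scenario_inoculum_sweep()

print(f"critical planting diameter (singleton navel + ring): "
      f"{result.macula_reference_width} sites")
print(f"first macula at width: {result.first_macula_width} sites")
print()
print(result.table.to_string(index=False))
print()
print("navel diameter never shrinks and the ring never regrows as the")
print("planting widens; the classification switches from rimmed to macula")
print("and never reverts.")
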