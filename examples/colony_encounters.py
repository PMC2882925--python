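"""Two colonies sharing one dish: smaller, sooner, and — when close —
fused under a common rim.

Pairs of point inocula are planted at increasing separations.  Because
the two colonies share the substrate quorum field and the global odor
pool, each member stays smaller and matures sooner than a singleton
grown under identical parameters; below a crossover separation the pair
develops a single common rim around both navels.
"""

from colonyca.experiments import scenario_encounters

result = scenario_encounters()

print(f"singleton control: diameter {result.singleton_diameter} sites, "
      f"mature at generation {result.singleton_maturity}")
print(f"confluence crossover: separation {result.crossover_separation} sites")
print()
print(result.table.to_string(index=False))
print()
print("every paired run matures sooner than the singleton; beyond the")
print("crossover the pair resolves into two rimmed colonies, each smaller")
print("than the singleton control.")
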