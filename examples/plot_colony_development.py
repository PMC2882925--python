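"""Render the development of the reference rimmed colony.

Writes a figure with the thickness and quorum cross-sections at a few
developmental stages plus the colony-size and odor time series, to
scratch/rimmed_colony.png.
"""

from pathlib import Path

from colonyca import builtin_config, build_inoculum, run_simulation
from colonyca.plotting import plot_profiles

cfg = builtin_config("rimmed")
trace = run_simulation(build_inoculum(cfg.inoculum, cfg.params), cfg.params)

final = trace.final.generation
stages = sorted({final // 4, final // 2, 3 * final // 4, final})
out = Path("scratch")
out.mkdir(exist_ok=True)
path = plot_profiles(trace, stages, out / "rimmed_colony.png")
print(f"development stages {stages} plotted to {path}")
print("the early hat-shaped profile grows into navel + ring, and the rim")
print("appears last, once the odor level crosses the reactivation limit.")
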