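# colonyca

A deterministic one-dimensional cellular-automaton simulator of
bacterial colony morphogenesis, for researchers studying how multicellular
bacterial bodies (e.g. structured *Serratia*-type colonies) acquire their
internal anatomy through chemical signaling rather than through any
pre-existing blueprint.

## The model

The dish is a row of `L` lattice sites; each site carries a bacterial
layer of integer thickness (0…`N`), a cell state, and — while in early
stationary phase — an age counter. Cells pass through four states:

1. **exponential growth** — thickness doubles each generation (capped at
   the nutrient-limited maximum `N`) and the colony spreads by migration
   of one daughter cell into each adjacent empty site; cells produce `P`
   units of a diffusible *quorum* signal per bacterium per generation;
2. **early stationary** — entered when the local quorum concentration
   reaches `Qlim` or the layer reaches `N`; growth stops while quorum
   production rises `S`-fold, for `A` generations;
3. **mature stationary** — terminal and absorbing; quorum production
   ceases and the cells instead emit a volatile *odor* signal (`O` units
   per bacterium per generation) that pools globally — its level is the
   same everywhere on the dish;
4. **refractory growth** — when the odor level crosses `Olim1`, growing
   and early-stationary cells switch to a state that divides, ignores
   the quorum signal, produces nothing, and arrests (into state 3) only
   at thickness `N` or at a second odor threshold `Olim2`.

Each generation applies four steps in order: state evaluation (all
sites judged synchronously against the same snapshot), division and
lateral migration, signal production, and quorum diffusion — `G` nested
iterations in which every adjacent pair of sites exchanges a fraction
`D ≤ 0.5` of its concentration difference. There is no randomness
anywhere: identical inputs give bit-identical traces.

This minimal signal pair is enough to reproduce, qualitatively, a whole
family of observed behaviours: colonies that stop growing on their own;
a **rimmed** phenotype (thick central *navel*, flat *interstitial ring*,
massive peripheral *rim* built late by refractory cells); a **rimless**
phenotype obtained by changing *only* the three sensitivity thresholds;
paired colonies that grow smaller, mature sooner, and fuse under a
common rim when planted close; and the collapse of over-wide plantings
into undifferentiated **maculae** once the planted area exceeds the
singleton colony's critical (navel + ring) diameter.

The reference rates are `N=140, P=1, S=10, A=5, O=0.01, D=0.495, G=5`.
The three thresholds are not printed anywhere and are recovered by a
grid search (`colonyca.experiments.tune_thresholds`); the shipped
defaults are `Qlim=1000, Olim1=100, Olim2=220` (tuned, not printed).

## Worked example

```python
from colonyca import builtin_config, build_inoculum, run_simulation, classify_trace

cfg = builtin_config("rimmed")            # reference rates + tuned thresholds
trace = run_simulation(build_inoculum(cfg.inoculum, cfg.params), cfg.params)
report = classify_trace(trace)
print(report.classification.value, report.generations_to_maturity)
```

Running `python examples/rimmed_colony.py` (the same computation with a
zone table) prints:

```
terminated at generation 29
classification: rimmed
total diameter: 57 sites (navel 13, interstitial ring 8, rim 20)
final odor level: 290.6 (arbitrary units)

zones of the final cross-section (left to right):
  interstitial  sites 147-154 (width  8), mean thickness   16.0
  rim           sites 155-164 (width 10), mean thickness  138.8
  interstitial  sites 165-168 (width  4), mean thickness   64.0
  navel         sites 169-181 (width 13), mean thickness  138.2
  interstitial  sites 182-185 (width  4), mean thickness   64.0
  rim           sites 186-195 (width 10), mean thickness  138.8
  interstitial  sites 196-203 (width  8), mean thickness   16.0
```

A single planted cell has developed, in 29 generations, into a finite
symmetric colony: a 13-site navel at full thickness, a thin interstitial
ring on each flank, a 10-site near-maximal rim on each side, and a thin
outer skirt where refractory spreading was cut off by the final odor
threshold. The other scripts in `examples/` demonstrate the rimless
threshold switch, colony encounters, the planting-size sweep, and
profile plotting.

## Command line

```sh
colonyca simulate -o trace.tsv                 # builtin rimmed run
colonyca classify -t trace.tsv -o report.json
colonyca sweep -o sweep.tsv --widths 1:41:2
colonyca scenario encounters -o outdir/
```

Traces are tab-separated (per-site rows plus a per-generation summary
file), reports are JSON, configs are YAML; see `docs/methods.md`.

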