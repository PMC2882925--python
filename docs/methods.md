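# Methods

## Model

The simulator is a one-dimensional continuous cellular automaton. The
state of the dish is: per site, a bacterial layer thickness (integer,
0…`N`), a cell state (empty / exponential / early stationary / mature
stationary / refractory), and an age counter defined only in the early
stationary state; plus a per-site quorum concentration (float) and one
global odor level (float). A *generation* applies four steps in order:

1. **State evaluation.** All sites are judged synchronously against the
   pre-step snapshot, with this precedence per occupied site:
   (a) exponential or early-stationary cells with odor ≥ `Olim1` turn
   refractory — odor outranks the quorum trigger, because refractory
   cells no longer respond to quorum, so co-occurring triggers must
   reactivate, not arrest; (b) exponential cells with local quorum ≥
   `Qlim` or thickness = `N` enter early stationary phase with age 0;
   (c) early-stationary cells whose age has reached `A` mature,
   otherwise their age advances by one; (d) refractory cells mature at
   odor ≥ `Olim2` or thickness `N`; (e) the mature state is absorbing.
   With this convention a site entering early stationary phase at
   generation *t* matures during the evaluation of generation
   *t + A + 1*.
2. **Division and migration.** Growing sites (exponential, refractory)
   double, capped at `N`. Every empty site adjacent to a growing site
   receives exactly one daughter bacterium and adopts the colonizer's
   state, unless blocked by diffusible factors: an exponential
   (quorum-sensitive) colonizer is blocked when the *target* site's
   quorum is already ≥ `Qlim`; a refractory colonizer ignores quorum
   but is blocked once odor ≥ `Olim2` — each state's colonization is
   limited by exactly the signals it is sensitive to. A sole eligible
   donor is decremented by one per exported daughter (floor 1). When
   *both* neighbors are eligible (two fronts meeting over one empty
   site), the site still gains exactly one bacterium in the shared
   front state, and neither donor is charged: charging one side would
   break the left-right symmetry that a mirror-symmetric dish must
   preserve exactly. The two fronts necessarily share a state, because
   the odor trigger is global — refractory and exponential cells can
   never coexist on one dish.
3. **Signal production.** Exponential sites add `P·thickness` quorum
   units locally; early-stationary sites add `S·P·thickness`; mature
   sites add `O·Σthickness` to the global odor pool. Refractory and
   empty sites produce nothing. Neither signal decays: conditioned-agar
   behaviour indicates the signals persist in the substrate, and no
   decay term is part of the model.
4. **Quorum diffusion.** `G` nested iterations; in each, every adjacent
   pair exchanges a flux `D·(qᵢ − qᵢ₊₁)` computed from the iteration's
   starting field and applied simultaneously. Dish walls are zero-flux
   (a Petri-dish wall neither absorbs nor supplies signal). `D` is
   restricted to [0, 0.5]: moving more than half of a pairwise
   difference per iteration makes the explicit scheme oscillate.

A run iterates generations until every occupied site is mature (the
absorbing, signal-quiet configuration — nothing can change afterwards),
recording that generation as `terminated_at`, or until the generation
cap (`max_generations`, default 10 000) is hit, in which case the trace
is flagged non-terminated and classification is refused.

### Numerical choices

- The diffusion update is implemented in accumulate-increment form:
  each site gains `D·(q[i−1]−q[i]) + D·(q[i+1]−q[i])` and the increments
  are applied at once. This is the same synchronous scheme as applying
  pairwise fluxes, but because float addition is commutative it is
  *bit-exactly* mirror-symmetric, and translation-invariant wherever
  the field stays clear of the walls. Total quorum is conserved to
  ~1e-15 relative per call (the contract is 1e-9).
- All state transitions compare with `≥` at thresholds; ties are
  deterministic.
- Thickness, states and ages are integers; only the signals are floats.
  Two runs with identical inputs are bit-identical — the model has no
  stochastic element.

## Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| `N` | maximum layer thickness (nutrient proxy) | 140 | bacteria/site |
| `P` | quorum production, exponential cells | 1 | quorum·bact⁻¹·gen⁻¹ |
| `S` | stationary/exponential production ratio | 10 | — |
| `A` | early-stationary production window | 5 | generations |
| `O` | odor production, mature cells | 0.01 | odor·bact⁻¹·gen⁻¹ |
| `D` | diffusion factor | 0.495 | fraction/iteration |
| `G` | diffusion iterations per generation | 5 | — |
| `Qlim` | quorum limit for growth arrest | 1000 (tuned) | quorum units |
| `Olim1` | odor limit for refractory reactivation | 100 (tuned) | odor units |
| `Olim2` | odor limit for final arrest | 220 (tuned) | odor units |
| `L` | lattice length | 351 | sites |

The first seven are the reference rates used for all rimmed-colony
simulations. The three sensitivity thresholds are available only
graphically in the source material, so they are recovered by the grid
search in `experiments.tune_thresholds`: candidates are run from a
single-point inoculum and kept when the run terminates and classifies
as rimmed. The default grid spans `Qlim` logarithmically over the
quorum scale implied by `P`, `S` and `N` (10²…3·10⁴), `Olim1` over the
odor scale implied by `O` and a mature biomass of order 10³–10⁴
(10…300), and `Olim2` as multiples (1.2–10×) of `Olim1`, since what
matters dynamically is the width of the refractory window relative to
the odor rise rate. Of the 33 feasible triples in the default 96-cell
grid, the shipped default `(1000, 100, 220)` was selected because its
singleton colony shows a well-proportioned three-zone anatomy (navel
13, ring 8, rim 20 sites at `L=351`) and its planting-size response
reproduces the full rimmed → macula sequence with the macula onset at
the singleton's critical diameter. The rimless partner `(20000, 100,
220)` differs only in `Qlim`, demonstrating that the phenotype switch
needs no change to any growth or production rate. Both are marked
"tuned, not printed" in the shipped configs.

## Inoculation

Planting layouts: `point` (dotting), `block` of a given width
(dropping), `multi` (several points), `ring_section` (the 1-D
cross-section of a ring: two symmetric blocks around a central gap),
and `background` (fixed-stride single sites, exploratory only). Planted
sites start exponential with `initial_thickness` (default 1) bacteria.
Even widths are centered by occupying the extra site on the left — a
documented, deterministic convention; simulation studies use odd widths
so that blocks center exactly on a lattice site and the whole run stays
mirror-symmetric.

## Phenotype classification

Zone segmentation thresholds occupied sites at `tall_fraction·N`
(default 0.5): final profiles are strongly bimodal (navel and rim sit
at or near `N`, the ring more than fourfold lower), so any mid-range
cut separates them; the fraction is exposed because it is the one
genuinely free choice. Maximal TALL/THIN runs within each connected
colony (colonies are separated by at least one empty site) are mapped
to zones: a single tall run is a navel; of two tall runs the inner is
the navel and the outer the rim; with three or more, the outermost two
are rims and every inner tall run a navel. Reported diameters:
`interstitial_diameter` counts every thin zone (so navel +
interstitial + rim = total), while `ring_diameter` counts only thin
sites *between* the outermost thick zones — the interstitial ring
proper, excluding the thin outer skirt left outside the rim when
growth arrests.

Classification per colony: navel + ring + rim → **rimmed**; two or
more navels inside one rim pair → **confluent rimmed**; a single tall
zone with (non-strictly) monotonically decaying flanks and no rim →
**rimless** (plateaus allowed — discrete thickness makes strict
monotonicity brittle); a single tall zone at least as wide as the
reference colony's ring outer diameter (when that reference is
supplied, as the sweep scenario does), or a no-rim body failing the
monotone-decay test → **macula**; anything narrower than `min_extent`
(default 5 sites) → **undeveloped**. A rim whose peak is below 0.8 of
the navel's is additionally flagged `imperfect_rim` rather than given a
class of its own. Classification is invariant under reflection and
translation of the profile, and refuses non-terminated traces.

## Scenarios and problem sizes

All scenarios run on a 351-site dish with the reference rates; each
single run takes a few milliseconds, the default tuning grid (96 runs)
a few seconds. Encounters scan separations 16–80 in steps of 4:
below ~16 sites the two plantings fuse into a single navel outright
(nothing left to call an encounter), beyond 80 the colonies barely
interact. The planting-size sweep uses odd widths 1–41, spanning from
a single site to about twice the singleton's critical diameter. The
translation-invariance check uses an 801-site dish so that even the
diffusing quorum tails (which advance one site per diffusion iteration)
never touch a wall within the ~30-generation run.

## What the tests do and do not show

All inputs are generated programmatically — parameter sets, planting
layouts, randomized dishes for the oracle comparison, and synthetic
zone-recipe profiles for classifier tests. The randomized dishes are
deliberately biased to place signal levels at and around the three
thresholds so that every transition branch is exercised. Passing tests
show that the automaton implements its own rules exactly (bit-exact
agreement with an independent naive transcription), that its conserved
quantities and symmetries hold, and that the stated colony-level
phenomena emerge under the tuned thresholds. They do not show anything
quantitative about real colonies: the model has no 2-D geometry, no
nutrient field, no swarming or variable lateral-spread kinetics, no
multi-clone interactions, and arbitrary units throughout; lengths are
lattice sites and times are generations, neither calibrated to
millimetres or hours.

## Known limitations

- Only one clone per dish; cross-feeding, mixed-clone and
  inter-species interactions are out of scope.
- Ring inocula are represented by their 1-D cross-sections (two
  blocks); genuinely two-dimensional effects (ring healing, ghost
  colonies) cannot arise.
- The macula/rimless distinction for a lone wide plateau requires a
  reference diameter; without one, a monotone plateau classifies as
  rimless.
- The odor signal is cumulative and never decays; development
  therefore always terminates once `Olim2` is finite and reachable,
  and re-growth after maturity is impossible by construction.
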