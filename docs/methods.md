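# Methods

## The model class

`popchart` executes hierarchical, parallel state-transition diagrams
(Harel statecharts) as population dynamics.  A chart describes what one
biological object — a thymocyte, a lymphocyte, a gene — can do: its states,
organised into parallel *regions* (simultaneously active tracks such as
differentiation, anatomical location and cell-cycle phase) and nested
*compound* states (e.g. numbered proliferation generations inside a
phenotypic stage), and the transitions between them.  The population
semantics is compositional: an individual occupies one leaf state per
region, so the population is accounted over the Cartesian *product* of the
regions' leaf states, and every authored transition induces a family of
fluxes on that product space.

Compilation has two stages.

**Flattening** removes hierarchy inside each region.  A transition leaving
a compound state is factorized over all of its leaf substates; it may carry
a single shared rate or a per-substate rate mapping (the mapping is resolved
innermost-first along the substate path, so a rate given for a nested
compound covers all of its leaves unless a deeper key overrides it).  A
transition *entering* a compound state is redirected to its initial
substate, recursively — entry into a staged compartment always happens at
the first stage.

**Expansion** forms the product of the flattened regions and emits one
*flux entry* per (flat transition × context) pair, where the context is an
assignment of leaf states to the other regions.  Cross-track interaction
enters in three ways:

* *Context-dependent rates* ("weak" coupling).  Rate expressions may
  contain `pop(S)` — the current total occupancy of any authored state,
  summed over the product states inside it — and `ind(S)`, an indicator
  that is 1 when the context coordinate of S's region lies inside S.
  `ind` terms are resolved to literals at expansion time, so each flux
  entry carries the rate appropriate to its context; `pop` terms stay
  symbolic and are evaluated along the trajectory (this is what makes
  mass-action and ligand-competition rates expressible).
* *Guards* ("strong" coupling).  A guard is a conjunction of
  `in(S)`/`not in(S)` predicates over *other* regions, with descendant
  semantics for compound S.  A guarded-out combination is **removed** from
  the network, not carried at rate zero: the flux table contains exactly
  the terms that appear in the written-out equation system, and the
  authored/expanded entry counts differ by exactly the pruned contexts.
* *Coupled (labelled) transitions.*  Transitions sharing a label fire as
  one synchronized event that moves every member's coordinate at once.
  Exactly one member carries the rate (and offspring factor); the others
  defer to it.  A label may have several members in the same region — they
  are alternative branches, selected by which member's source coordinate is
  active — but must span at least two regions.  Where some member region
  has no enabled branch (e.g. the last generation of a finite chain), the
  joint transition is disabled at that product state: firing half of a
  synchronized pair would contradict the point of the coupling.  This
  end-of-chain convention is a genuine design choice (the alternative —
  falling back to an uncoupled firing — is defensible but makes the
  semantics non-local); it is documented here and asserted in the tests.

Pseudostates close the system: `ORIGIN` marks constant-rate influx
(progenitor supply σ), with unspecified regions of the receiving product
state defaulting to their initial leaves (overridable per influx), and
`SINK` marks removal.  A removal in any track removes the whole
product-state individual — a death is a death of the cell, whatever the
other coordinates.  The *offspring* factor of a transition is the number of
individuals deposited at the target per departing individual: 1 for plain
movement, 2 for a division whose daughters land in the next compartment,
and an expression such as `2*delta` for division under a treatment
indicator (δ=1 untreated; δ=0 makes every division remove the mother and
deposit nothing — dividing cells are lost).

## Deterministic and stochastic readings

The chart stores continuous-time intensities only; deterministic versus
stochastic execution is a runtime choice with no representation in the
diagram.  Using intensities (per unit time) rather than per-step
probabilities is what makes the two readings consistent.

*ODE.*  Each proportional flux entry with value v = rate × X[from]
contributes −v to its source and +offspring·v to its target; constant
entries contribute +rate to their target only.  The right-hand side is the
plain sum of contributions, so every transition "appears twice" — as an
outflow and an inflow.  The default integrator is scipy's adaptive RK45 at
rtol 1e-8 / atol 1e-10; a fixed-step classical RK4 is available when
bit-level reproducibility across platforms matters.  Occupancies that
undershoot zero by less than 10×atol are clamped (solver artifact); a
larger undershoot raises, because it signals a modeling error rather than
roundoff.

*Stochastic.*  The same flux table defines event propensities (direct
Gillespie method, exact, no tau-leaping — desk-scale networks do not need
it and exactness keeps the consistency tests clean).  An event removes one
individual from the source and deposits `offspring` individuals at the
target; offspring expressions must evaluate to non-negative integers within
1e-9, anything else is an error rather than a silent rounding.  Identical
(network, parameters, init, seed) gives an identical event sequence;
ensemble means derive replicate seeds deterministically from one master
seed.  For pop()-free (linear) rates the ensemble mean is exactly the ODE
solution; the suite checks this at finite replication via 3-standard-error
bands.

## The example library and what it does (not) show

The built-in charts are the package's fixtures and the user's templates:
mass-action infection, a gene toggle, the DN→DP→SP thymocyte chain, DP
branching to SP4/SP8, a compound-state demo, the two-track
independent/weak/strong trio, the three-track lymphocyte chart
(differentiation × location × cell cycle, 18 product states, with the
cell-cycle compound blocking every other track while a cell divides), the
label-coupled division/generation chart, and the five-year student chart
(20 product states).  In the lymphocyte chart the activation rates use a
saturating ligand-competition form
`b·ligand/(K + pop(Naive) + pop(Memory))` — available ligand as a
parameter, the competing populations in the denominator — chosen so that
the chart keeps its three tracks and 18 product states; any other form can
be substituted through the expression language.  The cycling guard is
drawn on the differentiation, migration *and* death transitions, so death
is also suspended while a cell divides; redrawing the chart without the
guard on death is a one-line change if the biology is read otherwise.

The conveyor-belt builder produces the staged thymocyte chart: compound
DN and DP stages with numbered generations, per-generation proliferation
(`offspring 2*delta`) into the next generation, differentiation leaving
every generation at non-decreasing rates `m_i` and entering the next
compound at its first stage, one factored natural-death transition per
compound, DP selection death, SP4/SP8 output and egress to the periphery.
Generation counts and every rate are configuration; the defaults
(n_DN = n_DP = 4, SP stages simple, egress from the last SP generation)
are documentation-scale examples, not a reproduction of any published
parameterization — the original staged model's ~30-equation rate table is
not part of this package.  By default egress leaves the last SP generation;
`egress_from="all"` drains every generation.

These charts exercise the full compiler semantics, but they are idealized:
rates are constant or simple saturating functions, there is no spatial
structure, no per-agent attribute memory (interaction counters, binding
histories — those belong to agent-based executions outside this package's
population-level scope), and no measurement noise.  Passing tests
demonstrate that the compiler realizes the diagram semantics exactly and
that both executions agree with closed forms and with each other — not that
any particular chart is a calibrated model of a thymus.

## Numerical and structural choices

* Product-state names are the region-ordered coordinate tuple joined with
  `|` (`Naive|LymphNode|G0`); region order is document order.  CSV columns
  and DOT nodes inherit the same names, so outputs are reproducible and
  diffable.
* The expansion is eager, with a hard cap (100 000 product states) and a
  clear error beyond it; no lazy/symbolic expansion is attempted.
* Guards are restricted to conjunctions of `in`/`not in`; richer boolean
  logic is rejected by the parser.  The only place negation-of-compound
  matters — blocking everything while inside a cycling compound — is
  covered by descendant semantics.
* Unknown document keys are hard errors: a typo in a `rate:` key must never
  silently drop a term from a model.
* Test problem sizes (replicate counts, horizons, random-chart family
  sizes) are chosen to give comfortable statistical margins at desk scale:
  e.g. the linear-chain consistency check uses 5 000 initial cells × 100
  replicates, where the 3-SE band is a fraction of a percent of the
  population.

## Known limitations

* Rates may depend on occupancies (`pop`) arbitrarily, including across
  regions, which makes the stochastic process non-linear; the
  ODE-equals-expectation identity then holds only approximately (the suite
  restricts that check to linear networks on purpose).
* Coupled transitions synchronize coordinates but cannot express joint
  *rates* that depend on both members beyond the single bearer's
  expression.
* No steady-state analysis, bifurcation tracking or parameter fitting; the
  package compiles and simulates.
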