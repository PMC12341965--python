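# Methods

## Model family and semantics

A model assigns every node of a self-contained signed network one
equation of the standardized link-operator family: activators OR-joined,
inhibitors OR-joined, the groups combined as `Act AND-NOT Inh` or
`Act OR-NOT Inh`. The grouping is fixed to `(a₁∨a₂∨…) LINKOP ¬(i₁∨i₂∨…)`;
no other Boolean forms (nesting, XOR, thresholds) are representable, by
design. Nodes with a single regulator class take `Act` or `¬Inh`
directly and carry no link operator. The default assembly uses AND-NOT
(activation required *and* inhibition absent), the less permissive
reading. Contradictory curation (the same edge annotated both activating
and inhibiting) is kept as one activator plus one inhibitor, which the
default-equation scheme handles naturally.

Only fixed points `x = f(x)` are computed. They are update-scheme
independent and are the sole attractor class the fitness and growth
read-outs use; models whose attractors are all complex simply report
`n = 0` (fitness 0, growth undefined). Trap spaces and cycle
enumeration are out of scope.

## Fixed-point solver

The enumerator is a DPLL-style backtracking search over node states with
tri-valued constraint propagation: whenever a partial assignment
determines a node's update value, the constraint `x_v = f_v(x)` forces
`x_v`; contradictions prune. All solutions are enumerated (the analogue
of SAT blocking clauses), sorted lexicographically in node order. Guards:
a node-count capacity limit (default 4096) and a fixed-point cap
(default 64) that raises an explicit overflow error — the topologies of
interest have few stable states, and unbounded enumeration should fail
loudly. An independent oracle, a numpy-vectorized sweep of all 2^N
states (N ≤ 20), backs the property tests; 200 random ≤ 12-node models
match it exactly.

During GA scoring only, an offspring that overflows the cap is assigned
fitness 0 (with a warning) rather than aborting the whole training run;
under the multiple-stable-state penalty its fitness would be ~0 anyway.

## Genetic algorithm

Defaults are the published schedule: population 20, top 3 selected,
per-equation uniform crossover of parents drawn with replacement
(including self-crossover, i.e. asexual reproduction; single-point
crossover available via `crossover="single_point"`), 3 link-operator
flips per offspring, ×1000 while the burst phase lasts, threshold 0.99
compared against the minimum of the top 3, at most 20 generations, 50
evolutions, ensemble = 3 × 50 = 150 models. Topology mode mutates a
blacklist/whitelist of the original network's regulators (50 per
offspring during burst, 10 after), redrawing any removal that would
leave a target unregulated; in `both` mode topology mutations precede
operator flips.

Choices the schedule leaves open, decided here:

- **Elitism.** Selected parents re-enter the scored pool next
  generation, so the best kept fitness never regresses
  (`elitism=False` restores pure generational replacement).
- **Burst exit** is population-wide and permanent: the boosted mutation
  counts end after the first generation in which any member has a fixed
  point.
- **Ties** in fitness break by creation order (older model first), for
  determinism.
- **Seeding.** One master seed spawns an independent stream per
  evolution (`[seed, evolution_index]`), so evolutions are reproducible
  in isolation.
- **Operator memory.** When topology mutation empties one regulator
  class the link operator drops to NONE; if the class refills, the
  equation's last-used operator is restored (fallback AND-NOT). This is
  a convention, not an observed behavior of the original tooling.
- **Flip parity.** Applying an exact, even number of flips (3 × 1000)
  constrains the Hamming parity of the operator vector, so one burst
  generation samples uniformly from the even-parity half (2^(n−1)) of
  the parameterization space rather than all 2ⁿ. The odd post-burst
  count (3) toggles parity each generation, so the whole space stays
  reachable. The uniformity property test is stated over the reachable
  half.

Fitness is the average fraction of specified calibration entries matched
per stable state, `Σᵢ Σⱼ 1[fixᵢⱼ = ssⱼ] / (m·n)`; multiple disagreeing
stable states are thereby penalized.

## Simulation and synergy

Drugs clamp their targets to constants (0 for inhibitors, 1 for
activators) by equation replacement; models keep value semantics
throughout. Growth is the weighted output-node sum scaled affinely to
[0, 1] between the theoretical minimum (sum of negative weights) and
maximum (sum of positive weights), averaged uniformly over a model's
stable states (the affine scaling makes scale-then-average equal
average-then-scale) and then over models. Models that lose all fixed
points under a perturbation are excluded from that perturbation's mean —
growth is undefined without an attractor, and scoring them 0 would
conflate death with non-convergence; exclusion counts are reported.
Ensemble aggregation happens *before* Bliss scoring (ensemble-level
E, A, S); the output sets and weights are user configuration, never
hard-coded.

Normalization uses ensemble-level excesses: `exp(S_calibrated −
S_baseline)`, where the baseline ensemble is trained by the same GA
against a fresh random proliferative profile per evolution (all
negative-weight outputs 0, positive-weight outputs uniform bits redrawn
until one is 1, all other nodes unspecified). Pairs missing either score
are excluded from ranking and logged.

## Benchmarking

ROC AUC is the tie-averaged trapezoid (identical to the Mann–Whitney
probability of ranking a true synergy above a non-synergy; ties get half
credit). PR AUC is a step-wise integral with no linear interpolation,
taking each step's precision at the lower-recall endpoint. This
conservative convention was chosen over average precision deliberately:
its expectation under a uniformly random ranking equals the positive
prevalence `n_pos/(n_pos+n_neg)` — the standard "random classifier" PR
baseline (0.04 for 6 synergies among 153 pairs) — whereas the mean
average precision of a random ranking is biased upward (≈ 0.068 at
6/153) for small positive counts. A perfect ranking scores 1 under both.
The bootstrap comparison of two rankings is paired and stratified
(positives and negatives resampled separately, so no resample is
single-class), reporting the one-sided p per metric: the fraction of
resamples with AUC(A) ≤ AUC(B).

The agreement statistic reports, per link-operator node, the percentage
of (model, stable-state) observations in which the permissive OR-NOT
co-occurs with state 1 or the restrictive AND-NOT with state 0.

## Synthetic planted systems

`generate_planted_system` emulates the *shape* of curated signaling
topologies at desk scale: a random signed digraph (default 15 nodes, 25
edges, ~70% activating, no duplicate source→target pair, every node
regulated by construction), a random link-operator assignment redrawn
until it has a stable state (the *truth model*), one of its fixed points
as the calibration profile (optionally masked), 4 output nodes split
+1/−1, and a panel of single-target inhibitors. Gold labels come from
exhaustive simulation of all drug pairs on the truth model (synergy iff
S < 0 strictly; pairs with undefined growth are labeled negative and
flagged). The panel is redrawn until every arm has defined truth growth
and both label classes exist (`min_positives` raises the bar for
benchmark power).

Two properties of real curated systems the generator does **not**
emulate: scale-free degree structure and pathway organization, and a
biological relationship between the calibration profile and the drug
response beyond what the planted parameterization induces. Consequently
passing tests demonstrate the machinery's correctness and the
information flow from calibration data to predictions — not clinical
predictive power.

**Identifiability.** The calibration profile pins only those operators
whose activator and inhibitor groups agree at the planted state; if few
are pinned, ensembles calibrated to the profile are uninformative about
the planted drug responses *by construction*, and no degradation of the
inputs could make performance worse. Recovery and degradation
experiments therefore use `unique_optimum=True`: all 2ⁿ
parameterizations are enumerated at generation time and the draw is
accepted only if the planted assignment is the sole one achieving
fitness 1, making the planted truth identifiable from clean data.

Degradation operators: `corrupt_profile` flips exactly
`round(fraction·m)` specified bits (an involution at fraction 1);
`scramble_topology` modifies `round(fraction·E)` interactions by
pairwise source exchanges, pairwise target exchanges, or sign
inversion (`all` chains the three), redrawing exchanges that would
duplicate an existing edge. Exchange semantics preserve node count, edge
count and the target multiset, so self-containedness survives without
repair; a positive-self-loop repair path exists as a safety net and for
user-supplied non-closed networks. In `degradation_experiment`, GA seeds
depend only on (seed, mode, replicate), so fraction 0 reproduces the
clean benchmark bit-exactly.

## Problem sizes used by the test suite

Chosen so the full suite runs in a few minutes on one CPU: the
ensemble-size contract runs the full published schedule (50 evolutions)
on a 15-node system; parameter recovery uses two 20-node/40-edge
identifiable systems with 20 evolutions each; degradation uses one
15-node/25-edge, 8-drug identifiable system with 10-evolution ensembles
(30 calibrated + 30 baseline models per cell), 10 replicates at
fractions {0, 1} for corruption and 12 replicates for full scrambling
(replicates whose scrambled network yields no stable models report NaN
and are excluded from the mean); the solver-vs-oracle equivalence uses
200 random models of 5–12 nodes; the random-classifier baseline uses
1000 random rankings of 153 pairs with 6 positives.

## Known limitations

- Only the link-operator rule family is expressible; curated models with
  bespoke Boolean rules cannot be imported.
- Complex attractors are detected only as "no fixed point"; oscillatory
  phenotypes are invisible to growth.
- Drugs are all-or-none node clamps; no partial inhibition or
  dose–response surfaces, and no HSA/Loewe reference models.
- The GA offers no convergence guarantee; ensembles approximate the set
  of data-compliant parameterizations only as well as 50 restarts allow.
- SBML-qual / BoolNet import-export and network visualization are not
  provided.
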