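# Methods

## The EEM model

The electronegativity equalization method (EEM) assigns partial atomic
charges q_1..q_N to a molecule of N atoms by requiring that every atom's
effective electronegativity equals a shared molecular value χ̄, subject to
conservation of the total charge Q.  For atom i with type-dependent
parameters A_i (electronegativity-like offset) and B_i (hardness-like
self-interaction), and a global distance-coupling scale κ:

    A_i + B_i q_i + κ Σ_{j≠i} q_j / R_ij = χ̄        (i = 1..N)
    Σ_i q_i = Q

with R_ij the interatomic distance in Å.  This is one dense linear system
of size (N+1) per molecule in the unknowns (q_1..q_N, χ̄): row i has B_i on
the diagonal, κ/R_ij off the diagonal and −1 in the χ̄ column with
right-hand side −A_i; the final row is all ones with right-hand side Q.
Charges are conformation-dependent (they change when the geometry changes)
and the cost is Θ(N³) per molecule.

Parameters are defined per **atom type** — the pair (element, maximal bond
order of the atom): `N3` is a nitrogen with at least one triple bond, `C1`
a carbon with only single bonds.  κ is global.

### Gauge freedom

Two transformations leave every charge unchanged:

* a uniform shift A_t → A_t + c (χ̄ shifts by c);
* joint positive scaling (A, B, κ) → (sA, sB, sκ) (χ̄ scales by s).

Parameters are therefore identifiable from charges only up to these gauges.
All recovery guarantees in this package are stated **in charge space**
(RMSD between computed and reference charges), never as parameter equality.
Where a unique parameter representation is needed (the regression route),
the scale gauge is pinned by constraining B of a reference atom type to 1
and the shift gauge is resolved by the minimum-norm solution.

### Numerical choices

* The bordered matrix is asymmetric only through the sign of the χ̄
  column; substituting χ̄ → −χ̄ makes it symmetric indefinite and it is
  solved by an LDL^T factorization (`scipy.linalg.solve(assume_a="sym")`).
  An independent generic LU solve is used as a cross-check oracle in tests,
  never as the production path.
* A solve is declared unreliable (raising `SingularSystemError`) when the
  result is non-finite or its residual exceeds 1e−7 relative to the
  matrix/solution scale; inside parameter fitting such candidates score a
  worst-fitness sentinel instead of raising.
* Off-diagonal distances below 1e−6 Å are rejected up front (κ/R would
  blow up).
* Batch charge calculation is embarrassingly parallel; the thread count is
  a pure speed knob and results are bit-identical for any value.

## Linear-regression parameterization (per-κ least squares)

With charges fixed at their reference values, the stationarity condition
of each atom is linear in {A_t, B_t} for fixed κ.  The per-molecule
electronegativities χ_m are nuisance unknowns; centering every design row
within its molecule eliminates them exactly (fixed-effects absorption).
The scale gauge is pinned by fixing B = 1 for a reference type (the most
frequent type in the training set, ties broken alphabetically —
hydrogen-rich data pins H1); the uniform A shift survives centering as an
exact null direction and is resolved by the minimum-norm least-squares
solution.  Rank deficiency beyond that one known direction is an error
naming the affected types, and each type must occur at least twice with at
least two distinct reference charges (otherwise A_t and B_t are
confounded).

κ is scanned over a grid (default 0.05 to 1.50 in steps of 0.05, fully
configurable); each fitted candidate is evaluated by computing actual EEM
charges and the selection metric — pooled R² (maximized) or avg(RMSD_a)
(minimized) — and ties go to the smaller κ.  Without the gauge pinning
this profile would be flat in κ (every κ can be compensated by rescaling
A and B); with it, κ is identifiable and on noiseless synthetic data the
scan recovers the generating κ exactly with charge residuals at machine
precision.

Optional greedy discard: repeatedly remove the molecule with the worst
per-molecule RMSD, refit at the incumbent κ, and keep the removal only if
the selection metric improves by more than 1e−9 (guarding against
float-level pseudo-improvements), up to a configurable fraction of the
training set (default 10%); the κ grid is re-scanned once on the final
kept subset.  This one-at-a-time scheme is the package's own choice of
pruning strategy.

avg(RMSD_a) weights every atom type equally regardless of abundance, which
prevents abundant types (hydrogens) from hiding poor fits on rare types;
the pooled RMSD satisfies the partition identity
RMSD² = Σ_t n_t·RMSD_a,t² / Σ_t n_t, which the tests assert.

## DE-MIN parameterization (differential evolution + local minimization)

Candidates are flat vectors (κ, A_1..A_T, B_1..B_T) over the sorted atom
types, evolved inside a box (defaults κ ∈ [0.05, 3], A ∈ [0, 6],
B ∈ [0.1, 10]).  The loop is classic DE/rand/1/bin: mutant = a + F·(b − c)
over three distinct randomly chosen population members, binomial crossover
with rate CR and a guaranteed-crossover component, out-of-box components
reflected back inside.  A candidate is **promising** when its pooled
charges give R² > 0.2 and R > 0; promising vectors are handed to a
derivative-free trust-region local minimizer (COBYQA, of the
NEWUOA/BOBYQA family of quadratic-interpolation methods), with an
evaluation budget per call.  The screen is always evaluated in correlation
terms, whichever metric is being optimized.  The incumbent best receives a
final, longer polish.  Replacement is greedy one-to-one, so the incumbent
best is non-worsening (elitism), and local minimization never returns a
point worse than its start.

Cost design: one local run costs ~`local_budget` objective evaluations,
each of which solves the EEM system for the whole training set.  Local
search is therefore applied to every promising vector of the *initial*
population, but during evolution only to promising trials that improve the
incumbent best — intensification around new incumbents.  This keeps a
generation at O(population) evaluations; minimizing every promising trial
would multiply the cost by ~`local_budget` while adding nothing once the
population is promising-dense.  Fitness evaluation batches molecules of
equal size into stacked dense solves.

Defaults: population max(40, 8·(2T+1)), up to 300 generations with early
stop after 40 non-improving generations, F = 0.8, CR = 0.9, local budget
80 evaluations, polish budget 400.  These sizes were chosen so that a
training set of a few dozen small molecules parameterizes in seconds on
one core; all are configurable.  One seeded random stream drives
initialization, parent selection and crossover, so identical inputs,
configuration and seed give bit-identical results; different seeds give
slightly different parameter vectors (often in a different gauge — e.g. a
recovered κ of 1.2 with proportionally larger A, B is charge-equivalent to
the generating κ of 0.4) with closely similar final fitness.

The method is more robust than the regression route on heterogeneous or
noisy training sets because it optimizes the actual charge-space objective
rather than a linearization around the reference charges: on the noisy
eight-type synthetic benchmark the worst per-type RMSD_a of DE-MIN is
roughly a third of the regression route's.

## Validation

* **Coverage**: a molecule is covered iff every one of its atom types has
  an entry in the parameter set; the report carries counts, a percentage
  (printed to 2 decimals; serialized at full precision), and per-molecule
  missing-type listings.  Coverage is monotone under parameter-set growth.
* **Quality**: R, R², Spearman ρ (average ranks over ties), ρ², RMSD,
  mean absolute difference Δ and maximal absolute difference Δ_max, at
  three granularities — pooled over all atoms, per atom type and per
  molecule — plus the aggregates avg(RMSD_a), max(RMSD_a), max(Δ_a).
  The summary pools atoms across molecules; per-molecule statistics are
  exposed separately.  Correlations of constant or single-atom vectors are
  reported as not-available (NaN) rather than 0; error statistics are
  still computed.  Types present in the parameter set but absent from the
  data are listed with n = 0.
* **Scatter export**: a long-format per-atom table (molecule, index, type,
  reference charge, EEM charge) sufficient for correlation plots overall
  or per type; PNG rendering is optional and off by default.

## Synthetic data

The fixtures module stands in for real calibration data (3D structures
plus QM charges).  Molecules are grown atom by atom, each new atom placed
1.0–2.0 Å from a randomly chosen previous atom and rejected if any pair
falls below 0.9 Å; the placement tree doubles as the bond spanning tree,
plus optional extra bonds.  Bond orders are drawn from the intersection of
both endpoints' allowed orders, so palettes control exactly which atom
types can occur (the four-type palette H1/C1/N1/O1, or the eight-type
palette H1/C1/C2/N1/N2/O1/O2/S1).  A configurable fraction of molecules
(default 20%) carries a ±1 formal charge.  Reference charges are the EEM
solution under a known ground truth, optionally plus i.i.d. Gaussian noise
re-centred per molecule so Σq = Q stays exact.  Ground-truth magnitudes
mimic published ranges (κ ≈ 0.4, A ∈ [2, 3], B ∈ [2, 8], arbitrary
consistent units) with B(H1) = 1 as the gauge reference, and element
weights favour hydrogen so H1 is the most frequent type, as in organic
molecules.

What this does *not* emulate: real QM charge surfaces (the noiseless
reference charges are exactly EEM-representable, which real NPA/MPA
charges are not), chemically valid valences, conformer ensembles, or real
chemical space.  Passing recovery tests therefore demonstrates the
correctness of the fitting machinery — that each route finds the optimum
of its objective — not the physical accuracy of EEM on laboratory data,
which depends on the reference QM method and the similarity of the target
molecules to the training set.  Dataset generation forces every palette
type to appear at least twice (round-robin forced inclusion), satisfying
the regression identifiability preconditions by construction.

## Formats and conventions

* Structures: MDL SDF, V2000 molfiles only; V3000 is rejected.  Formal
  charges come from `M  CHG` lines only (their absence means neutral; the
  deprecated atom-block charge column is ignored).  Aromatic bond order 4
  is rejected by default with advice to kekulize; an opt-in maps it to 2,
  since the atom-type vocabulary spans orders 1–3.  Isolated atoms get
  order 1.  Element symbols are matched case-sensitively.
* Reference charges: a plain-text block format (name / count / indexed
  charge lines) defined by this package; written at 17 significant digits
  so write→read round trips are exact.
* Parameter sets: a JSON dialect (κ plus per-type element/order/A/B
  entries), also round-trip exact.  B ≤ 0 and duplicate types are
  rejected on read; a fitted B ≤ 0 (possible in the unconstrained
  regression) triggers a warning instead, and such candidates survive only
  if their EEM solves succeed.
* CLI: exit 0 success, 1 usage, 2 data/format, 3 numerical failure;
  outputs written atomically; `--threads k` never changes output bytes.

## Known limitations

* The regression route reports parameters in the reference-type gauge;
  comparing raw A/B values across fits with different reference types is
  meaningless (compare charges instead).
* No support for per-atom (rather than per-type) parameters, distance
  cutoffs or periodic systems.
* The greedy discard evaluates its metric on the kept subset, so part of
  each apparent improvement is evaluation-set shrinkage; it is a pruning
  heuristic, not a cross-validated model selection.
* Bond-order perception, protonation and 2D→3D generation are out of
  scope; inputs must be complete V2000 records with explicit bond orders.
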