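# Methods

## The process-interaction formalism

A PIM is a directed graph over process nodes. Four process types are
supported:

| type              | assignments            | reversible | reaction center      |
|-------------------|------------------------|-----------|----------------------|
| binding           | two (molecule, site)   | default   | two sites gain a bond |
| modification      | one (molecule, site)   | default   | site state U → M     |
| homodimerization  | one (molecule, site)   | default   | two monomers bond    |
| degradation       | one molecule           | never     | molecule deleted     |

An influence edge `i → j` means process `j` occurs with context-dependent
kinetics; `all_or_none` (AON) edges additionally assert that `j` can occur
only after `i`. Bidirectional interactions are stored as two directed plain
edges, because parameter tables consume directed predecessors only; the
document format accepts `kind: bidirectional` as sugar and expands it on
load.

Mass-action kinetics are assumed throughout; rate constants are taken as
given in consistent per-molecule-per-cell units, and units are not modeled.
Forward rate constants must be positive: a process that "cannot occur" in
some context is expressed by a very small constant, not by zero, so
dissociation-only reactions are approximated by a reversible binding with
small `k_eq`.

### Contexts and admissibility

The canonical predecessor order is ascending process id, and context rows
are enumerated in binary-counting order over the *free* inputs — the
non-AON predecessors. AON inputs are fixed at 1 and contribute no table
column (their column is reported as constant 1 in exports). Two further
filters apply:

* **Mutual exclusion.** Two preceding binding processes competing for one
  site *of a molecule that also carries the influenced process* can never
  both have occurred on one instance; their joint rows are removed from the
  kinetic table. The qualification matters: two binding processes may share
  a *ligand* site (one ligand species occupying two receptor sites) without
  being exclusive, since distinct ligand copies bind one receptor instance.
  Excluded rows may still carry a direct logical output `y` (default `*`)
  for the logical view, where both competitors can be active simultaneously.
* **Competing-for-center conflicts.** An influence whose source binding
  process is anchored on the target's molecules only through a site the
  target itself is about to bind is rejected at validation: its
  occurred-context would require the center site to be simultaneously free
  and occupied.

Homodimerization duplicates the free inputs per monomer; contexts are
unordered pairs of per-monomer assignments (symmetric duplicates collapsed,
the lexicographically smaller monomer first).

## Rule generation (BNGL)

Each admissible context yields one rule. Context encoding on both rule
sides: an occurred modification shows the site `~M` (not occurred: `~U`); an
occurred binding shows the center-molecule site bonded to an explicit
partner pattern (not occurred: the site written unbound); homodimer contexts
attach a partner monomer. When a predecessor binds the two center molecules
to each other, the centers are bonded directly. When a predecessor shares a
site with the reaction center itself (e.g. the common ligand site of the two
insulin-binding processes), the context is anchored on the other, persistent
molecule. Symmetric homodimer associations carry `0.5*k_fw`, following the
usual statistical-factor convention for indistinguishable reactant pairs.

Modification sites use the uniform state alphabet `~U`/`~M`; a site that is
both modification and binding site is declared once with states and may
show a state and a bond simultaneously. Seed species are the basic
molecules, unbound and unmodified, at concentration 1 (a placeholder to be
adjusted before simulation). Degradation is emitted as `Mol() -> 0 k`,
restricted to single-molecule deletion; complex-degradation keywords are not
generated. Parameter names `kf_n{node}_c{bits}` / `kb_n{node}_c{bits}`
preserve provenance. Output is deterministic byte-for-byte: ascending node
id, binary-counting context order, sorted molecule blocks.

## Discretization

For thresholds `t1 < t2` (global, with optional per-process overrides):
`y = 1` iff `k_eq ≥ t2`, `y = 0` iff `k_eq ≤ t1`, else `*`; irreversible
processes use `k_fw` in place of `k_eq`. Comparisons are inclusive and
exact on the parsed floats — no epsilon is applied, because thresholds are
deliberately placed *between* occurring parameter values and the comparison
at an exactly-equal value is meaningful (it decides which side a variant
model takes). Output is monotone in `k_eq`, and raising (lowering) both
thresholds can only lower (raise) outputs in the order `0 < * < 1` — the
mechanism behind the nested model variants below. For homodimerization only
the equal-monomer rows enter the logical view, since a logical species has
one state for all its representatives.

## Logical-model construction

One site L-node per referenced (molecule, site), one basal-activity L-node
per molecule. Basal nodes are the analysis inputs: fixing one to 0 removes
the molecule and everything downstream. The corresponds-to relation maps
each process to exactly one L-node:

* modification / homodimerization → its unique site node;
* binding at a previously modified site (AON from that modification) → the
  *partner* site node (the modified site stays with its modification
  process);
* binding of two unmodified sites → the site of the second-listed molecule
  (configurable tie-break); the first site then passes its basal value
  through an activating edge. The choice is arbitrary: with fully defined
  inputs both orientations give identical steady states, and with undefined
  inputs only the pass-through node itself differs (it mirrors its basal
  input instead of the binding event) — downstream values and classes are
  unchanged. Both facts are asserted in the test suite.
* collisions (one molecule binding several previously modified sites
  through one site) are resolved by auxiliary L-nodes: the lowest-id process
  keeps the site node, later ones get `mol.site__p<id>` nodes owned by the
  binding molecule and activated by its basal node.

Unsigned edges mirror the PIM influences one-to-one between corresponding
L-nodes; activating edges encode molecule structure (basal → site) and the
orientation pass-through. A degradation process becomes its own L-node with
a delay-flagged inhibiting edge onto the molecule's basal node.

Gates: the process's truth table is extended over *all* predecessors (AON
inputs re-enter with output 0 in their 0-rows), minimized to DNF by
Quine–McCluskey, and AND-conjoined with every activating input. A node with
no unsigned inputs gets the pure AND of its activating inputs. Rows with
`*` cannot feed two-valued minimization; the default ITT policy
("conservative") treats them as don't-cares, flags the gate and keeps the
raw table attached; `star_as_0`/`star_as_1` resolve them instead. A table
that is entirely `*` is an error — no gate can be inferred. The in-package
Quine–McCluskey (essential primes, then branch-and-bound exact cover with a
greedy fallback above a generous node budget, ≤ 10 inputs) is cross-checked
in the tests against sympy's independent `SOPform` minimizer and against
exhaustive evaluation.

## Three-valued analysis

Kleene semantics: `AND` is 0 if any input is 0, 1 if all are 1, else `*`;
dually for `OR`; negation swaps 0/1 and fixes `*`. Steady states iterate
all gates synchronously from all-`*` on the non-fixed nodes. Every gate is
monotone in the information order (`*` below both 0 and 1), so values only
ever resolve and the iteration reaches its least fixed point in at most one
sweep per node; the scheme is deterministic and update-order independent.
Nodes on cycles that no defined value reaches stay `*` — e.g. a mutual
activation loop whose external support is absent has both all-0 and all-1
as two-valued fixed points, and the three-valued least fixed point honestly
reports the ambiguity. Delay-flagged degradation edges are excluded from
the iteration, so results are the pre-degradation response; the model lists
the ignored edges.

Species equivalence classes enumerate all `2^k` completions of the
scenario's undefined inputs (`k ≤ 16`), compute steady states, and group
nodes by their value vectors; nodes with constant vectors are
input-independent and belong to no class. Minimal intervention sets search
subsets of candidate nodes (all site and basal nodes except the scenario's
stimulus inputs; the target itself is a legitimate candidate — blocking a
binding site is a bona fide intervention) fixed to 0, of size ≤ k_max ≤ 4,
keeping sets that drive the target to the definite opposite of the value to
prevent; supersets of hits are pruned, so the result is an inclusion-minimal
antichain. The insulin-stimulation scenario used in the examples fixes the
insulin basal input to 1, EGF to 0, and all other basal inputs to 1.

## Fixtures and the synthetic-data generator

The **small example** (A and B binding receptor R; two coupled
phosphorylation sites) is constructed so that, at the default thresholds
0.01/0.1, the phosphorylation of R.p1 discretizes to an OR over its two
inputs and R.p2 to the identity on R.p1 — rates 0.001 (off-context) and
1–2 (on-context) with `k_bw = 1`.

The **EGF–insulin crosstalk fixture** is a synthetic reconstruction: the 18
processes and their influence structure follow the published description
(two mutually influencing insulin-binding processes feeding both receptor
phosphorylation sites; Shc/IRS docking gated by phosphorylation; Shc shared
between the receptors; Grb2 recruited to phospho-Shc and, through one SH2
site, to both phospho-IRS sites — the shared-site special case; EGF binding
and EGFR homodimerization coupled bidirectionally), but the original
per-rule rate constants are not reprinted here. Equilibrium constants are
drawn from the ladder {0.001, 0.01, 0.1, 0.25, 1} and placed so that the
documented qualitative behavior holds exactly: at `t1 = 0.01, t2 = 0.1` the
reference model M; at 0.1/0.25 (`M_up`, thresholds moved to the next larger
occurring values) EGF binding additionally requires dimerization and the
insulin sites mutually inhibit; at 0.001/0.01 (`M_down`) the IRS/Shc
phosphorylation processes lose their binding requirement. The realized edge
sets nest, `M_down ⊂ M ⊂ M_up`. What passing these fixtures shows is that
the *transformations* (rules, discretization, logic, analysis) behave as
specified — not that the encoded rate values are the experimentally fitted
ones.

The **random-PIM generator** (seeded, reproducible) emulates the structural
variety of real models — mixed process types, AON edges only from a
modification onto a binding at the modified site, influences only between
molecule-sharing processes, occasional shared binding sites producing
mutual exclusion — with table values from a fixed ladder spanning the
threshold bands. It does not emulate realistic kinetic magnitudes,
molecule copy numbers, or biological network motifs beyond these local
constraints; property tests on it certify structural invariants
(context-count formula, round-trip identity, graph bijections), nothing
quantitative.

## Numerical and degenerate-input choices

* Steady-state iteration cap |nodes| + 1 sweeps; exceeding it is an
  internal error (monotonicity makes it unreachable).
* Tables whose every row is `*` raise at gate synthesis; random models can
  legitimately produce them, and callers are expected to adjust thresholds.
* A no-input table with `y = 0` yields the constant-false gate.
* `k_eq` is undefined for irreversible rows and for `k_bw = 0`; both raise.
* Problem sizes used by the shipped analyses: 18 processes / 36 rules /
  27 L-nodes for the crosstalk model; 2 undefined inputs (4 completions)
  for classes; k_max = 2 over 25 candidates for intervention sets; property
  checks run on 300 random PIMs and 60 random gate tables per invocation,
  sizes chosen to exercise all structural cases while keeping a full run in
  seconds.

## Known limitations

* Synthesis processes, compartmental models (cBNGL) and ODE/stochastic
  simulation are out of scope; the emitted BNGL is meant for external
  tooling.
* Degradation is single-molecule only, and its delayed inhibition is
  excluded from steady states rather than given timed semantics.
* The equivalence-class definition is operational (identical value vectors,
  `*` counted as a value); edge-case treatment of `*` in other tools may
  differ.
* Intervention-set search is exhaustive and capped at k_max = 4.
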