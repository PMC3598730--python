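# pimkit

Process-Interaction-Models (PIMs) for early signal-transduction events: one
compact process graph that generates **both** a quantitative rule-based model
(BNGL) and a qualitative site-specific logical model, keeping the two
consistent by construction.

## Who this is for

Modelers of receptor-proximal signaling face a combinatorial explosion: a
receptor with *n* modifiable, bindable sites has up to 3^n states. Rule-based
languages (BNGL, Kappa) tame this with the don't-care-don't-write principle,
while logical models answer qualitative questions (can this ligand activate
that adaptor? which knockouts block it?) without rate constants. A PIM is a
single source for both: a directed graph whose nodes are *processes*
(binding, post-translational modification, homodimerization, degradation) and
whose edges are kinetic *influences* — process `j` has different rate
constants depending on whether process `i` has occurred. Each node carries a
parameter table with one row per admissible reaction context, holding the
mass-action rate constants `k_fw`, `k_bw` for that context.

## The formalism in brief

* **Rule generation.** Every process node is a reaction center; each table
  row becomes one reaction rule whose context sites encode the predecessors'
  occurrence. An *all-or-none* (AON) influence restricts a process to
  contexts where its prerequisite occurred (e.g. binding at a site that must
  first be phosphorylated), so AON predecessors add no rows. Mutually
  exclusive predecessors (two bindings competing for one site of the center
  molecule) remove their joint rows. Total rule count = Σ over nodes of the
  admissible-context count.
* **Discretization.** Two thresholds `t1 < t2` map each row's equilibrium
  constant `k_eq = k_fw / k_bw` (the forward constant for irreversible
  processes) to a three-valued output `y`: `y = 1` if `k_eq ≥ t2`, `y = 0`
  if `k_eq ≤ t1`, else `y = *` (unknown). Parameter tables thereby become
  truth tables.
* **Logical model.** L-nodes are created for every molecule site plus one
  basal-activity input per molecule; a one-to-one corresponds-to relation
  links each process to an L-node and transports the PIM's influence edges
  into the interaction graph. Each L-node receives a DNF gate: the
  Quine–McCluskey minimum of its truth table, AND-conjoined with its
  activating inputs. Gates with `*` rows are flagged as
  incomplete-truth-table (ITT) gates.
* **Analysis.** Kleene three-valued synchronous iteration from all-unknown
  yields logical steady states; on top of that the package computes species
  equivalence classes (nodes with identical steady-state vectors over all
  completions of undefined inputs) and minimal intervention sets (inclusion-
  minimal knockout sets blocking a target node).

## Worked example

Two fixtures ship with the package: `small-example` (four processes on a
receptor R bound by A and B) and `egf-insulin`, an 18-process reconstruction
of early EGF/insulin receptor crosstalk (EGFR and insulin receptor, the
adaptors Shc, Grb2 and IRS). From the shell:

```sh
pimkit export-bngl egf-insulin --out model.bngl   # 36 reaction rules
pimkit analyze classes egf-insulin --undef ins,egf
```

prints

```
class	vector	members
1	0011	egf,egf.b1,egfr.b_egf,egfr.d1,egfr.p1,egfr.p2,grb2.b_egfr,shc.b_egfr
2	0101	grb2.b_irs,grb2.b_irs__p18,ins,ins.b1,ir.b_ins,ir.b_ins2,ir.p1,ir.p2,irs.b_ir,irs.p1,irs.p2,shc.b_ir
3	0111	grb2.b_shc,shc.p1
#	input-independent	egfr,grb2,ir,irs,shc
```

With insulin and EGF undefined and every other basal activity present, the
model splits into an EGF-specific class (on exactly when EGF is present), an
insulin-specific class, and a class driven by either ligand — Shc
phosphorylation and Grb2–Shc binding, the crosstalk point. Asking which
knockouts prevent Grb2–Shc binding under insulin stimulation:

```sh
pimkit analyze mis egf-insulin --target grb2.b_shc --kmax 2 --off egf --on ins
```

```
size	knockouts
1	grb2
1	grb2.b_shc
1	ins.b1
1	ir
1	ir.p1
1	shc
1	shc.b_ir
1	shc.p1
2	ir.b_ins,ir.b_ins2
```

i.e. remove a whole protein (rows 1, 4, 6), block a binding site (2, 3, 7),
prevent a required phosphorylation (5, 8), or block both insulin sites on
the receptor together (9). `pimkit sweep-thresholds egf-insulin 0.001,0.01
0.01,0.1 0.1,0.25` shows how the derived logic tightens as the thresholds
rise: the low-threshold variant drops the binding requirement for Shc/IRS
phosphorylation, the high-threshold variant adds mutual inhibition of the
two insulin sites and makes dimerization necessary for EGF binding.

The same functionality is available as a library (`pimkit.build_egf_insulin`,
`export_bngl`, `derive_logical_model`, `equivalence_classes`,
`minimal_intervention_sets`, ...), and PIMs are read and written as a small
YAML document format (see `pimkit.io`).

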