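# Methods

This note documents the models and procedures implemented in `mempis`, the
defaults they use, and what the synthetic benchmarks do and do not show.

## 1. Network model

A metabolic network is an undirected bipartite graph with reaction and
compound nodes and an edge for every participation of a compound in a
reaction.  Two reductions are applied at load time and never revisited:

* **Binary stoichiometry.**  Coefficients are parsed and preserved for
  round-tripping, but connectivity queries and the solver see only the
  participation relation.  This makes the network a pure connectivity model:
  no mass balance, no flux, no thermodynamics.
* **No direction.**  `<=>`, `=>` and `<=` are normalized at parse time
  (`<=` swaps sides); reversibility survives only as metadata.  A reaction
  "connects" all its participants symmetrically.

The loader consumes a TSV dialect (`reaction_id`, `equation`, `ecs`,
`modules`, `pathways`) mirroring the content of KEGG REST reaction entries,
so users can export a KEGG snapshot themselves; there is deliberately no
KEGG API client.  Glycan and generic-polymer entries ("n A") are not
understood — tables must be pre-filtered to well-formed integer-coefficient
equations.

**Currency metabolites.**  Water, ATP, NAD(P)(H), O2, ADP, phosphate, CO2
and H+ (`C00001`–`C00009`, `C00011`, `C00080`) are blacklisted by default.
A blacklisted compound never carries connectivity: without this, nearly any
two reactions are "connected" through water and minimal subnetworks collapse
to meaningless stars around cofactor hubs.  The blacklist is configurable
and may be emptied; the flag is derived only from the blacklist, never from
input files.

## 2. Differential expression and EC selection

Counts are EC-by-sample matrices.  Normalization scales each sample by the
75th percentile of its *nonzero* counts (linear interpolation), rescaled by
the geometric mean of those percentiles so values stay count-like.  All-zero
samples are rejected by name.

The evidence rule for the solver is deliberately simple and strict:

* BH step-up adjustment over all tested ECs: `q_(i) = min_{j>=i} p_(j)·m/j`,
  capped at 1;
* select EC iff `padj < 0.1` **and** `log2FC > 1` (strict inequalities —
  boundary values are excluded).  A stricter report-style preset
  (`padj < 0.05`, FC > 1.5) is available but is not the default evidence
  rule.

Fold changes compare group means of normalized counts with a pseudocount
`c0 = 0.5` (chosen to keep 3-replicate designs finite when a group is
all-zero; results are insensitive to `c0` once counts are ≳ 50, and the
test suite documents the residual sensitivity at counts ≈ 10).

**The p-value engine is a stand-in and pluggable.**  The built-in test is a
two-sample Welch t on `log2(normalized + c0)`.  It is *not* a
negative-binomial count model; with n = 3 per group it is conservative
(low power, see §5), which errs on the side of fewer forced ECs.  Users with
DESeq2 or edgeR output can bypass it entirely: `read_differential_table`
accepts tables with columns `ec, baseMean, log2FoldChange, lfcSE, pvalue,
padj`, and selection then operates on those numbers verbatim.

## 3. The minimal-subnetwork MILP

Variables: binary `y_r` per reaction; binary `z_c` per non-currency
compound (fixed to 1 for measured non-currency compounds); binary witness
selectors `w` (below); continuous flow on directed arc pairs.

Constraints:

* **Coverage** — every measured compound has ≥ 1 active incident reaction.
* **Forcing** — per over-expressed EC, in `at_least_one` mode (default) one
  carrier reaction must be active; in `all` mode every carrier is fixed
  active.  `at_least_one` is the default because a single EC can annotate
  dozens of reactions across unrelated pathways, and forcing all of them
  imports contextually absent chemistry wholesale.
* **Connectivity** — single-commodity flow on the bipartite graph.  The
  terminal set is: measured non-currency compounds; one auxiliary terminal
  per forced EC (`at_least_one`) and per measured currency compound; and, in
  `all` mode, every carrier reaction directly.  The root is the
  lexicographically smallest real-node terminal (an auxiliary terminal roots
  only when no real terminal exists).  Each non-root terminal consumes one
  flow unit, the root supplies |T|−1, non-terminals conserve flow, and each
  arc's capacity is |T| gated by the `y`/`z`/`w` binaries of its endpoints.
  Flow never traverses currency compounds.

**Witness semantics.**  An auxiliary terminal is wired to its candidate
reactions through selectors with `Σ_r w_ar = 1` and `w_ar ≤ y_r`; flow on
those arcs is gated by `w`.  Consequently a forced EC (or a measured
currency compound) attaches to the connected subnetwork through *exactly
one* chosen reaction, and can never itself bridge two otherwise disconnected
parts.  The exhaustive oracle and the solver-independent verifier implement
exactly the same semantics by graph traversal, which is what makes the
oracle-equivalence test meaningful.

**Objective.**  `Σ y + ε Σ z`, with `ε = 1/(2(n_compounds+1))` so the total
compound term can never trade against one reaction; the reaction count is
therefore the true lexicographic objective, and the connector set is minimal
among reaction-count optima.  Deterministic mode (default) adds
`(ε/(2 n_r²))·rank(r)` per reaction — strictly smaller than one ε increment
in total — so the reported optimum is reproducible; alternative optima are
enumerated explicitly (`enumerate_alternates`, integer no-good cuts at the
fixed optimal cardinality) and compared as sets.

**Solver.**  HiGHS branch and bound through `scipy.optimize.milp` — an
exact solver; there is no commercial-solver dependency.  Time limit 300 s
per condition by default; hitting it yields status `within-gap` with the
incumbent, never a silent "optimal".  Infeasible evidence (a measured
compound with no incident reaction; terminals in different components) is
reported as `infeasible` with the violating items named.

Degenerate cases: empty evidence → empty optimal subnetwork; a single
terminal → no flow constraints (coverage/forcing alone); unmapped evidence
ids are partitioned into a reported list by `map_evidence`, never silently
dropped and never fatal.

## 4. Module classification and comparison

A solved subnetwork's reactions are binned by their module annotations; a
reaction with several modules counts once in each (counts are *not*
fractionally split — distributions over modules may therefore sum to more
reactions than were active, which is why correlation uses the normalized
fraction vectors by default; counts are available by flag).  Unannotated
reactions accumulate under `unassigned`.  Two distributions are compared by
Pearson correlation (Spearman optional) over the union of module keys with
absent keys as 0; the coefficient is undefined (NaN, with a warning) for a
1-module union or constant vectors.  Cross-condition tags
(`first-only`/`second-only`/`both`) and cross-network tags
(`common`/`unique`, driving a node-size attribute) are written into GraphML
or GEXF exports with deterministic node order.

## 5. Synthetic benchmarks: what they show

`generate_network` plants a connected chain of `planted_len` reactions
(compound *i* → compound *i+1*), each carrying a unique EC that appears
nowhere else, inside a background of preferential-attachment-wired random
reactions (2–4 non-currency participants each, hub compounds arise
naturally, and ~30% of reactions additionally touch a blacklisted currency
hub).  Background reactions never touch two chain compounds at once, so the
chain is the unique cheapest connector of its own metabolites — the planted
truth is identifiable by construction.  Counts are negative-binomial
(variance μ + α μ², log-normal baseline means, median ≈ 90) with planted
ECs shifted by `2^planted_log2fc` in the treatment group.

Default study conditions: 60 reactions, 45 compounds, 8-reaction chain,
`planted_log2fc = 2`, dispersion `α = 0.1`, 3 replicates per group, full
metabolite coverage.  Under these conditions the pipeline's median Jaccard
between solved and planted reactions over 20 seeds is ≥ 0.8 (the acceptance
script recomputes it), and with no planted effect and no metabolite
evidence the solved subnetwork is empty in ≥ 90% of 100 seeds.

What this does **not** show: real KEGG networks are two orders of magnitude
larger and far denser; real expression signals are not 1:1 EC-to-reaction;
real metabolite evidence is sparse, biased toward identifiable compounds,
and includes compounds far from any transcriptional signal.  Passing the
planted benchmark demonstrates the machinery (selection → constraints →
exact optimization → scoring) is correct, not that recovery rates transfer
to field data.  On the full KEGG-scale problem the MILP remains exact but
runtimes depend on evidence density; the 300 s default time limit plus the
`within-gap` status exist for that regime.

## 6. Soil-physics utilities

`wfps(gwc, Db, Dp)` = `gwc·Db/(1 − Db/Dp)`, with defaults Db = 1.1 g cm⁻³
and Dp = 2.65 g cm⁻³ (a typical mineral-soil particle density); validated
`0 < Db < Dp`.  `co2_flux(dC/dT, V, M, P, T)` converts a headspace CO2
mole-fraction rate to μmol g⁻¹ s⁻¹ via the ideal gas law with
R = 8.3 × 10³ cm³ kPa mol⁻¹ K⁻¹; both are cross-checked in the tests by
independent routes (direct porosity arithmetic; SI-unit mole computation).

## 7. Numerical and reproducibility choices

* Percentile rule: linear interpolation over nonzero counts, fixed.
* All randomness flows from explicit integer seeds (`numpy` Generator); the
  CLI's `simulate` derives sub-seeds by fixed offsets.
* Tabular outputs are written with sorted keys and fixed float formatting;
  two runs of the demo pipeline under the same seed/config are
  byte-identical (graph files are canonicalized by sorted node insertion).
  Wall-clock timing is logged to stderr (line-delimited JSON), not into
  report files, so reports stay byte-stable.
* The acceptance/benchmark problem sizes (200 oracle instances of ≤ 12
  reactions; 20 recovery seeds at 60 reactions; 100 null seeds) were chosen
  as the smallest sizes at which the checks are statistically meaningful.

## 8. Known limitations

* Connectivity is a Steiner-style relaxation: the solver guarantees the
  *terminals* are connected; at optimality the whole active set is connected
  in practice (any disconnected piece could be dropped), but a user-supplied
  solution can be "verified" terminal-connected while containing inactive
  islands — `verify_solution` checks exactly the stated contract.
* The built-in Welch-on-logs test is underpowered at n = 3; treat the
  default selection as conservative and prefer feeding DESeq2/edgeR tables
  for real studies.
* Multi-functional enzymes are handled only through the EC → reactions
  index; isozyme- or taxon-resolved expression is out of scope.
* The equation parser rejects non-integer and symbolic coefficients rather
  than guessing.
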