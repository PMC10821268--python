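# Methods

This note documents the models and procedures mitoflux implements, the
choices made where the design was genuinely open, and what the synthetic
data generators do and do not emulate.

## Decomposable Gaussian graphical model (`mitoflux.ggm`)

### Model

Gene co-expression is modelled as a multivariate Gaussian on
log2(FPKM + 1) whose conditional-independence structure is a chordal
(decomposable) graph. For a decomposable model the maximized log-likelihood
factorizes over a junction tree,

    ll(G) = sum_C ll_C - sum_S ll_S,

with C the maximal cliques, S the separator multiset, and `ll_A` the
maximized Gaussian log-likelihood of the marginal on A,
`-n/2 (|A| log 2π + log det Σ̂_A + |A|)` at the unrestricted MLE covariance
of the subset. Model complexity is scored by
BIC = -2 ll + df log n with df = 2p + |E| (a mean and a variance per gene
plus one free parameter per edge). Only BIC *differences* along the search
path matter, and they are invariant to the 2p mean/variance constant.

### Structure search

1. **Tree initialization.** The maximum-likelihood spanning tree over the
   genes. The likelihood gain of joining two genes is
   `-n/2 log(1 - r²)`, strictly increasing in |r| (Pearson correlation of
   the log2 data), so Kruskal's algorithm on that weight gives the
   Chow-Liu tree. Ties are broken lexicographically by gene-id pair, making
   the tree unique.
2. **Forward selection.** Greedy addition of the single edge with the
   largest BIC reduction among the *addable* edges — the non-edges whose
   addition keeps the graph chordal. For a chordal graph, a non-edge
   (u, v) is addable iff the common neighborhood N(u) ∩ N(v) separates u
   from v (or the endpoints lie in different components); the common
   neighborhood of a non-adjacent pair in a chordal graph is itself a
   clique, so a legal addition creates exactly one new maximal clique
   {u, v} ∪ S with S = N(u) ∩ N(v). The likelihood change is closed form:
   `Δll = -n/2 log(1 - ρ²_{uv·S})`, with ρ the partial correlation of u
   and v given S, and Δdf = 1. The loop stops when no addable edge reduces
   BIC, a local BIC minimum. Ties again break lexicographically.

Chordality is verified by maximum-cardinality search plus a
perfect-elimination check; cliques come from the elimination ordering and
separators from a maximum-weight spanning tree of the clique graph. The
closed-form edge delta, the clique-decomposition likelihood and the
addability criterion are each cross-checked in the test suite against
independent oracles (full rescoring, direct density evaluation at the
IPS-fitted constrained MLE, and per-edge chordality retesting on all
connected chordal graphs with ≤ 6 vertices).

Genes with zero variance cannot enter the correlation step;
`build_network` drops them up front, and the individual operations raise,
naming the offending gene.

### Branches, functional nodes, activities

The fitted network is partitioned into branches by divisive community
detection: edges are removed in decreasing edge-betweenness order
(Girvan-Newman) and the partition sequence is cut at the maximum of
**modularity density**, `Q_d = sum_c (2 e_in(c) - e_out(c)) / |c|`.
Newman-Girvan modularity was evaluated first and rejected: at this
package's typical scale (tens of genes, modules of ~6) its resolution
limit makes merged partitions score above the true module structure, so
the cut under-splits; modularity density is parameter-free, deterministic
and does not suffer that limit. Communities smaller than `min_size` are
merged into the neighbor they share the most edges with.

Each branch becomes a functional node. Labels come from a one-sided
hypergeometric enrichment against a user-supplied gene-set collection
(GMT), Benjamini-Hochberg adjusted across candidate sets — an offline
replacement for web-service ontology tools, chosen for reproducibility.
Node **activity** is the arithmetic mean of the member genes' raw
abundances per sample; activities are compared across condition groups
with the tie-corrected Kruskal-Wallis test (chi-square null on
groups − 1 df). A group needs at least two samples.

## Expression-constrained FBA (`mitoflux.fba`)

Reaction capacity is tied to transcription in four steps, per sample:

1. **GPR resolution.** Each gene-protein-reaction boolean rule is parsed
   (AND binds tighter than OR; n-ary flattening) and evaluated with OR as
   the **sum** and AND as the **minimum** of its operands — isozymes add,
   complex subunits limit. A gene absent from the expression matrix acts,
   under the default `partial` policy, as the identity of its parent
   operator (0 in an OR, skipped in an AND if a sibling resolves); a rule
   with no resolvable leaf is ABSENT and leaves the reaction at default
   bounds. A `strict` policy raises instead. The policy is configurable
   because published descriptions of partial-rule handling differ.
2. **Max-min normalization** of the resolvable scores onto [0, 1] within
   the sample. If all scores are equal, everything maps to 1: uniform
   expression must not close the network.
3. **Bound injection (E-flux).** A reaction with normalized score s gets
   upper bound `s · UB_default`, and, if reversible, lower bound
   `-s · |LB_default|`. Score 0 closes the reaction; score 1 leaves it at
   defaults. The input model is never mutated.
4. **LP.** Flux through the biomass objective is maximized subject to
   steady state (S v = 0) and the bounds (HiGHS). Optimal solutions
   satisfy mass balance to 1e-6 per metabolite. Infeasible or unbounded
   problems are reported as such in the solution status, never as silent
   zeros. FBA optima are generally non-unique; an optional parsimonious
   step re-minimizes total |flux| at the fixed optimum for a unique,
   loop-free solution.

**Pathway flux activity** sums |v| over the reactions of each subsystem
(absolute values, because signed sums of reversible fluxes can cancel; a
`signed` option restores literal summation). Condition activity is the
mean over the condition's samples (a per-condition-mean-expression mode is
available as a flag), and the treatment effect is
`delta = treated - control`, so a pathway that shuts down under treatment
reads negative.

## G-quadruplex scanning (`mitoflux.g4`)

G4Hunter-style scoring: every base in a run of n consecutive G scores
+min(n, 4), every base in a run of n consecutive C scores -min(n, 4);
A/T/N score 0 and N breaks runs. Windows of 25 nt (default) slide with
step 1; a window whose mean score has absolute value ≥ 1.2 (default, the
published G4Hunter defaults — both are flags) flags a site. Overlapping
qualifying windows of the same sign merge into one hit spanning their
union; the hit's score is the mean base score over the merged interval
and its strand is + for G-rich windows, − for C-rich ones (a quadruplex on
the complement). Refinement/trimming steps of the original tool are not
reproduced.

Circular sequences are first-class: runs, windows, hits and features may
wrap the origin. Coordinates are 1-based inclusive; a wrapped interval is
written with end < start, and BED export splits it into two 0-based
half-open arcs. Wrap-around interval length uses the one-endpoint-
exclusive convention `(L - start) + end` — the convention under which the
mitochondrial control-region amplicon 16,067 → 644 on the 16,569-bp circle
measures 1,146 bp (the fully inclusive count would give 1,147).
`region_extract` by contrast is inclusive of both endpoints.

Hits are annotated by the feature containing their midpoint (first match
in table order; unannotated positions count as other_noncoding). The
bundled rCRS gene coordinate table carries 13 protein-coding, 2 rRNA and
22 tRNA features plus one D-loop interval (16,067–644, matching the
amplicon bounds used throughout). Summary fractions treat rRNA/tRNA as
their own classes; "non-coding" means D-loop plus intergenic.

## Bioenergetics (`mitoflux.bioenergetics`)

Mito Stress Test parameters from an OCR trace with phases
baseline → oligomycin → FCCP → rotenone/antimycin A:

- plateau of a phase = mean of its last 3 points (Seahorse convention;
  the aggregation is not standardized across instruments);
- non_mito = rotenone/antimycin plateau; basal and maximal are reported
  net of non_mito by default (`raw` skips the subtraction);
- maximal = max (not mean) of the FCCP phase, the conventional reading of
  uncoupler-stimulated maximal respiration;
- src = maximal − basal; atp_linked = basal − oligomycin plateau;
  proton_leak = oligomycin plateau − non_mito. By construction
  basal = atp_linked + proton_leak, and adding a constant to the whole
  trace changes nothing.

Indirect calorimetry: RER = VCO2/VO2 and EE = (3.185 + 1.232·RER)·VO2,
with VO2 > 0 enforced.

## Synthetic data (`mitoflux.synthetic`)

All generators flow from a single integer seed through
`numpy.random.default_rng`; no global state. Identical seeds give
byte-identical outputs.

**Expression.** log2 abundance of gene g in sample j is
`mu_g + noise_sd · (sqrt(rho) Z_m + sqrt(1-rho) eps)`: an equicorrelated
Gaussian latent per module, exponentiated to strictly positive FPKM-like
values. Within-module pairs have population correlation exactly `rho` on
the log scale (slightly less after the log2(x+1) pseudocount, noticeably
so for genes near FPKM 1). Baselines `mu_g` are uniform on [0, 12] log2
units, spanning the ~3.5 orders of magnitude a real transcriptome covers.
The Treated group's mt-encoded block is multiplied by
`mt_downregulation_factor` (default 0.5), scaling its expectation exactly;
TreatedInactive is drawn from the Control distribution, emulating an
inactive analogue that modulates no genes. Defaults: 11 modules of 6
genes, rho = 0.7, noise_sd = 1, 6 samples per group (replicate counts in
the emulated design are 4–7 and are configurable). Not emulated: read-level
sequencing noise, library-size effects, batch structure, heavy-tailed
outliers — passing tests say nothing about robustness to those.

**Toy metabolic networks.** A linear uptake → chain → biomass path
(capacity 1 per step, so the biomass optimum is min(uptake, 1)),
optionally a parallel branch that doubles the optimum, and `n_background`
independent uptake→sink transport units. Chain reactions are subsystem
OXPHOS with two-isozyme OR rules over the mt-encoded gene names; branch
reactions are Glycolysis with nuclear isozyme pairs; background units
carry single nuclear-gene rules. The background exists because max-min
normalization is anchored by the extreme scores: in a genome-scale model
the pathway under study contributes ~1% of GPRs and essentially never
sets the anchors, and the toy family must reproduce that proportion or
the anchors themselves become treatment-dependent (halving the block
would then *raise* other reactions' normalized scores). Monte-Carlo
analyses in the tests and acceptance script therefore use
`n_background = 150` (OXPHOS = 3 of 161 GPR reactions) with 20-sample
groups; the analytic failure mode — the top-baseline gene landing in the
mt block — has probability ≈ 6/162 per seed before this sizing.

**Planted G4 sequences.** Background bases are uniform with G/C runs
capped at two, so default scanning yields no background hits; each planted
motif is four G-tracts of 3–4 separated by 1–3 A/T loop bases, T-flanked,
placed with ≥ 60 bases of separation (one motif straddles the origin on
circular backbones when n ≥ 2). Planted intervals are recovered with
sensitivity 1 at default scan parameters by construction.

## Problem sizes

Default analyses run at tens of genes, hundreds of reactions and
kilobase-scale sequences; the structure-learning search is exact at these
sizes (the closed-form edge delta keeps each greedy step O(candidates ×
BFS)). The mitochondrial-genome scan benchmark (109 sites; 82% in
protein-coding features; 45% of non-coding hits in the D-loop; 9 sites in
the D-loop) requires the NC_012920.1 sequence, which is not redistributed
with the package: place a FASTA copy at `data/NC_012920.1.fasta` to run
it. The feature coordinate table needed to reproduce the annotation split
is bundled.

## Known limitations

- The branch-extraction rule substitutes a community-detection criterion
  for a procedure the emulated analysis left unspecified; different but
  defensible criteria (plain modularity, Leiden/CPM) give different cuts
  at small scales.
- FBA pathway activities are reported from one optimum; without the
  parsimonious flag, degenerate parts of the network (e.g. cycles not
  touching the objective) can carry solver-dependent flux.
- The df convention 2p + |E| is one of several in use; it matters only if
  BIC values are compared across tools.
- Hit-to-feature assignment by midpoint is unambiguous but coarse for
  hits straddling feature boundaries.
- The wrap-interval length convention is deliberately origin-excluding;
  `region_extract` is endpoint-inclusive. Mixing the two on wrapped
  intervals differs by one base.
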