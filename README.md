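# mitoflux

Tools for asking, from expression data and sequence alone, whether a
treatment is shutting down mitochondrial function in tumor cells — and for
the bioenergetics arithmetic that goes with the wet-lab follow-up. The
package grew around a recurring analysis pattern in studies of
mitochondria-targeting compounds in cancer (pancreatic cancer stem cells
being the motivating system): transcriptomes of control vs treated tumors
are summarized as a gene network whose branches behave as functional
units, the same expression is pushed through a genome-scale metabolic
model to see which pathways lose flux, the mitochondrial genome is scanned
for G-quadruplex-prone sites a DNA-binding compound could target, and
respirometry/calorimetry traces are reduced to their standard parameters.

Four analysis stages, each usable on its own, plus seeded generators that
make every stage testable without any download:

1. **`mitoflux.ggm`** — decomposable Gaussian graphical models of gene
   co-expression: maximum-likelihood spanning tree, then greedy
   decomposability-preserving edge addition to a local minimum of
   BIC = −2 ℓ + df·log n, where the Gaussian log-likelihood factorizes
   over the junction tree as ℓ = Σ_C ℓ_C − Σ_S ℓ_S. Network branches
   (edge-betweenness communities, cut at maximal modularity density)
   become functional nodes; node activity is the mean expression of the
   member genes, compared across groups by Kruskal–Wallis tests, with
   offline hypergeometric gene-set enrichment for labels.
2. **`mitoflux.fba`** — expression-constrained flux balance analysis:
   GPR boolean rules evaluated with OR = sum, AND = min; scores max–min
   normalized to [0, 1] and injected as reaction bounds (E-flux); biomass
   maximized by linear programming; pathway flux activities
   (Σ|v| per subsystem) and treated-minus-control deltas.
3. **`mitoflux.g4`** — G4Hunter-style G-quadruplex scanning with
   first-class circular-genome support (runs, windows, hits and features
   may wrap the origin), plus feature annotation against a bundled human
   mtDNA gene table.
4. **`mitoflux.bioenergetics`** — Mito Stress Test parameters (basal,
   maximal, SRC = maximal − basal, ATP-linked, proton leak,
   non-mitochondrial OCR) and indirect calorimetry
   (RER = VCO2/VO2, EE = (3.185 + 1.232·RER)·VO2).

`mitoflux.synthetic` generates the inputs with known ground truth:
grouped expression matrices with correlated gene modules and a
down-regulated mtDNA-encoded block in the treated group, small feasible
metabolic models with GPRs and an analytically known biomass optimum, and
sequences with planted quadruplex motifs. See `docs/methods.md` for the
models, conventions and limitations.

## Worked example

Simulate a 60-sample cohort (Control / Treated / TreatedInactive, 11
correlated modules of 6 genes, mt-encoded block halved under treatment),
fit the network, and test node activities:

```sh
$ mitoflux simulate expression --seed 1 --n-per-group 20 --out sim
wrote 66 genes x 60 samples to sim
$ mitoflux ggm --expr sim/expression.tsv --groups sim/groups.tsv --min-branch 3 --out net
66 genes, 113 edges, 11 functional nodes; BIC 8321.39
```

The 11 planted modules come back as 11 functional nodes. In
`net/nodes.tsv` the mtDNA-encoded block is node 10
(`MT-0001 … MT-0006`), and `net/comparison.tsv` shows it is the node with
the strongest group difference — Kruskal–Wallis H = 14.31, p = 7.8e-4 —
because its activity drops in the Treated group while the inactive
analogue tracks Control.

Push the same expression through a toy metabolic network whose OXPHOS
chain is wired to the mt-encoded genes:

```sh
$ mitoflux simulate model --seed 1 --chain-length 4 --branch --out toy
wrote 29-reaction model (optimum 2.0) to toy
$ mitoflux fba --model toy/model.json --expr sim/expression.tsv --groups sim/groups.tsv --out flux
             Treated  TreatedInactive
Glycolysis  0.007513        -0.061547
Exchange   -0.005354        -0.021564
OXPHOS     -0.023575        -0.003146
Transport   0.000000         0.000000
Biomass    -0.005354        -0.021564
```

The OXPHOS delta is negative for the Treated condition (flux activity
lost relative to Control) and an order of magnitude smaller for the
inactive analogue — the direction the method is built to detect.

Scan a circular sequence with planted quadruplex motifs:

```sh
$ mitoflux simulate sequence --seed 1 --length 5000 --circular --n-planted 3 --out seq
$ mitoflux g4scan --fasta seq/sequence.fa --circular --out g4out
synth_1: 3 hits
$ head -4 g4out/synth_1.g4.tsv
# mitoflux 0.1.0 format=g4hits window=25 threshold=1.2 circular=True
start	end	strand	score	length
2549	2593	+	1.1556	45
4849	4890	+	1.0476	42
```

All three planted motifs are recovered; the third hit (4975 → 25) wraps
the origin and is reported once with end < start. Library equivalents of
every command live in the modules named above, e.g.:

```python
from mitoflux import g4
g4.circular_interval_length(16067, 644, 16569)   # -> 1146 (D-loop amplicon)
```

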