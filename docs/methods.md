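# Methods

## Update semantics

A logical network is a set of named Boolean nodes.  *External* nodes model
extracellular stimuli and carry no rule; *internal* nodes carry one Boolean
rule over other nodes (`!`, `&`, `|`, parentheses, and the constants `0`/`1`;
NOT binds tightest, OR loosest).

One simulation iterates a discrete-time stochastic map:

1. every external node is independently resampled ON with probability
   `level/100`, where `level` ∈ [0, 100] is that simulation's activity level
   for the stimulus;
2. every internal node synchronously evaluates its rule on the previous
   state;
3. perturbation overrides are applied last: knocked-out nodes are set to 0,
   forced nodes are resampled ON with probability `forced_level/100`,
   ignoring their rule entirely (the "activator" semantics: forcing is
   independent of the node's upstream regulators).

The *activity* of a node is 100 × (fraction of ON states over the trailing
window).  Defaults follow the experimental protocol: 800 iterations,
window 300, 1,000 simulations per experiment.  External resampling at every
iteration is the default; holding the externally drawn state fixed for a
whole simulation is available as a config flag (`resample_external=False`)
since either convention is defensible for platform-style simulators —
per-iteration resampling is what produces graded dose-response curves from
Boolean rules, which is why it is the default.

Initial states: internal nodes Bernoulli(0.5) by default (no bias toward any
attractor); `all_off` and fixed assignments are available.  External nodes
start from a Bernoulli draw at their level.  Perturbation overrides apply to
the initial state too, so a knocked-out node is OFF in every row of the
trajectory.

Randomness: each simulation consumes one NumPy `Generator`.  Draw order is
fixed (initial-state uniforms, then the iteration × external block, then the
iteration × forced block), and experiment simulation `i` uses the stream
seeded `base_seed + i`, so every result is a pure function of its arguments
and seeds, and trajectories are bit-identical across re-runs.

## Exact oracle

For ≤ 12 nodes the map above is a Markov chain on `2^n` states whose
transition matrix factorizes into a deterministic part (internal nodes) and
independent Bernoulli bits (external/forced nodes).  `stationary_oracle`
builds the matrix exactly, propagates the initial distribution for the full
horizon, and averages per-node ON-probabilities over the trailing window —
the exact expectation of the simulated activity, with no sampling.  The
engine is accepted when 1,000-simulation means match the oracle within ±2
activity points per node on 20 random 8-node networks.

Those oracle-equivalence fixtures use the generator's *acyclic* mode
(regulators drawn from inputs and earlier nodes): a ±2-point band on a
finite-window Monte-Carlo mean presumes the window average forgets the
initial state, which input-driven feed-forward networks do within a few
steps.  Cyclic networks can freeze their initial condition (e.g. a
self-loop `A = A` makes each simulation's window average 0 or 100), leaving
irreducible cross-simulation variance of up to 100·√(0.25/1000) ≈ 1.6 points
per node; cyclic semantics are therefore tested separately with tolerances
derived from that variance.

## Environments and genotypes

The three tissue conditions assign each of the 29 stimuli a category
(Zero, Low, Med, Med-High, High, or Full-Range; e.g. ECM is High in all
three conditions, GP130 zero everywhere, and IL-10 is Med / High /
Full-Range in wild type / Disease A / Disease B).  Categories map to
subranges of [0, 100]:

| category | randomized draw | fixed level |
|----------|-----------------|-------------|
| Zero     | {0}             | 0           |
| Low      | [0, 33.3]       | 25          |
| Med      | [33.3, 66.7]    | 50          |
| MedHigh  | [50, 83.3]      | 75          |
| High     | [66.7, 100]     | 90          |
| FullRange| [0, 100]        | (always drawn) |

The *randomized* mode (default) draws each simulation's level uniformly
from the subrange, reconciling categorical environments with per-simulation
random levels; the *fixed* mode pins levels for reproducible
single-variable sweeps and is the background for dose-response curves
(wild-type condition; inputs without a table entry, including the GPCR
ligands and the CAV1 activator, default to 0).  Both modes are exposed;
neither is claimed to be the platform's exact internal procedure.

Genotypes map one-to-one onto perturbations: WT → none; KO → clamp CAV1
OFF; Het50 → force CAV1 at level 50 (one functional allele ≈ active half
the time); RandomActivation → force at a level drawn uniformly per
simulation.  Ranking compares a perturbed genotype against the wild-type
genotype *within* the same environment, by signed difference of mean
activity (ratios were rejected because baseline activities of 0 occur).
Ties in |Δ| break lexicographically.

## The reference T-cell model

The packaged model (46 internal nodes, 32 inputs) is a
faithful-in-named-interactions miniature, not a reconstruction of any
larger model: every internal edge encodes an interaction with a documented
qualitative direction (see the annotations in
`src/cav1net/data/reference_tcell_manifest.tsv`), and the Boolean forms are
this package's own construction, chosen so the model meets its qualitative
constraints:

* CAV1 is an AND-term in LCK, FYN, Integrin, and KSR1 — knockout silences
  the TCR-proximal, integrin/actin, and RAF/MEK/ERK branches;
* CAV1 appears negated in CD26, BCL10, RAC1, and GATA3 — knockout
  up-regulates them;
* CD28, PI3K, and AKT contain no CAV1 dependency — the costimulatory branch
  is genotype-invariant;
* the six validated stimulus→readout pairs (APC→ERK, ECM→F-actin,
  GαQ→PI3K, ECM→MAPK, IL-2→MAPK, Gα12/13→Cdc42) are monotone by
  construction (no negative path from the swept input to the readout).

`MAPK` is a pathway-level readout (ERK AND sustained receptor engagement
via integrin or IL-2R) so that cytokine and matrix inputs register on the
cascade without saturating it.  Cytokine receptor complexes follow their
biology (IL-6R and IL-27R require gp130 — which the environment table holds
at zero; IL-15R shares the IL-2R β chain); remaining stimuli feed
pass-through collector nodes (γ-chain, STAT3, Th1 inputs) that do not gate
the tested phenomena.  Within leukemia cohorts some of these molecules
correlate *positively* with CAV1 (e.g. BCL10); the logical model encodes
the knockout direction observed in tissue, and the cohort-level
correlations are handled exclusively by the expression module's planted
targets — the model does not try to explain both at once.

The model is frozen by a SHA-256 digest of its canonical rule text, checked
at test time against the builder and both packaged serializations.

## SBML-qual dialect

Models are exchanged as SBML Level 3 + qual (Boolean dialect): every
species `maxLevel="1"`; external nodes are species without transitions;
each internal node has one transition with MathML `and`/`or`/`not` over
`eq(species, 1)` function terms, result level 1, and a default term of 0;
constant-1 rules serialize as `<true/>` and constant-0 as a default-only
transition.  Multi-valued species, missing default terms, and unknown
MathML are rejected with specific messages.  Round trips preserve every
rule's full truth table (tested exhaustively for the packaged model).

## Expression analysis

Fold-change is log2(group mean / control mean) per gene — logs make
up/down symmetric, which the clustering metric expects.  Clustering is
agglomerative on distance 1 − similarity with *unweighted* average linkage
(UPGMA): inter-cluster distance is the mean over all original item pairs,
recomputed exactly at each step (the definitional algorithm; n is small).
The default similarity is uncentered correlation (cosine), the classic
Cluster 3.0 metric; ties break toward the lowest cluster ids, and the
`.cdt`/`.gtr` writers emit Java TreeView-loadable files.  "Pearson
regression" against CAV1 is the product-moment correlation across the
subtype fold-change columns (healthy is the denominator, not a column);
slope and intercept are also reported.  Whether per-sample or
per-subtype-mean profiles are the right unit is not settled; per-subtype
means without a healthy column are used, and both choices are documented
here.

The synthetic generator plants correlations by construction: reference
profile `z ~ N(0, I)` over the columns, gene `g = r·z + √(1−r²)·ε`.  Its
default planted map is the reported ATL signature (BCL10 0.947, DEC2 0.782,
SHP2 0.742, GATA3 0.694; SOS1 −0.981, FYN −0.949, SOS2 −0.825, CD26
−0.740).  At 100 columns the sampling sd of a recovered r is (1−r²)/10
(≈ 0.05 at r = 0.7), so recovery is accepted on the cross-seed mean (20
seeds, band ±0.1 ≈ 8σ) plus per-seed sign and rank agreement.  At the
cohort's own 4-column width the pipeline runs and reports r, but no
accuracy claim is made — the 4-column sampling spread of r spans most of
[−1, 1].

The generator emulates planted *correlation structure only*: real cohort
data add array-normalization artifacts, patient heterogeneity within
subtypes, and gene-gene correlations beyond the planted ones, so passing
recovery tests demonstrates the estimator and pipeline, not robustness to
those effects.

## Problem sizes and numerical choices

Experiments use the full protocol (1,000 simulations × 800 iterations,
window 300).  Dose-response curves use an 11-point grid with 30
simulations per level.  Oracle equivalence uses 20 networks of 8 nodes;
clustering oracles cover all sizes 2–8.  The simulation engine lowers rules
to truth tables (≤ 20 regulators per node) and runs batched across
simulations, so the whole acceptance recomputation finishes in well under a
minute on one CPU.  Floating-point output is fixed at six decimals in CSV
writers so that seeded re-runs are byte-identical.

## Known limitations

* The reference model is a miniature built from named interactions; it does
  not reproduce any specific large model's rankings, and nodes outside the
  constrained subgraph (collectors, endpoints) are plausible rather than
  anchored.
* Synchronous-update semantics with per-iteration resampling is one of
  several defensible stochastic schemes for logical models; asynchronous
  update orders are not implemented.
* The exact oracle is limited to 12 nodes (dense 4096² transition matrix);
  beyond that, verification is statistical.
* Expression analysis starts from a normalized genes × samples matrix;
  microarray preprocessing, differential-expression testing, and cohort
  retrieval are out of scope.
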