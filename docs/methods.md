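# Methods

`phyloframe` implements a complete supermatrix phylogenetics workflow for a
mixed mitochondrial + nuclear data set of the kind assembled for a
family-level fish radiation: alignment with stability filtering, partitioned
supermatrix assembly, parsimony / likelihood / Bayesian tree inference with
compartment-partitioned supports, RY recoding and compositional diagnostics,
likelihood-based topology tests, and penalized-likelihood divergence dating
with fossil calibrations. This note records the models, the numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## Data model

A `CharacterMatrix` is a taxa × sites byte matrix over a DNA, RY (purine /
pyrimidine) or multistate alphabet. `?` (unsampled) and `-` (alignment gap)
are both treated as fully unobserved everywhere: likelihood integrates them
out, parsimony assigns them no state, and completeness counts them as
missing. This matches a workflow in which long indels are excluded rather
than scored. A `PartitionMap` tiles the matrix with named, disjoint gene
ranges tagged by genome compartment (mito / nuclear / morphology) and codon
position; it is the unit for per-gene models, rates, stratified resampling
and partitioned supports. Internally all coordinates are 0-based half-open;
files are read and written 1-based inclusive (the PHYLIP/RAxML convention).

## Synthetic data generator

The generator produces data with the statistical structure the downstream
analyses assume, with known truth:

* **Tree**: birth–death topology conditioned on the number of extant tips
  (dendropy), rescaled to a fixed root age. Defaults: 63 taxa, birth 0.09 /
  death 0.03 per MY, root at 59.1 MY. Because the conditioned simulation
  stops exactly at the last speciation event, every tip branch is extended
  by one exponential no-event waiting time so no terminal branch has zero
  length (dating requires positive terminal branches); ultrametricity is
  preserved.
* **Rates**: strict clock, or an autocorrelated lognormal clock in which a
  child branch's log-rate is normal around its parent's with variance
  sigma^2 × branch duration (default sigma^2 = 0.02 /MY — strong enough
  heterogeneity that the clock LRT rejects at family scale). The base rate
  0.00155 substitutions/site/MY corresponds to a pairwise divergence rate
  of 0.31 %/MY, the scale reported for salmonid mitochondrial genes.
* **Sequences**: GTR+G+I simulation along the dated tree, per-site rate
  categories drawn from the discrete gamma + invariant mixture. The default
  33 partitions comprise 16 mitochondrial blocks (13 genes, a 1.5 kb
  concatenated tRNA block, and two cytochrome genes of 1141 and 1551 bp)
  with fast rates, strong transition bias and AT-rich composition, and 17
  slower, compositionally symmetric nuclear genes.
* **Compositional bias**: designated mitochondrial partitions switch to a
  second, more biased stationary composition on the terminal branches of
  one root-adjacent clade (a two-regime, non-stationary process). This
  gives the chi-square homogeneity test true positives that RY recoding
  removes when the bias is confined to transitions.
* **Missingness**: whole gene-by-taxon blocks are deleted at random until
  completeness reaches the target (default 22.9%), under the retention
  rules that every taxon keeps at least one gene and every gene at least
  four taxa — the way a GenBank-mined supermatrix is actually sparse.
* **Introgression**: a mitochondrial-capture event replaces the recipient's
  mito sequences with copies diverged from the donor tip t MY ago. Under a
  reversible model this is simulated locally by evolving the donor's
  sequence for 2t MY, which has the correct marginal distribution. Event
  strength (the capture age t) is a free scenario parameter.

Everything is driven by one integer seed; identical seeds give identical
output. The generator does **not** emulate coalescent gene-tree
discordance, alignment error in the input sequences, sequencing error, or
indel evolution; passing tests demonstrate correctness of the estimators
under the generating model, not robustness to those real-data features.

## Supermatrix assembly

Progressive alignment uses Gotoh affine-gap dynamic programming
(match +1, mismatch −1, configurable gap open/extend), a neighbor-joining
guide tree built from pairwise p-distances (scikit-bio NJ; ties broken by
taxon-label order), and profile–profile merges scored by mean pairwise
column score. The gap-parameter sweep re-aligns under a 3 × 3 grid of
(open ∈ {3, 9, 15}) × (extend ∈ {3, 5, 7}); the stability filter keeps a
column of the reference alignment only if its homology statement — the
exact set of (taxon, residue-index) pairs it asserts — recurs in every
sweep alignment (an agreement fraction below 1 is configurable). Columns
inside any maximal gap run longer than 2 bp in any taxon are excluded.
Concatenation takes the taxon union, fills unsampled blocks with `?`, and
merges designated genes (e.g. 22 tRNAs) into single partitions.

RY recoding maps A,G,R→R and C,T,Y→Y; every other ambiguity code, `?` and
`-` become `?`. The chi-square homogeneity test is a taxa × states
contingency test on observed counts (`scipy.stats.chi2_contingency`,
states with zero total count dropped). Note the test is calibrated for
independent rows; phylogenetic correlation (shallow cherries) makes it
conservative, so the type-I calibration experiment uses a long-branch star
tree, where taxon compositions are effectively independent draws.

## Parsimony

Fitch scoring is bitmask-encoded and vectorized over sites; ambiguity codes
are state sets. The heuristic search is random-order stepwise addition
followed by SPR hill-climbing, pooling all equally parsimonious trees
(deduplicated by split set, pool capped at 1000) across random-addition
replicates; strict consensus collapses splits absent from any best tree.
SPR is the default swap; it matches exhaustive enumeration on the problem
sizes the package targets and stays testable against the full-enumeration
oracle.

Bremer support runs a reverse-constraint search (trees containing the
focal split score +infinity); the partitioned decomposition takes per-site
Fitch step differences between the best unconstrained and best
reverse-constrained tree, summed within compartments, so components add
exactly to the total. When several optimal trees exist the first canonical
pair is used. The Templeton test applies the Wilcoxon signed-rank test to
nonzero per-site step differences (exact null for ≤25 nonzero differences,
normal approximation with continuity correction beyond).

## Likelihood

Time-reversible models (JC, K80, HKY, TIM, GTR; a 2-state model for RY
data) with discrete-gamma (4 mean-category rates) and invariant-sites
mixtures; rate matrices are rescaled to one expected substitution per unit
branch length and diagonalized in the symmetric √π form. Felsenstein
pruning runs on compressed site patterns with per-node max scaling. The
invariant class is a zero-rate category, so no special casing is needed.

Branch lengths are optimized coordinate-wise (bounded Brent per branch) to
a total-lnL tolerance of 1e-6; the tree search hill-climbs over SPR
neighborhoods with one quick re-optimization sweep for candidate moves and
a full re-optimization on acceptance. Model selection fits the 20-model
ladder {JC, K80, HKY, TIM, GTR} × {-, +G, +I, +G+I} on one NJ topology with
branch lengths held fixed (optimized once under HKY+G), using empirical
base frequencies, warm-starting each fit from its nested submodel and
refitting when a nested model scores higher; winners by AIC, BIC, or
hierarchical LRTs. Fits with three or more free parameters use L-BFGS-B
(Nelder–Mead reliably stalls in ≥3 dimensions on these surfaces).

The ML bootstrap resamples columns within partitions (preserving each
gene's share of the matrix) and reports split frequencies across replicate
searches.

The clock LRT compares free branch lengths against a strict-clock fit with
node heights parameterized as root height × nested sigmoid proportions
(monotonic by construction), optimized by Nelder–Mead with multiple height
scales and an L-BFGS-B polish; the statistic is referred to chi-square with
n−2 degrees of freedom. Per-gene relative rates follow the distance-
regression idea: per-gene pairwise ML distances are regressed through the
origin on reference-tree patristic distances and the slopes normalized to
mean 1 — the cheap approximation appropriate for ranking 30-odd partitions.

## Bayesian inference

A single-chain Metropolis–Hastings sampler: NNI topology proposals (the
NNI neighborhood has constant size on binary unrooted trees, so the
proposal is symmetric), branch-length multipliers (Hastings ratio equal to
the multiplier) against an Exponential(10) prior, and multiplier/window
proposals on each partition's gamma shape (Exponential(1) prior) and
invariant proportion (uniform on [0, 0.95]). Exchangeabilities and base
frequencies stay at their input values. Metropolis-coupled heating is not
implemented; instead independent runs from random starting trees are
compared by average split-frequency deviation, the standard two-run
convergence diagnostic. Prior-only runs (likelihood switched off) are used
to validate the sampler: topologies uniform, branch lengths exponential.

Default burn-in is 25%, with a trace-based heuristic available (first
window whose mean lnL falls within one SD of the final quarter). The root
posterior map prunes the outgroup from each post-burn-in tree and records
the ingroup split of the branch it attached to; a non-monophyletic
outgroup is counted at its MRCA's attachment and tallied. Aggregation over
named clades credits a branch to every group that contains one side of its
split, so a branch bounding two groups contributes to both.

## Topology tests

All (2k−5)!! unrooted backbones over k ≤ 8 group labels are enumerated by
recursive leaf insertion and rooted on the outgroup label. Constraints are
resolved by freezing each group's subtree from the unconstrained ML tree
and re-optimizing branch lengths. The SH test uses RELL resampling with
the centered-maxima null; the AU test fits signed distance d and curvature
c by weighted least squares to Φ⁻¹(1−BP(r)) = d√r + c/√r over ten scales
0.5–1.4 (binomial delta-rule weights), reporting p = 1 − Φ(d − c).
Degenerate scales (BP ∈ {0,1}) are dropped; with fewer than three
informative scales the naive bootstrap proportion is returned (this also
makes the single-scale limit exactly the naive BP). No multiple-testing
correction is applied across candidate topologies.

## Divergence dating

Penalized likelihood maximizes Σ_j [x_j ln μ_j − μ_j] − λ·P(r), where
x_j is the branch's expected substitution count (ML branch length ×
alignment length), μ_j = r_j t_j × alignment length, and P(r) penalizes
squared differences of parent–child branch rates plus the variance of the
root-adjacent rates. The penalty is computed on mean-normalized rates, so
λ is dimensionless: the λ→∞ limit is then exactly the strict clock
regardless of the absolute rate scale (with raw rates of order 1e-3 the
clock limit is numerically out of reach at any practical λ).

Ages are parameterized as root age × nested sigmoid proportions with
static lower bounds propagated from fixed and minimum calibrations, so age
monotonicity and constraint feasibility hold by construction; rates are
log-parameterized. Optimization is L-BFGS-B warm-started from the
single-rate (clock) solution, with jittered restarts. At least one fixed
calibration is required (minimum ages alone leave the rate × time product
unidentified). Stem calibrations attach to the parent of the clade's MRCA,
crown calibrations to the MRCA itself. Zero-length terminal branches are
rejected with instructions to prune.

λ is chosen by leave-one-terminal-out cross-validation on the default
21-value log grid spanning 0.1–10000: each tip is pruned, the model
refitted, and the tip's substitution count predicted as (fitted rate of
the attachment edge) × (midpoint age of that edge), scored by
Σ(obs−pred)²/max(pred, 1). The midpoint-age rule is an approximation — the
attachment node no longer exists after pruning — and contributes an
irreducible floor to the score, which is shared across λ and so does not
bias the selection. Fossil cross-validation refits without each
calibration in turn and flags minimum-age fossils whose constraint the
remaining evidence violates (with 5% / 0.2 MY slack for optimizer noise).
Bootstrap age intervals resample columns within partitions, re-optimize
branch lengths on the fixed topology, refit, and take percentile
intervals.

The divergence rate ρ is pairwise: 100 × (model-corrected tip-to-tip
distance) / (MRCA age), averaged over clade pairs (a per-lineage variant
halves it). Pair rates share tree paths and are strongly correlated, so
the CI comes from a taxon-level bootstrap widened by the curvature
standard error of the pairwise distances (treated as fully shared across
pairs — deliberately conservative) and, when supplied, by calibration-age
uncertainty via the delta rule.

## Problem sizes

The test-suite and validation experiments run at desk scale: oracle
comparisons at 4–7 taxa where exhaustive enumeration is feasible,
parameter recovery at 20 taxa × 5 kb, calibration experiments at 200–250
replicates of 4–6 taxa × 400 sites, and the conflict and rate pipelines at
6–8 taxa with kb-scale genes. The full 63-taxon × ~30 kb generator default
is exercised for assembly and completeness, not for tree inference.

## Known limitations

* The MCMC sampler fixes exchangeabilities and frequencies at their input
  values and does not average over substitution models.
* The SPR-based searches are hill-climbers; on large, conflicted matrices
  they can stop in local optima that PAUP*/RAxML-style searches with TBR
  and randomized restarts would escape.
* The AU implementation follows the standard multiscale-bootstrap fit but
  is not a reimplementation of CONSEL's exact numerics (e.g. its Newton
  refinement of the fit).
* The chi-square homogeneity test ignores phylogenetic correlation, as in
  standard practice; its nominal calibration applies only to deeply
  diverged taxa.
* Penalized-likelihood CIs are branch-length-bootstrap percentiles; they do
  not propagate topology uncertainty.
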