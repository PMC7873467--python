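# Methods

This note documents the statistical models behind `ceranet`, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Paired differential expression (`de.py`)

**Model.** The design is eight patients each contributing one ectopic
(EC) and one eutopic (EU) sample, so the paired contrast reduces to a
one-sample problem on per-patient differences dᵢ = log2(EC)ᵢ −
log2(EU)ᵢ. With so few pairs, per-feature variance estimates are noisy;
we assume the true residual variances follow a scaled inverse
chi-square prior with d₀ degrees of freedom and scale s₀², which makes
the observed s² marginally s₀²·F(d, d₀) with d = n−1. The posterior
variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) yields the moderated statistic
t = d̄ /√(s̃²/n) on d₀ + d degrees of freedom.

**Hyperparameters.** (d₀, s₀²) are fitted by closed-form moments
matching on z = log s²: Var(z) in excess of the trigamma term ψ′(d/2)
identifies ψ′(d₀/2) (inverted by Newton iteration), and the mean of z,
de-biased by the digamma terms of both chi-squares, identifies log s₀².
When the observed dispersion of log-variances does not exceed what a
single shared variance predicts, d₀ is flagged infinite and the pooled
variance is used for every feature. Zero-variance features are excluded
from the fit (they carry no information about the variance
distribution) but still receive a posterior variance. The test suite
cross-checks the fit against the Bioconductor limma implementation on a
fixture; the two agree to several significant digits, as expected since
limma's `fitFDist` is the same moments-matching scheme.

**Gates.** Significance requires Benjamini–Hochberg adjusted p < α
(default 0.05, applied within each RNA class) *and* fold change > 2,
read as |log2FC| > 1 — the standard interpretation on log2 data. Raw
correlation between the two gates is intentional: a large, precisely
estimated 1.5-fold shift stays non-significant by design.

**Degenerate inputs.** Fewer than 3 pairs is an error. An identically
zero difference matrix (EC ≡ EU) returns the trivial null result
(log2FC = 0, p = 1) rather than an error; any other all-zero-variance
matrix (e.g. a constant fill) raises, since variance moderation is
undefined there and the input is almost certainly malformed.

**Known gap.** The stage requires already log2-normalized input and
performs no count modeling, library-size normalization, or precision
weighting; how the original expression matrices were normalized
upstream is the caller's responsibility.

## Hypergeometric pair selection (`network.py`)

A lncRNA (N miRNA partners) and an mRNA (t partners) sharing r partners
from a universe of T miRNAs are scored by the upper tail
P(X ≥ r), X ~ Hypergeometric(T, t, N), summed in log space from cached
log-factorials so large counts do not lose precision to cancellation
(the complementary sum 1 − P(X < r) would). r = 0 returns exactly 1,
so only pairs with at least one shared miRNA are enumerated — an
optimization, not a semantic change. An exhaustive sweep of every valid
instance with T ≤ 60 against exact rational enumeration bounds the
relative error below 10⁻¹².

**The universe T is a modeling decision, not a constant.** "All human
miRNAs" could mean an annotation count (~1,500), the interaction
database's miRNA set, or only the differentially expressed ones, and
every p-value moves with it. Default `interaction-union` counts the
miRNAs present in the DE-filtered interaction tables, which keeps T, t,
N, r internally consistent within one universe; `de-only` and `fixed`
(externally supplied count) are available.

Other choices: DE filtering of miRNAs happens *before* overlaps are
counted (a flag relaxes this); both pair endpoints must be DE (flag to
relax); the 0.01 threshold applies to raw p-values, as is conventional
for ceRNA pair screens — an optional BH mode exists. Positive
co-expression is deliberately not enforced here; correlation gating
belongs to the annotation stage.

## Topology (`topology.py`)

The ceRNA graph is undirected and unweighted (competition is symmetric
and no edge weights are defined). Centralities are computed with
networkx: Brandes betweenness normalized by (n−1)(n−2)/2, and closeness
with Wasserman–Faust component scaling (k−1)/(n−1) · (k−1)/Σd so scores
remain comparable when the network has several components — harmonic
closeness would be the alternative; rankings of the large component are
insensitive to the choice. Rankings break ties lexicographically by
node ID so top-k lists are deterministic. Hubs are nodes in the top-k
(default k = 10) of all three measures. The degree-distribution helper
fits an OLS line to log frequency vs log degree over nonzero bins —
a shape check for heavy tails, not rigorous power-law inference — and
skips the fit below 5 distinct degrees.

## Random walk with restart (`rwr.py`)

P_{t+1} = (1−r)·W·P_t + r·P₀ with r = 0.5, W the column-normalized
adjacency of the bipartite lncRNA-mRNA network (miRNA nodes are not
part of the walk; they mediate edges but the competition network is
what propagates disease signal), P₀ uniform over the seed genes.
Iteration stops when the L1 difference of successive vectors falls
below 10⁻¹⁰ (the norm is a choice; L1 pairs naturally with probability
vectors); with r = 0.5 the map is a 0.5-contraction, so ~35 iterations
suffice regardless of graph size, and the fixed point matches the
direct solve r(I − (1−r)W)⁻¹P₀ to 10⁻⁸ on random graphs. Isolated
nodes have all-zero columns and would leak walker mass, so they are
pruned before the walk. Seed genes absent from the network are dropped
with a warning (disease-gene lists are drawn from external databases;
only the members that made it into the network can seed the walk); it
is an error if none remain.

**Permutation null.** Each of N permutations (default 10,000; scale
down for exploratory runs) draws |seeds| mRNA nodes uniformly without
replacement — only mRNAs can be disease-gene seeds in this network —
re-runs the walk (all permutations propagate as one batched matrix),
and each lncRNA gets p = M/N with M the number of permutations whose
score *strictly* exceeds the real one. A score never exceeded gives
p = 0; an optional (M+1)/(N+1) pseudocount mode avoids exact zeros.
Uniform seed draws bias the null toward low-degree seeds, so a
degree-matched draw is available behind a flag.

## Annotation (`annotation.py`)

Pearson correlation between a lncRNA and each competing mRNA over all
16 samples (both conditions pooled — ceRNA co-expression is claimed
across the dataset; a sample-subset argument restricts to one condition
if preferred), two-sided p from the exact t transform with m−2 df.
Selection requires r > 0 and p < 0.05, uncorrected — the gate is a
screen, not an inference. Selected targets feed an over-representation
test against GMT gene sets using the same hypergeometric tail as pair
selection with (T, t, N, r) = (|universe|, |set|, |query|, |overlap|),
BH-adjusted across sets. This replaces web-service enrichment tools
with an offline, versionable equivalent; specific pathway-term output
therefore depends entirely on the GMT the user supplies.

## Synthetic data (`simulate.py`)

**What it emulates.** The paired study design: 8 patients × EC/EU × 3
RNA classes on log2 scale; planted differential expression (default
30% of features, ±2 log2 units, random sign per feature, Gaussian
noise σ = 0.3); planted ceRNA structure; and miRNA-target tables with
background edges (3 per miRNA). Feature counts (300 mRNAs, 60 lncRNAs,
350 miRNAs) are desk-scale stand-ins for genome-wide profiles, chosen
so the filtered miRNA universe (T ≈ 80–90) is large relative to
per-transcript partner counts, as in real interaction databases.

**Planting model.** Every planted lncRNA owns one fixed miRNA
repertoire (shared_mirna_count + 2 = 7 planted-DE miRNAs, disjoint
between lncRNAs), and each of its competing mRNAs is wired to a random
5-subset of that repertoire — mirroring how a sponge lncRNA has a
single partner set its targets share subsets of. This keeps a hub's
partner count near the repertoire size however many pairs it has, so
planted evidence stays decisively above the background expectation
(~N²·density² ≪ 1 chance overlaps) instead of diluting as pairs
accumulate. One hub lncRNA absorbs 6 of the 10 planted pairs; one
disease-proximal lncRNA is paired with all 4 designated seed genes,
placing it two competing-edge hops from every seed. With frac_de = 0
nothing structural is planted (planting requires DE members) — the
null configuration used for calibration.

**What it does not emulate.** Read counts and their overdispersion,
library-size or batch effects, correlated features, miRNA-mediated
expression coupling (planted pairs are wired, not co-expressed beyond
their shared DE direction), or realistic genome-scale feature counts.
Passing tests demonstrate that the inference chain recovers structure
under its own stated assumptions — not performance on raw RNA-seq.

**Determinism.** One `numpy` Generator seeded by `rng_seed` drives
every draw in a fixed order; identical configs produce byte-identical
fixtures.

## Problem sizes used by tests and the acceptance script

Default synthetic study as above; permutation tests at 1,000 draws
(a scaled-down stand-in for the conventional 10,000 — the planted
disease lncRNA's score is essentially never exceeded, so the 0.01
threshold is decidable at 1,000); null calibration over 50 replicates
of 420 features each (~21,000 pooled tests, binomial SE ≈ 0.0015 on
the 0.05 false-positive rate, asserted within ±0.0075 to allow for the
within-replicate correlation that shared hyperparameters induce);
kernel oracles on random graphs of ≤ 30 nodes and hypergeometric
universes of T ≤ 60.

## Known limitations

- No identifier mapping: expression and interaction tables must use
  one consistent ID space (symbols or Ensembl); mixed spaces silently
  reduce overlap.
- The hypergeometric screen ignores expression correlation and miRNA
  binding strength; edges are evidence of shared partners, not of
  regulation.
- Permutation p-values are granular at 1/N and reported unadjusted
  across lncRNAs.
- The moments-matched prior fit assumes a common variance distribution
  across features of a class; strong variance-mean trends (unremoved
  count noise) violate it.
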