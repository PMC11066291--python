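# Methods

This note documents the models, algorithms and design choices behind
repeatphylo, in the order the pipeline runs them, together with what the
synthetic data generator does and does not emulate.

## Synthetic repeatome evolution

Each repeat family is specified by a consensus sequence, a genomic mass
(Mb) at the root of the species tree, and optional *burst edges*. The
generative model has three layers:

1. **Abundance evolution.** Log-mass evolves by Brownian motion with rate
   σ² on the λ-transformed tree, i.e. the tip vector is drawn from
   N(log m₀·1, σ²·C_λ). Evolving on the log scale guarantees positive
   masses and models repeat turnover as multiplicative amplification and
   loss, which is how retrotransposon copy numbers change. After the BM
   draw, every burst edge multiplies the mass of all tips below it by its
   factor — a stylized hybridization- or polyploidy-triggered
   amplification event placed on a known branch. σ² = 0 gives the
   deterministic limit (tips at base mass times their bursts), which is
   the configuration the standard study design uses: bursts are the
   designed contrast, and any Brownian drift would itself constitute real
   phylogenetic signal in every family.
2. **Sequence evolution.** Optionally, each family's consensus evolves
   along the tree with per-branch substitution probability
   1 − exp(−r·ℓ) per site, giving species-specific repeat variants.
   This layer is what gives inter-species read similarity its
   phylogenetic structure; without it every species reads from an
   identical consensus and the repeat-similarity network carries no
   signal. The default rate r = 0.21 per unit tree height yields ~4–7%
   pairwise divergence within clades and ~20–35% between clades on the
   standard height-1 clade tree.
3. **Read emission.** Each species emits exactly n single-end reads; a
   read comes from family f with probability mass_f/1C, and the
   single-copy remainder emits uniform random sequence. Consensi are
   circular for start-position sampling (no edge-effect
   underrepresentation), and each read site mutates with an independent
   "sequencing divergence" probability (default 0.005). Reads carry their
   family of origin as provenance, used only for evaluation, never by the
   pipeline.

Tandem (5S rDNA-like) arrays are generated separately: n_v monomer
variants share a conserved block (fraction 0.3 of a 120 bp unit by
default) and diverge in the remainder at 0.2 substitutions/site relative
to a common ancestral unit; the array interleaves variants cyclically so
every junction exists, and reads are drawn from the circularized array.

Reproducibility: a single integer seed is forked per species/family by a
stable CRC32 hash of the label, so outputs do not depend on iteration
order and rerunning with the same seed is byte-identical.

**What the generator does not emulate:** paired-end layout and insert
sizes, position-dependent quality error models, LTR element substructure
(LTR/internal domains), nested insertions, and genuine satellite
higher-order repeat structure. Passing tests therefore demonstrate the
statistical machinery on data satisfying the model's assumptions, not
robustness to every artefact of real genome skims.

## Comparative clustering

Two reads are connected when they share ≥ `min_shared` distinct canonical
k-mers (defaults k = 13, min_shared = 8: roughly a 20 bp near-identical
overlap). Clusters are connected components, ordered by total size with
ties broken by the smallest contained read id, so the "top N" cut is
deterministic. Components under 0.01% of the pooled read total are
flagged small; isolated reads form the remainder.

The graph is built from an inverted k-mer index: for every k-mer, all
reads containing it are paired, and a pair's number of index hits equals
its count of distinct shared canonical k-mers, so the result is exactly
the all-pairs graph (property-tested against a brute-force oracle). The
pair multiset is aggregated in fixed-size numpy chunks with periodic
compaction; peak memory scales with the number of distinct overlapping
pairs, not with the multiset. Clustering 200k pooled 150 bp reads from
25 kb consensi takes about a minute and under 4 GB.

Two behaviours of component clustering are worth knowing. First,
single-linkage transitivity means one spurious edge merges two clusters;
at deep coverage, rare chance k-mer homology between unrelated family
consensi (read pairs scoring just past the threshold) can merge families
into one cluster. This is accepted by design — components are exactly
reproducible, whereas community detection is not — and none of the
downstream quantities depend on families mapping 1:1 to clusters.
Second, with highly diverged species a family can split into per-clade
components at shallow coverage; the pipeline requires enough depth that
clusters span all ingroup species before network construction.

## Quantification

Cluster read counts scale to Mb by (count/total)·1C per species; masses
are conserved exactly (cluster + remainder = 1C). The per-species repeat
percentage sums non-small, non-plastid clusters — unclassified repeats
included, single-copy and small-cluster mass excluded — over 1C. Fold
ranges of genome size are max/min rounded half-up to one decimal.

## Pagel's λ and PGLS

The BM covariance C of a rooted tree has C_ij = the root distance of the
MRCA of tips i, j. λ multiplies the off-diagonal of C. μ and σ² are
profiled out analytically (GLS mean, RSS/n), leaving a one-dimensional
likelihood in λ maximized by bounded scalar search (tolerance 1e-6) with
the endpoints 0 and 1 checked explicitly, since the optimum frequently
sits on the boundary. On a star tree the likelihood is flat in λ and λ̂
is reported as 0 by convention. λ is restricted to [0, 1]; the
PD-feasible extension above 1 is not searched.

The LRT against λ = 0 uses the χ²₁ reference without a boundary
correction, and the fit object carries a note saying so. Because λ = 0
lies on the parameter boundary, the null distribution is closer to a
½χ²₀ + ½χ²₁ mixture and the test is conservative: simulated independent
traits on the 13-tip reference tree reject at ~1% at nominal 5%
(calibration asserted ≤ 7% in the test suite).

PGLS whitens y and X = [1, x] by the Cholesky factor of C (or C_λ̂, λ
profiled jointly by ML) and solves least squares; R² is computed against
the GLS-centered total sum of squares, adjusted R² = 1 − (1−R²)(n−1)/(n−2),
and the slope is tested with F(1, n−2). With an identity covariance this
reproduces OLS to machine precision (tested).

λ estimation quality depends strongly on tree shape: λ is identified by
contrasts between shared and independent history, so trees with deep
shared branches (the reference 13-tip tree uses crown depth 0.05 and
backbone start 0.2 on height 1) recover λ = 1 with mean λ̂ ≈ 0.9 at
n = 13, while shallow-history trees are markedly noisier at the same n.

**Trend classification.** A cluster's abundance trend is "none" unless
its λ LRT is significant (raw p < 0.05 per cluster, matching common
practice for per-cluster screening; a Benjamini–Hochberg option exists in
spirit via the returned p-values but no correction is applied by
default). Given significance, the trend is the sign of the PGLS slope of
abundance on a user-supplied clade-order score (default: clade rank in
the order the clades are declared). The order score formalizes "from
clade A towards clade D" as a monotone covariate; it is a screening
device, not a causal model.

## Tandem-repeat loop counts

Reads are decomposed into canonical k-mers (k = 21); k-mers seen fewer
than min_cov = 2 times are dropped as noise; edges are the observed
canonical (k+1)-mers; unbranched paths are condensed. "Loops" are
formalized as the circuit rank E − V + C of the condensed multigraph —
the unique graph invariant counting independent cycles, and invariant
under relabeling and condensation. A single monomer gives rank 1; an
array interleaving v variants that share a conserved block longer than
k−1 gives rank v, because each variant contributes an independent path
between the conserved anchors. Very low variant divergence merges loops:
below roughly 1 − (1/2)^(1/k) ≈ 3% pairwise divergence in the variable
region, variant paths start sharing k-mers and the rank drops; the
default simulated divergence (0.2) sits far above this. Classification:
rank 0 "non-tandem", 1 "simple (non-hybrid pattern)", ≥ 2 "complex
(hybrid/polyploid pattern)" with the count retained.

## Repeat-similarity consensus network

For each cluster, observed edge counts between species pairs are compared
with a uniform-random-edge-placement null: E_ij = E_tot·n_i n_j / C(N,2)
off-diagonal and E_tot·C(n_i,2)/C(N,2) on it. This is the simplest
exchangeable null and gives ratio 1 for well-mixed clusters. Clusters
without any inter-species edge (after optional outgroup removal) are
dropped. Ratios are normalized by the off-diagonal maximum and flipped
into distances in [0, 1].

Neighbor joining is the canonical Saitou–Nei/Studier–Keppler algorithm;
ties in Q break on the lexicographically smallest taxon-pair label (each
partial subtree labelled by its smallest tip), so taxon order never
changes the result; negative branch-length estimates are clamped to zero
with the deficit moved to the sister branch (clamping cannot trigger on
additive input, which is tested). The consensus split set keeps
bipartitions occurring in ≥ 10% of the cluster trees, inclusive at the
boundary. Only the split *system* is computed; drawing the splits graph
is delegated to external viewers via a SplitsTree-compatible NEXUS file
that round-trips exactly.

## Network selection

AIC = 2k − 2·lnL over fitted-model summaries. Two k conventions are
exposed because published selection tables are sometimes computed with
k = branch-length parameters only even when the text defines k to include
reticulations; the default ("branch") reproduces such tables digit for
digit, and "total" adds one parameter per reticulation (the two differ by
exactly 2·reticulations). Ties prefer fewer reticulations. The network
search itself (gene trees, pseudo-likelihood optimization, inheritance
probabilities) is out of scope; fits enter as TSV summaries.

## Problem sizes and numerical conventions

The standard synthetic study uses 10 species in 4 clades, 8 families of
300 Mb on 25 kb consensi, single-copy 425 Mb (~85% repeat content),
a 2.5× burst on clade D's stem, and 20 000 reads of 150 bp per species,
all clustered without subsampling; recovered repeat fractions then carry
only multinomial emission noise (SE ≈ 0.25 pp). λ calibration uses 200
recovery and 1000 null replicates on the 13-tip reference tree. Rounding
of fold ratios and printed selection-table deltas is half-up (decimal,
not banker's). Degenerate inputs fail loudly: zero-variance traits,
constant predictors, empty graphs, all-zero O/E matrices and sub-3-taxon
distance matrices all raise instead of returning placeholders.

## Known limitations

- Connected-component clustering inherits single-linkage chimerism and
  fragmentation (discussed above); no community detection is attempted.
- The λ LRT's χ²₁ reference is conservative at the boundary; p-values
  near 0.05 should be read accordingly.
- The O/E null assumes exchangeable edge placement within a cluster;
  strong within-species coverage heterogeneity would distort ratios.
- The consensus network requires a common taxon set across cluster trees;
  clusters missing species are currently dropped rather than restricted.
- Genome sizes are inputs, never estimated; flow-cytometry style
  measurement error is not modelled.
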