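# Methods

## The model

Gene co-expression is modeled as a graphical Gaussian model (GGM): genes are
jointly multivariate normal on the log scale, and an edge between two genes
means they are conditionally dependent given all other genes — equivalently,
that the corresponding off-diagonal entry of the precision (inverse
covariance) matrix is non-zero. The edge statistic is the partial
correlation

    pcor_ij = -omega_ij / sqrt(omega_ii * omega_jj),

the correlation between genes i and j after removing the linear effect of
every other gene. Compared with marginal (Pearson) correlation, partial
correlation discounts indirect co-expression that merely flows through
shared neighbors, which is why GGM networks are far sparser than
correlation networks at comparable confidence.

## Preprocessing

Raw expression is an FPKM gene-by-sample matrix. Genes whose maximum FPKM
across all samples is strictly below 20 are removed (a gene never reaching
20 FPKM anywhere carries mostly noise), and the rest is transformed by
log2(FPKM + 1). RNA-seq expression has a strong mean-variance dependency on
the raw scale — highly expressed genes have larger variances — which the
log transform largely removes; `mean_variance_profile` quantifies this as
the Spearman correlation between per-gene means and SDs, with a running
median (default window 301 ranks, centered, clipped at the boundaries) as
the trend line. The matrix container carries a scale tag so the filter can
only run on FPKM values and the transform cannot be applied twice.

## Shrinkage partial correlation on random subsets

A direct GGM fit needs an invertible correlation matrix, impossible when
genes outnumber samples. The estimator here is the Schafer–Strimmer
shrinkage: the empirical correlation matrix R is replaced by
R* = lambda* I + (1 − lambda*) R with

    lambda* = clamp( sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2, [0, 1] ),

where Var(r_ij) is the standard unbiased estimate of the variance of the
empirical correlation computed from the standardized data products. R* is
always full rank for lambda* > 0, and its inverse yields the partial
correlations. Numerical guards: positive definiteness is checked by
Cholesky before inversion; a genuinely singular matrix (k > n with forced
lambda = 0) raises an error instructing positive shrinkage; constant genes
get all-zero partial correlations with a warning instead of failing.

Because even the shrunk estimate is quartically expensive in the gene
count, the estimator runs on random gene subsets: each iteration draws
`subset_size` genes uniformly without replacement and estimates that
block's partial correlations. For every gene pair, the recorded value with
the smallest absolute magnitude across all iterations that co-sampled the
pair is kept, sign retained. The minimum rule is deliberately conservative:
a pair that ever looks conditionally independent (in some conditioning
context) is treated as such, which suppresses associations that are
artifacts of a particular subset's limited conditioning. Ties in absolute
value resolve to the earliest iteration. Each iteration draws from its own
seeded stream (seed, iteration index), so results are independent of
execution order and extending a run never perturbs earlier iterations; a
corollary is that aggregated |pcor| is non-increasing in the iteration
count for a fixed seed. Pairs never co-sampled get pcor 0 (no evidence of
direct association) and the run reports pair coverage; a warning fires when
the expected co-sampling count n_iter·(s/g)·((s−1)/(g−1)) falls below a
configurable floor (default 1).

Defaults are the full-compendium settings (25,000 iterations of 2,000-gene
subsets); tests and the validation runs use reduced plans (see "Problem
sizes" below).

## Edge selection

Pearson correlations are computed on the same log-scale matrix (the scale
choice is recorded in the network metadata). An edge is admitted iff

    (pcor >= 0.035 and pcc >= 0.35)  or  (pcor <= −0.035 and pcc <= −0.35),

i.e. the pair must pass both statistics with consistent signs; the PCC
co-filter removes pairs whose partial correlation is nominally large but
whose marginal correlation is too weak to support a direct interpretation.
The edge sign is the pcor sign, and positive/negative counts are reported
separately.

## Network statistics and MCL modules

The global clustering coefficient is transitivity, 3 × triangles /
connected triples, ignoring edge signs; the reference value for a random
graph of the same size is the Erdos–Renyi edge probability 2E/(N(N−1)).
(The mean-local-coefficient variant would also be comparable against the
same expectation; transitivity is fixed here for determinism.)

Modules come from Markov clustering (MCL) on the unweighted, sign-blind
adjacency with unit self-loops: column-normalize to a random-walk matrix,
then alternate expansion (matrix squaring) and inflation (elementwise power
1.5 with column renormalization), pruning entries below 1e-6 and keeping at
most 1,500 per column, until the max-norm change falls below 1e-8 (cap 200
iterations; non-convergence clusters the current matrix with a warning).
Clusters are read from the limit matrix: rows with positive diagonal mass
are attractors, attractors connected through the limit matrix form one
attractor system, and every node joins the system it flows to; a node
flowing to several systems goes to the largest (tie: the module that will
receive the smaller id). The command-line mcl program's "scheme" presets
are adaptive resource controls; the fixed pruning bounds used here preserve
the algorithm's fixed points at the scales this package targets, though
bit-compatibility with the mcl binary on large graphs is not claimed.
Modules with fewer than 5 genes are set aside as small-module genes, and
the rest are numbered 1, 2, … by descending size (ties by smallest member
gene id).

## Enrichment

Term over-representation per module is the one-sided hypergeometric tail
P(X ≥ k) for k hits among n module genes, K term genes, N universe genes,
with Benjamini–Hochberg adjustment across the terms tested within a module.
Annotations are taken as given; if DAG-aware results are wanted the caller
must propagate annotations to ancestor terms first — conditional
graph-decorrelated testing is intentionally out of scope. The universe
defaults to the network's genes and is configurable.

Promoter-motif enrichment scans IUPAC patterns on both strands (TF binding
is strand-agnostic), counting overlapping occurrences; N in a sequence
never matches. The per-module test is binomial: a gene "has the motif" iff
its promoter has ≥ 1 match, p0 is the universe-wide fraction of such genes,
and p = P(X ≥ k) for X ~ Binomial(n, p0). The gene-level Bernoulli unit was
chosen over per-base occurrence counts because it is insensitive to unequal
promoter lengths.

## Cross-species conservation

Given a second network and a homolog map (e.g. InParanoid output), a gene g
has a conserved interaction when some homolog of g is in the partner
network and at least one of g's neighbors (group A) is homologous to at
least one neighbor of g's homolog(s) (group B). Many-to-many homology is
honored: B is the union over all homologs. Per-module conservation is the
percentage of module genes with the flag; by default all module genes count
in the denominator, including genes with no homolog at all (module
percentages are then directly comparable across modules with different
homolog coverage); a switch restricts the denominator to genes with
homologs.

## Profiles and neighbor voting

Module profiles average log-scale expression over a module's genes within
each ordered sample group and report each row relative to its maximum
(all-zero rows stay zero). The scale is configurable to raw FPKM; group
membership is an explicit input, never inferred from sample names.

Network quality against known gene sets is summarized by leave-one-out
neighbor voting: each gene of degree ≥ 1 is scored by the fraction of its
neighbors inside the set, and the AUROC (mid-rank form, ties counted half)
measures how well members outscore non-members. Cross-validated fold
variants add partition nondeterminism without changing the ranking
semantics at these scales, so the leave-one-out form is used.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground truth
attached:

- **Planted GGM.** The precision matrix is the identity with −within_pcor
  at planted edges; modules sit on disjoint diagonal blocks, so cross-module
  entries are exactly zero. Within a module the pattern is a ring plus
  size//3 random chords — sparse, like a GGM's conditional-dependence
  structure, because full-clique precision blocks of realistic magnitude
  are near-singular. If the smallest eigenvalue falls below 1e-3 a diagonal
  ridge delta·I restores positive definiteness (logged; realized partial
  correlations shrink by 1/(1+delta)). At the default within_pcor = 0.3 and
  module size 20 no repair is needed and planted partial correlations are
  exactly 0.3. The default 0.3 is a free parameter — real partial-correlation
  magnitudes are not characterized beyond being concentrated near zero —
  chosen to put planted edges well above the sampling-noise floor at a few
  hundred samples.
- **Expression.** Latent values are drawn from N(0, Omega^{-1}),
  standardized per gene, then shifted/scaled to gene-specific base means
  (uniform on log2 scale 3–8, i.e. ~7–255 FPKM) and SDs (uniform 0.6–1.4),
  and mapped to FPKM = 2^z − 1 clipped at 0 — the exact inverse of the
  pipeline's log2(FPKM+1), so preprocessing recovers the latent Gaussian up
  to the rare clip. The exponential map produces the raw-scale
  mean-variance dependency.
- **Conservation fixtures.** The partner network is a relabeled copy with a
  chosen fraction of edges rewired to random non-edges; the homolog map
  links a chosen fraction of genes to their copies.
- **Annotations and promoters.** Each module's marker term annotates 80% of
  its genes plus 5% of the rest by default; promoters are uniform ACGT with
  one concrete IUPAC-motif expansion implanted per selected gene.

What the generator does **not** emulate: read counts or count noise,
library-size and batch effects, the composition of a multi-study
compendium, unbalanced module sizes, hub genes, or negative/mixed-sign
modules. Passing recovery tests therefore demonstrates the pipeline's
correctness and statistical behavior under its own model assumptions, not
performance on real compendia.

## Problem sizes and reduced settings

Validation runs use desk-scale conditions: edge recovery on 200 genes
(8×20-gene modules), 400 samples, 200 iterations of 80-gene subsets;
end-to-end module recovery on 800 genes (40×20), 400 samples, 200
iterations of 100-gene subsets. For the end-to-end run the edge thresholds
are relaxed to pcor ≥ 0.04, pcc ≥ 0.15: the planted partial correlations
are 0.3 and direct inversion of ring-plus-chords blocks shows the implied
marginal correlations of planted edges bottom out near 0.33, so the default
pcc 0.35 (calibrated to compendium-scale noise floors) would clip true
edges under sampling noise at these sample counts. Subsets of
about five times the module size keep conditioning local enough that
within-module structure is estimated well while the minimum rule still
suppresses cross-module artifacts.

## Known limitations

- The shrinkage estimator reproduces the documented dynamic-lambda
  estimator with identity target; exact numeric agreement with any
  particular R implementation is not claimed.
- MCL here is dense-matrix; graphs beyond a few thousand nodes need the
  sparse mcl binary.
- Degenerate-plan equivalence between the subsampled and direct estimator
  holds to ~1e-12 (BLAS kernel selection varies with buffer alignment), not
  bitwise.
- Conservation percentages depend on the denominator convention; both
  variants are computed but only one can match any given external report.
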