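# Methods

This note documents the statistical procedures implemented in `crenadelim`,
the choices made where the underlying survey methodology left details open,
and what the synthetic-data tests do and do not establish.

## Data model and missing data

Allozyme genotypes are diploid, codominant and multiallelic: each cell of
the genotype table is an unordered pair of allele labels or missing.
Allele labels are arbitrary case-sensitive strings; the electrophoretic
mobility order behind the conventional alphabetical labelling plays no role
in any statistic, so the package treats labels as opaque.

All between-group statistics use pairwise deletion: a locus enters a
comparison only when it is typed in both groups, and the per-locus gene-copy
count 2n_l counts typed copies only.  Consequently the %FD denominator is
the number of loci scorable in *both* groups, not the panel size — the
published combined table is internally inconsistent under a fixed
denominator (one cell implies 41 jointly scored loci, another 42), so
varying denominators are the only reading consistent with pairwise
deletion.  Displayed percentages are rounded half away from zero; the
unrounded value is retained.

## Fixed differences and the tolerance rule

Strictly, a fixed difference is a locus at which two samples share no
alleles.  The survey's reporting statistic relaxes this with a "cumulative
10% tolerance for any shared alleles"; the cited methodological source is
not reproduced here, so the package adopts a symmetric reading: the
shared-allele mass at a locus is

    m = sum over alleles present in both groups of (p_A + p_B) / 2

and the locus counts as a fixed difference iff m <= tolerance.  Averaging
over the two taxa makes the rule symmetric in its arguments, reduces to the
strict rule at tolerance 0, and is applied per locus (not summed across
loci; the count is then trivially monotone in the tolerance).  Cluster
*validation* during stepwise PCO uses the strict rule by default, because
the tolerance is introduced for the reported %FD statistic rather than for
diagnosability; both tolerances are configurable.

Small-sample caveat: for a singleton sample (2 gene copies) "fixed" means
only that the two observed copies share nothing with the other sample.
The congruence report therefore records sample sizes alongside FD support.

## Genetic distances

* **Rogers' distance** — per-locus Euclidean distance between frequency
  vectors scaled to [0, 1], averaged over jointly typed loci.  It is a
  metric, which matters because it feeds the PCO embedding.
* **Nei's unbiased D** — ratio-of-means form: J̄_AB, J̄_A, J̄_B are means
  over jointly typed loci, with the within-group identities bias-corrected
  by (2n J − 1)/(2n − 1).  Loci with fewer than 2 typed copies in either
  group are excluded (the correction is undefined).  The correction can
  overshoot and give a slightly negative D for very similar samples; this
  is clamped to 0 with a warning.  Samples sharing no alleles anywhere give
  +infinity with a warning, never an exception.
* **DNA divergences** — p-distance and JC69/K2P/TN93 closed forms, with
  sites containing gaps, N or any IUPAC ambiguity code excluded from the
  pair (never partially matched).  The TN93 implementation follows the
  textbook closed form; it was cross-checked against a step-by-step
  independent evaluation (note that some toolkits ship slight variants).
  The `gtr_g` model maximizes the pairwise likelihood of a single branch
  length under GTR with discrete-gamma rates (4 categories, mean-of-band
  discretization), base frequencies empirical from the pair unless
  supplied.  It is the default corrected distance because the survey's
  phylogenetic analyses used GTR+I+G, while the exact correction behind the
  published corrected matrix is not stated; the model is selectable for the
  same reason.  Saturated closed-form cases (log of a non-positive
  argument) return +infinity with a warning.
* **Rate conversion** — rate = 100·d/(2·age) percent per lineage per Myr:
  the only dating-related computation kept in scope (tree dating itself is
  the province of dedicated Bayesian tools).

## Principal co-ordinates

Classical (Gower) scaling: double-centre −½D², eigendecompose, scale
eigenvectors by √λ.  Negative eigenvalues — possible for non-Euclidean
inputs — are discarded from both the coordinates and the
percent-of-variation denominator, and their count is reported; this is
standard Gower practice and the only policy that keeps the reported
percentages non-negative.  Input distances are used as-is (no square-root
transform): Rogers' distance is already metric.  Each axis's sign is fixed
by making its largest-magnitude loading positive, so repeated runs and
permuted inputs give reproducible coordinates (up to exactly-degenerate
eigenvalues, which planted configurations avoid).

## Stepwise delimitation

The original procedure read scatterplots by eye.  The automated surrogate
must be deterministic and testable, so candidate partitions come from
average-linkage agglomerative clustering on the first two PCO axes, scanned
over k = 2..min(8, n−1) cluster counts; a partition is accepted only if
**every** pair of its groups is diagnosable by at least `min_fd` strict
fixed differences, and the accepted partition with the largest k wins (ties
broken toward lexicographically smallest member sets).  The default
`min_fd` = 3 encodes the survey's treatment of subgroups differing by fewer
than three fixed differences as non-distinct.  One amendment to the scan
bounds: at n = 2 the k ≤ n−1 cap would forbid the only possible split, so
the two-singleton split is scanned there; the cap's purpose — keeping the
trivial all-singletons partition out of consideration — is preserved for
all larger n.

Recursion applies the same detection inside each validated cluster
(`max_rounds` = 3 by default, matching the three rounds of the original
analysis: all individuals → regional clusters → within-Kimberley).  Because
each round re-embeds only the cluster's own members, structure hidden by a
parent's 2-axis projection resurfaces in the child's own PCO — the point of
doing PCO stepwise.

The congruence verdict for a terminal cluster requires: FD support
≥ `min_fd` against every other cluster; reciprocal monophyly on the mtDNA
tree (evaluated on the unrooted topology — the cluster's tips separated
from all others by a single edge — and "not assessable" rather than false
for singletons or unsequenced clusters); and minimum between-cluster mtDNA
divergence strictly greater than the cluster's maximum within-cluster
divergence, on every scale (uncorrected/corrected) where both sides are
computable.  Clusters with no sequenced member fall back to allozyme-only
evidence with the mtDNA fields not available.

## Synthetic data: what it emulates, and what it does not

The generator plants fixed differences as per-locus block partitions of the
groups: each block is fixed for its own allele, so planted FD counts are
exact by construction rather than approximated by rejection sampling.  A
greedy union-find realizer converts a target FD-count matrix into such
partitions where possible (targets must decompose into per-locus cuts; the
demands 1/1/3 among three groups, for example, cannot, and are rejected as
infeasible before any sampling).  Genotypes are drawn under Hardy–Weinberg
equilibrium; sequences evolve site-independently under GTR with optional
discrete-gamma heterogeneity and invariant sites, branch lengths in
expected substitutions per site.

The study-like scenario mirrors the survey's design: 94 individuals at 42
loci in 10 groups — five regional groups plus the Kimberley group split
into subgroups A–E (13 individuals, three of them singletons); planted
cross-regional FD counts of 9–20 and Kimberley-internal counts of 4–7,
each Kimberley subgroup carrying 3–4 private-allele FD loci; two loci with
a low-frequency (5–6%) shared allele that exercise the tolerance boundary;
1% missing data; and an 828-site alignment for a ~52-individual subset
whose between-group uncorrected divergences fall in ~0.15–0.29 with
within-group divergences below 0.06.  Tree heights were chosen so the
realized divergences land in that band under the scenario's
transition-biased GTR+I+Γ model (shape 0.75, 35% invariant sites,
mtDNA-like base frequencies).

What passing tests show: the statistics are implemented correctly (oracle
equivalence, closed forms), and the pipeline recovers planted structure of
the study's shape and signal strength.  What they do not show: performance
on real allozyme data — the generator draws loci independently, plants
clean block-structured fixed differences, uses HWE within groups, and puts
no homoplasy, introgression (beyond the explicit haplotype-sharing test
scenario) or scoring error into the data.  Real gels are noisier in all of
these ways.

## Numerical conventions

Eigenvalues within 1e-9 (relative) of zero are treated as zero, not
negative; distance-matrix symmetry is enforced within 1e-12 and frequency
sums within 1e-9; the GTR+Γ branch-length search is bounded ML on
[1e-8, 20] substitutions/site; FD tolerance comparisons allow 1e-12 slack
so planted boundary cases (m exactly 0.10) count as within tolerance.
Problem sizes in the test-suite simulations (20 seeds × 94 individuals;
100 kb two-taxon alignments for consistency checks; 10 kb × 50 replicates
for the unbiasedness check) were chosen to hold Monte-Carlo error an order
of magnitude below the tolerances asserted.

## Known limitations

* Cluster detection depends on the first two PCO axes per round, as in the
  original procedure; pathological configurations needing three axes within
  a single round would require more recursion rounds instead.
* Nei's D between a singleton and anything is dominated by the 2n = 2
  correction; it is reported but should be read with its sample size.
* The pairwise GTR+Γ distance estimates only the branch length — the
  exchangeabilities and gamma shape are inputs, not jointly estimated, as
  is usual for pairwise (rather than tree-wide) likelihood.
* `plant_fd_partitions` is greedy and may declare a decomposable target
  infeasible in adversarial cases; the constructive partition interface
  covers such plans exactly.
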