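# Methods

`micronet` analyses amplicon sequence variant (ASV) count tables from a
paired two-timepoint, five-arm rodent study design: every subject
contributes a baseline sample (T0) and a post-treatment sample (T1)
from one of five arms — water or alcohol binge exposure, crossed with
vehicle or oleoylethanolamide (OEA) pretreatment, OEA given orally or
intraperitoneally. The package implements the downstream analysis
chain: normalization, α/β-diversity, permutation-based community
comparison, per-taxon testing and biomarker scoring, sparse signed
association-network inference, network topology statistics, and a
betweenness-targeted "attack" simulation of community reassembly.
Everything runs on synthetic count tables with known ground truth, so
every stage has a testable recovery target.

## Data model and normalization

The universal input is a taxa × samples non-negative integer matrix
with per-sample metadata (`sample_id`, `subject_id`, `timepoint`,
`liquid`, `pretreatment`, `route`). Zero-sum samples are rejected at
ingest; within a selected sample group, taxa with zero total count are
dropped before analysis (they can carry neither abundance nor network
signal) and the drop is logged.

*Rarefaction* subsamples each sample without replacement to a common
depth (default: the smallest library) with a single seeded
multivariate-hypergeometric draw per sample. It is used only for
α-diversity, where unequal depth would bias richness directly.

*Cumulative sum scaling* (CSS): for sample *j*, the scaling factor
`s_j` is the sum of counts no larger than the per-sample quantile
(default 0.5) of its nonzero counts; normalized values are
`log2(1 + c_ij · K / s_j)` with `K = 1000`. The fixed-median quantile
is used rather than the adaptive choice of the originating package: it
is reproducible, logged, and adequate for the simulated depth profiles.
Bray–Curtis β-diversity is computed on the CSS+log2 matrix by default
(`beta_on_css = False` switches to raw proportions).

*α-diversity*: richness `S` (taxa with count > 0), Shannon entropy `H`
in nats, Pielou evenness `J = H / ln S`. `J` is reported as missing for
`S ≤ 1` rather than coerced to 0. Shannon uses the natural log, the
default of the common microbiome tooling.

*PCoA* is classical scaling: double-center `-D²/2`, eigendecompose,
scale eigenvectors by the square roots of the positive eigenvalues.
Bray–Curtis is a semimetric, so negative eigenvalues occur; they are
reported but excluded from coordinates and from the denominator of
variance explained.

## Hypothesis tests

Wilcoxon comparisons of diversity between T0 and T1 within an arm are
paired (signed-rank; the design pairs samples by animal); cross-arm
comparisons at T1 are unpaired (rank-sum). Exact null distributions are
used for tie-free samples with combined n ≤ 12, otherwise the normal
approximation with tie correction. One-way ANOVA and Kruskal–Wallis
cover per-taxon abundance scans; Benjamini–Hochberg adjusted p-values
accompany every multi-test scan.

PERMANOVA partitions the squared-distance sums: `SS_total =
(1/N) Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`, `R² =
1 − SS_within/SS_total`, pseudo-F with `(a−1, N−a)` degrees of freedom.
ANOSIM ranks all pairwise distances jointly and compares mean between-
vs within-group ranks, `R = (r̄_B − r̄_W)/(M/2)`. Both use seeded label
permutations and the `(b+1)/(m+1)` p-value estimator, so p is never 0
and every rerun is bit-identical. Both are implemented in-package
because reproducible seeded permutation streams are part of the
pipeline contract; scikit-bio's implementations serve as independent
cross-checks in the test suite. Calibration: under a simulated null
(iid data, random labels, 500 replicates) both tests reject at
nominal α = 0.05 with frequency inside [0.02, 0.09].

The biomarker stage follows the LEfSe decision rule: per-taxon
Kruskal–Wallis screen across classes (α = 0.05), survivors scored by a
bootstrapped (30 resamples, seeded) one-vs-rest linear-discriminant
effect size, retained when the log10 score exceeds 2.0 and labeled with
the class of highest mean abundance. Effect sizes are computed on
abundances rescaled per sample to 10⁶ units so the conventional
score-2.0 cutoff is on its familiar scale. The published algorithm's
subclass (within-class Wilcoxon) step is intentionally omitted — the
design has classes only. Note the screen alone controls the null
behavior: with identically distributed classes the expected number of
false markers is ≈ α × (number of taxa); the LDA threshold does not
filter chance survivors because on the 10⁶ scale chance class-mean
differences far exceed 100 units.

## Association-network inference

The counts of one sample group are mapped to unconstrained space with
the centered log-ratio transform (pseudocount 1), then a
conditional-independence graph is estimated by Meinshausen–Bühlmann
neighborhood selection: each taxon's CLR abundance is lasso-regressed
on all others and an edge is a nonzero coefficient in either direction
("or" rule; "and" available). Neighborhood mode is used rather than a
covariance/graphical-lasso mode because the analyses concern edge sets,
signs and topology.

The penalty is chosen by StARS: a geometric 30-point path from
`λ_max` (the largest absolute marginal covariance, where every
neighborhood is empty) down to `0.01·λ_max`; 20 seeded
without-replacement subsamples of size `⌊10√n⌋` for `n > 144`, else
`⌊0.8n⌋` (the `10√n` rule is meaningful only when well below `n`;
near-full subsamples show no selection variability and the penalty
collapses); per-pair selection frequencies θ̂ give instability
`mean 2θ̂(1−θ̂)`, monotonized from the dense end, and the smallest
penalty with running-supremum instability ≤ β = 0.05 is selected and
re-fit on the full data. Subsample draws derive from the seed and the
*sorted* sample identifiers, and samples are put in canonical order
before fitting, so the result is bit-identical under any permutation of
input columns.

Edge sign is the sign of the directional coefficient of larger
magnitude (ties go to the lower-index direction); weight is the mean of
the two directional coefficients. Taxa without neighbors remain as
degree-0 nodes, so fragmented-network statements ("x% of nodes are
unconnected") are expressible.

Recovery under the generative model below (p = 30, n = 200, band /
cluster / scale-free topologies): edge precision and recall both
exceed 0.5 and F1 exceeds three times a size-matched random-guess
baseline. A known limitation: in small communities the CLR closure
term cancels much of a *positive* latent pairwise association (at
p = 10 a planted positive partial correlation of 0.3–0.5 is
essentially undetectable while its negative counterpart is amplified);
sign-recovery behavior is therefore characterized at p ≥ 20.

## Topology statistics

Degree distribution (percent of nodes per degree), unnormalized
unweighted betweenness, connected components (isolated nodes are
singletons), and mean shortest-path length averaged over node pairs
*within the same component* — the convention that keeps the statistic
finite on fragmented networks; it is reported missing when no two nodes
share a component. Edge percentages are rounded half-up to integers,
with raw counts always emitted alongside. All statistics ignore signs
and weights: their downstream use (removal order, histogram
comparison) is ordinal.

## Attack simulation

Starting from a group's count table, taxa are removed one at a time —
in decreasing order of betweenness of the *initial* network (ties:
degree descending, then taxon id; per-step recomputation available
behind a flag) or uniformly at random (20 replicates by default, each
with its own derived seed). Each removal deletes the taxon's row from
the count table and the network is re-inferred from the reduced data;
mere graph-node deletion is available for tests but excluded from
reported results. Each step's degree distribution is compared with a
reference distribution by total-variation distance (fractions, in
[0, 1]); "resembling" the reference is formalized as TV ≤ ε with
ε = 0.1 by default, always reported rather than hard-coded into
conclusions. The match point is the first step within ε.

The acceptance experiment plants the reassembly signal exactly: arm B's
table equals arm A's with the 3 top-betweenness hub taxa (of A's
inferred network) removed. The targeted attack reconstructs B's exact
condition at step 3 (and may match earlier), whereas random removal
rarely hits the hub set early; the reported contrast is the fraction of
20 random replicates whose match point is no earlier than the targeted
one. An earlier variant drawing arm B as an independent sample with a
hub-knockout effect proved uninformative: at n = 30 per arm the
between-network TV distance is dominated by edge-density noise
(~0.17–0.3 for all trajectories), so no trajectory ever matched.

## Synthetic data generator

Logistic-normal multinomial: per sample a latent vector is drawn from
`N(μ, Σ)` where `Σ` is the inverse of a sparse positive-definite
precision matrix whose off-diagonal pattern is the planted graph;
softmax maps it to a composition; counts are a multinomial draw at a
depth uniform in 10 000–100 000 reads (typical 16S library sizes). The
baseline log-mean μ is heterogeneous (standard normal per taxon, fixed
by the truth seed) so communities are uneven as in real data.
Precision off-diagonals are uniform ±[0.2, 0.5] with the diagonal set
to the absolute row sum plus 0.1 (Gershgorin), then the covariance is
rescaled to unit variances; this keeps partial correlations detectable
(≈0.2–0.45) at the study's sample sizes without being trivial.

Planted effects act on the latent means: multiplicative fold changes;
silencing of a random fraction of taxa (richness suppression) or of
the top-betweenness hubs of the true graph — silenced taxa get exactly
zero probability, so richness effects are exact. The default study
uses the paper-scale arm sizes (6/11/8/7/7 subjects, paired T0/T1) and
directional effects: richness suppression in the alcohol arms
(strongest, 0.3, under oral OEA), fold-change shifts of a few taxa,
and a 3-hub knockout in the i.p. OEA arm. Magnitudes are calibration
choices — the emulated study reports directions, not effect sizes.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy, overdispersion beyond the logistic-normal (no zero
inflation), temporal dynamics beyond two timepoints, or subject-level
random effects (T0 and T1 draws are independent given the arm effect).
Passing tests therefore demonstrate correctness of the algorithms under
a clean compositional model, not performance on real dysbiosis data.

## Reproducibility and problem sizes

Every random draw derives from explicit seeds (sub-seeds via CRC32 of
stable strings, all < 2³¹); the full pipeline is a pure function of
(inputs, config) and reruns are byte-identical. Reported simulation
sizes — 500 null replicates for permutation-test calibration, p = 30 /
n = 200 / 3 seeds for recovery, p = 40 / n = 30 per arm with 20 random
replicates for the attack contrast — are the package's chosen
desk-scale study conditions; they complete in a few minutes on one CPU.
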