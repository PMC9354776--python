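# Methods

This note documents the models and procedures implemented in `macsnet`, the
choices made where the design was genuinely open, and what the synthetic
study does and does not establish about real data.

## Chemometric models

**Scaling.** Unit-variance (auto) scaling is the default, matching common
chemometrics practice for this workflow; `center` and `pareto` are options.
A constant column has no unit-variance scale and raises an error naming the
column. Class labels are coded ±1 with the alphabetically first group at −1
(logged), so "treated" is +1 against "control" in the generated data.

**PCA** is computed by NIPALS (power iteration with deflation, tolerance
1e-12), which matches a full SVD to 1e-6 on the matrices used here — the SVD
serves as the independent oracle in the tests, never as the implementation.
Every component's loading sign is fixed so its largest-magnitude entry is
positive, making fits reproducible across linear-algebra backends.

**PLS-DA** uses single-response NIPALS; with one response the weight vector
of the first component is exactly X'y normalized, a closed form the tests
assert at 1e-8. R²Y is the fraction of (centered) class variance captured by
the extracted components.

**OPLS-DA** follows the single-response O-PLS scheme: the predictive weight
w ∝ X'y; each orthogonal component uses the part of the loading p orthogonal
to w; the deflated matrix yields the final predictive component. Because the
orthogonal weights are exactly orthogonal to X'y, orthogonal scores have
exactly zero covariance with the class vector — asserted at |r| < 1e-8. With
zero orthogonal components the model reduces to one-component PLS-DA. The
loading-recovery contract (structured y-orthogonal variation leaves
predictive loadings unchanged within 1e-6) is exercised with an explicit
algebraic construction: the added variation uses score directions orthogonal
to {1, y, t, t_ortho} and a variable-space direction in the right null space
of the centered matrix. Under unit-variance scaling the identity breaks for
a trivial reason — the augmentation changes per-column variances and hence
the scale factors — so that contract is stated and tested under
centering-only.

**VIP** uses the standard weighted form, VIP_j² = p · Σ_a SSY_a (w_aj/‖w_a‖)²
/ Σ_a SSY_a, so Σ_j VIP_j² = p identically; for OPLS-DA only the predictive
component enters. The number of orthogonal components (default 1) and the
scaling are configuration options because the upstream software convention
does not pin them down.

**Q² and permutation validation.** Q² = 1 − PRESS/SSY under stratified
k-fold cross-validation, 7 folds by default, reduced with a logged warning
when a group is smaller than the fold count. Fold assignment is
deterministic (round-robin within group), so fitted models carry no hidden
randomness. Permutation validation refits PLS-DA under label permutations
(identity-equal label vectors are redrawn) and declares the model valid iff
*every* permuted R²Y and Q² falls strictly below the original. This strict
rule is deliberately conservative: when variables far outnumber samples,
one-component PLS overfits any labels and permuted R²Y approaches the
original, so validity is then carried almost entirely by Q². On null tables
the flag fires in well under 10% of runs (measured ≈1–2%).

## Differential metabolites

Welch's unequal-variance t-test (two-sided) is used for the univariate
screen — the safer default when only "t-test" is conventional. Selection is
strict on both criteria: VIP > 1 and p < 0.05; boundary values are excluded.
No multiple-testing correction applies at this stage (correction enters in
pathway enrichment); under the null the joint rule selects ~4% of
metabolites, bounded by the nominal α because the VIP condition only
filters further. A metabolite constant in both groups with equal means gets
p = 1 by convention, logged.

## Pathway enrichment and impact

Over-representation uses the hypergeometric upper tail
P(X ≥ overlap | N, K, n) with the universe defined as the metabolites
actually measured (plus any externally merged list), not all known
metabolites — a right-tailed Fisher exact test gives identical values.
Holm and BH adjustments are delegated to statsmodels. Impact is the MetPA
convention: relative betweenness centrality (normalized by (n−1)(n−2)/2)
summed over hit members and divided by the pathway total; 0 when no member
is central. The **core** flag uses the *raw* p < 0.05 (strict): the
adjusted values are reported alongside, but the core rule predates
adjustment in the workflow this package operationalizes; the threshold is
configurable.

## Coexpression and the candidate gate

Per cohort, Pearson r (with exact two-sided p from the beta form) between
every candidate target and every metabolic gene, computed on tumor samples
by default — the disease state is where target–metabolism coupling is of
interest; `normal` and `all` are options. Cohort matrices are combined
element-wise by median (robust to one discordant cohort). How this matrix
feeds target scoring is the one genuinely open interface in the workflow;
here it is an explicit, optional gate: candidates whose max |consensus r|
falls below `r_min` (default 0.3) are dropped before scoring, and
`r_min = 0` disables the gate. The bundled demo disables it: with a small
candidate pool the gate removes exactly the noise targets, which empties
the lower half of the score distribution and makes the above-average
retention rule split the true positives instead of separating signal from
noise. With realistic candidate pools (hundreds of predicted targets) the
gate and the retention rule are complementary.

## Mutual information and the MACS ranking

**Estimators.** Default is the KSG k-nearest-neighbor estimator
(algorithm 1, Chebyshev neighborhoods, k = 3), implemented with a KD-tree;
marginal neighbor counts use a relative margin of 1e-12 below the k-th
neighbor distance so the strict-inequality boundary (where the k-th
neighbor always sits in one marginal) is decided deterministically rather
than by the last floating-point bit. Inputs are centered before estimation;
together these make estimates exactly symmetric and exactly invariant to
adding a constant. The histogram plug-in on equal-frequency bins
(⌈√n⌉ per margin by default, duplicate quantile edges collapsed) is the
fully deterministic alternative and handles discrete data exactly
(x = y over four equiprobable levels gives ln 4). Negative estimates are
clipped to zero; units are nats throughout. Calibration at n = 2000: mean
estimates across 20 seeds land within ±0.01 nats of −½ln(1−ρ²) for
ρ ∈ {0.3, 0.6, 0.9}, and independent pairs stay below 0.05 nats in ≥99% of
runs.

**Pathway activity.** The "pathway" random variable is operationalized as
the per-sample standardized mean of z-scored constituent-gene expression —
the simplest summary that makes I(gene; pathway) computable sample-wise from
the same matrices used for coexpression. An activity with variance below
1e-10 (e.g. mutually cancelling genes) is rejected as degenerate.

**Ranking.** Relevance D is the mean MI over core-pathway activities
(averaging is the natural extension when several pathways are core; the
single-pathway form needs no choice). Greedy forward selection uses the
first-order incremental criterion ℵ(x|S) = D(x) − mean_{s∈S} I(x; s); the
joint high-order mutual information of a gene *set* with the pathway is not
estimated — its sample complexity is exactly why the D/R decomposition
exists — and an exhaustive per-step argmax survives only as a test oracle,
which the greedy implementation matches exactly on all small instances.
Ties break lexicographically by gene id (logged). Each gene keeps the
marginal ℵ it had when selected, giving every candidate one number; scores
are aggregated across cohorts by mean (median available) on the shared
candidate set, and genes strictly above the average aggregated score are
retained. Whether cohorts should be pooled instead of averaged is unstated
upstream; per-cohort-then-mean keeps cohorts exchangeable and is the
default.

A consequence of the redundancy penalty worth knowing: planted informative
targets that share a pathway factor are mutually redundant, so the greedy
order defers the later ones — exactly the behavior the duplicate-gene case
mandates — and their marginal scores drop toward the noise-score order
statistics. Retention of *all* planted targets by the above-average rule is
robust (100% of 100 replicate studies at the documented scale); their
occupying the literal top-k ranks is not, and is not claimed.

## Synthetic data

The generators emulate the study design, not the instrument: metabolite
intensities are log-normal (σ = 0.3 on the log scale, typical of LC-MS peak
areas) with planted log-mean shifts of ±effect·σ alternating in sign so both
up- and down-regulated metabolites occur; pathways are disjoint connected
graphs (random spanning tree plus chords) with planted core pathways
absorbing the differential metabolites round-robin; expression cohorts give
each pathway one latent activity factor, gene loadings of 0.7, informative
targets coupled to their (round-robin) pathway factor at the requested
correlation, small per-gene tumor/normal offsets, and everything else
independent noise. Defaults in the bundled demo: 10+10 samples × 80
metabolites, 12 planted shifts at 3 SD, 10 pathways (3 core), three cohorts
sized 39/30, 39/39 and 240/193 like typical public HCC series, 20 targets
with 4 informative at coupling 0.8.

Not simulated: chromatographic drift, QC/batch structure, overlapping
pathways, probe-level artifacts, and heavy-tailed expression noise. Passing
tests therefore demonstrate the *algorithmic* chain — selection rules,
estimators, ranking, retention, export — under a faithful but idealized
correlation structure; they do not certify performance on real cohorts.

## Pipeline engineering

The eight stages run in fixed order; every stage writes TSV/JSON/GraphML
outputs and the manifest records parameters and SHA-256 checksums. One
global seed fans out to per-stage seeds by hashing `"{seed}:{stage}"`
(SHA-256, reduced below 2³¹), so stages are decoupled and the whole run is
byte-reproducible — asserted by hashing two complete runs. Configuration is
YAML with unknown-key rejection and logged defaults (VIP 1, p 0.05,
core α 0.05, r_min 0.3, KSG k = 3, UV scaling, 1 orthogonal component,
100 permutations, 7-fold CV). Expression matrices are consumed as provided
and assumed log-scale and probe-collapsed; GEO/SOFT parsing, external
target-prediction and protein-association services, and network layout are
out of scope — the target–gene link table is a user-supplied input, and a
synthetic stand-in ships with the generator.

## Problem sizes used in checks

Calibration and recovery studies run at: MI closed-form and independence,
n = 2000 (20 and 100 seeds); greedy-vs-oracle, 50 instances of ≤8
candidates at n = 120; planted-target recovery, 100 replicates of 200
samples × 40 candidates; VIP fuzzing, 100 random tables; null calibration,
200 tables (selection) and 100 tables × 20 permutations (validation flag);
end-to-end determinism, the demo design twice. These sizes were chosen so
each study's Monte-Carlo error is small relative to the margin it checks.
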