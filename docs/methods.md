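# Methods

`immunebalance` implements a quantitative analysis of immune balance for
post-gated flow-cytometry cohorts: per-sample subset frequencies
(percent-of-parent) for patients and healthy controls, optional binary
clinical tables, and optional genetic labels. This note documents the
models, the synthetic-cohort generator, the numerical choices, and the
limitations.

## Scores

**Immune dysregulation score (IDS).** For a panel with inflammatory subsets
$P$ and regulatory subsets $A$,

$$\mathrm{IDS} = \log \frac{\mathrm{GM}(x_P)}{\mathrm{GM}(x_A)}$$

where GM is the geometric mean of the percent-of-parent frequencies. The
default panel is 3 inflammatory (BCL6⁺ and ICOS⁺BCL6⁺ follicular-helper-like
T cells, activated CD8⁺CD25⁺ T cells) versus 3 regulatory subsets
(CD4⁺CD25ʰⁱCD127ˡᵒFOXP3⁺ Tregs, transitional and memory Bregs). The log base
is natural by default, configurable, and recorded in the output metadata so
results are convertible. A pseudocount (default 0.01 percentage points)
engages **only when a zero frequency is present**; with strictly positive
inputs the score is the exact log-ratio, which makes two invariants exact:
antisymmetry under swapping the panel lists, and equivariance
$\mathrm{IDS}(c \cdot x_P, x_A) = \mathrm{IDS}(x_P, x_A) + \log c$.

**ΔIDS** is IDS minus the control-group mean IDS, so controls average to
zero by construction. **Pro_mean / Anti_mean** are arithmetic means of
control-standardized (z-scored against control mean and SD) frequencies of
the inflammatory / regulatory panel subsets; the three subsets on each side
live on different scales, so standardization precedes averaging. A zero
control SD in any panel subset leaves these undefined and is raised as an
error rather than silently propagated.

**Clinical dysregulation score (CDS)** counts binary-coded (0 absent / 1
present) clinical manifestation domains. Two presets exist: the
four-domain set (autoimmunity, chronic inflammation, lymphoproliferation,
malignancy; range 0–4, the default) and a six-domain set
(autoimmune/inflammatory, malignancy, lymphadenopathy, recurrent
infections, hypo-/hypergammaglobulinemia, hepatosplenomegaly). Samples
missing any configured domain are excluded from clinical scoring and
reported, mirroring the common pattern in which clinical completeness is
lower than immunophenotyping coverage. **clinical_z** standardizes CDS over
the scored patients (controls carry no clinical table).

**Balance search.** `select_balance` is a greedy forward search over
compositional balances: the candidate score for disjoint sets $(N, D)$ is
the log-contrast $\overline{\log x_N} - \overline{\log x_D}$, scored by
cross-validated AUC against a binary outcome. The search starts from the
best single pair and adds one variable per step to whichever side improves
the criterion most, stopping at `max_vars` or when the improvement is below
tolerance. Because the log-contrast has no fitted parameters, a naive CV of
a fixed balance equals its apparent AUC; the reported criterion is
therefore an *outer* cross-validation in which the greedy selection is
repeated inside each training fold and the fold-specific balance is scored
on the held-out fold. On pure noise this criterion stays near 0.5 while a
genuinely discriminative balance scores near its true out-of-sample AUC.
Balance trees and the visualization layer of full compositional-balance
toolkits are out of scope.

## Group statistics and delta-correlation networks

Per-subset patient-vs-control comparisons use the two-sided Mann–Whitney
test: the exact null distribution when both groups have ≤ 8 samples and no
cross-group ties, the tie-corrected normal approximation otherwise.
Multiplicity is controlled by Benjamini–Hochberg across all subsets tested
in one call (one family, no hierarchy); subsets constant across all samples
have no defined statistic and are flagged and excluded from the family.

Correlation matrices default to Spearman (robust for bounded percentages);
Pearson is used where a linear correlation is explicitly wanted (the
IDS–clinical_z coupling). Constant columns yield undefined correlations
that propagate as missing and never form network edges.

The delta network connects subset pairs with
$|\Delta r| = |r_{patient} - r_{control}| \ge$ a threshold (default 0.4,
configurable; deliberately conservative since no edge-level significance
test is attached). Each edge records both group correlations, Δr, the sign
of the dominant association, and which group carries it. When the two
magnitudes are within 0.1 of each other — the fully reversed association —
the edge is reported from the control reference: the healthy association
that was lost or reversed in patients. Node degrees and a degree-sorted hub
ranking accompany the edge list.

The 2-D embedding (`embed_2d`) is a visualization contract, not a
contribution: scikit-learn t-SNE (exact method, PCA initialization, fixed
seed) on internally standardized features. It is validated only through
neighborhood-preservation properties (trustworthiness, blob purity), and
cohorts are small enough that the exact O(n²) method is the right trade.

## SOM metaclustering

Sample immunophenotypes (subset-frequency vectors, z-scored over the full
cohort) train a small online Kohonen map: default 4×4 grid, 200 epochs,
initial learning rate 0.5 decaying linearly to 0, Gaussian grid
neighborhood with radius decaying from half the grid diagonal to 1, one
explicit seed for initialization and presentation order. Codebook nodes are
merged by average-linkage Euclidean hierarchical clustering cut at k
(default 8) metaclusters; consensus-clustering variants were omitted for
determinism. Metacluster labels are renumbered MC1..MCk by descending
training-sample occupancy, so MC1 is always the most populated and labels
are reproducible given seed and data.

Clustering operates at the **sample** level, not per cell: the package
consumes gated frequency tables, and group compositions are fractions of
samples per metacluster. Composition differences (patient − control,
percentage points; they sum to zero by construction) get percentile
bootstrap 95% CIs from resampling samples within group (default 1000
draws). Within each metacluster with at least 2 samples per group, marker
differences are reported as z-score differences with Mann–Whitney p and BH
q (FDR family = features within that metacluster); undersized metaclusters
are flagged untested, never silently zeroed. Metacluster-to-IDS weights
are Pearson correlations between metacluster membership indicators and
per-sample IDS.

## Clinical clustering

Patients are clustered on binary clinical profiles. The distance is
Jaccard, $d = 1 - |a \cap b| / |a \cup b|$, with two all-zero rows at
distance 0 by convention: two patients with no recorded findings are
clinically identical under this feature set. Rows with missing values are
excluded and reported. The embedding for display is classical (Torgerson)
MDS — double-centering eigendecomposition with negative eigenvalues
truncated — which round-trips Euclidean configurations exactly.

The clusterer is PAM (partitioning around medoids), k = 3 by default.
Because Jaccard is non-Euclidean, PAM rather than k-means is the canonical
choice; partition-based feature importance accepts any partition. For
realistic cohort sizes the optimal medoid set is found by exhaustive
enumeration (whenever $\binom{n}{k} \le 5\times10^4$); beyond that, greedy
BUILD plus best-improvement SWAP runs to convergence. All ties resolve to
the lowest index, making the result fully deterministic.

Feature importance permutes one binary feature at a time, reclusters, and
reports the mean of 1 − ARI against the original partition (clipped at 0):
load-bearing features scramble the partition when permuted. Severity tiers
map the three clusters to mild/moderate/severe by ascending mean CDS, with
ties broken by cluster size (larger = more severe) — a data-driven rule in
place of narrative assignment.

## Prediction and validation

ROC analysis enumerates all empirical cutpoints (positive = score ≥
threshold); AUC uses the rank formulation with half credit for ties; the
95% CI is DeLong's (deterministic; a bootstrap variant can be cross-checked
against it); the operating point maximizes the Youden index, ties resolving
to the lowest threshold. Composite severity models take the four features
(Pro_mean, Anti_mean, IDS, ΔIDS) into either a one-vs-rest logistic
(per-class binary fits, probabilities renormalized to sum to 1) or a random
forest; discrimination is reported one-vs-rest per class with no
macro-averaging claim. Variable importance is permutation-based mean
accuracy decrease.

Calibration uses equal-count decile bins (bin sizes differ by at most 1;
fewer bins when n is small) plus intercept and slope from a logistic fit of
the outcome on logit(prediction); predictions at the 0/1 boundary are
clipped to [1e−6, 1−1e−6] and logged, and constant predictions flag the
slope undefined. Decision curves report net benefit
$\mathrm{TP}/n - (\mathrm{FP}/n)\,p_t/(1-p_t)$ against treat-all and
treat-none references.

Internal validation follows Harrell's bootstrap optimism procedure
(default B = 500 resamples; the implementation requires B ≥ 200): refit on
each resample, optimism = metric on the resample minus metric on the
original data, corrected = apparent − mean optimism; failing draws are
skipped and counted. Repeated stratified 10-fold CV (folds reduced with a
warning when the smallest class is below k) serves as the sensitivity
analysis. Two honesty caveats are worth knowing and are exercised by the
test suite. First, the optimism estimate retains a small residual bias for
rank metrics at very small n (the boot model is partly evaluated on its own
training points), and cannot rescue a pure memorizer such as an unpruned
random forest scored on in-bag points; with models of moderate flexibility
it removes well over half of the apparent-vs-true gap. Second, the CV mean
of a *single* null dataset inherits that dataset's accidental structure
(SD ≈ 0.09 at n = 100, p = 4), so chance-level behaviour is asserted on
means over independent null datasets.

## Synthetic cohorts

The generator exists so every downstream stage is testable without patient
data; it emulates the statistical structure the analysis assumes, not any
real cohort. Frequencies are simulated on the logit scale — Gaussian draws
around per-subset baselines, optionally correlated within group via a
Cholesky factor of a target correlation matrix (non-positive-definite
targets are rejected), then back-transformed to percent — which keeps every
value strictly inside (0, 100) and approximately preserves correlation
targets. Default size is 39 patients / 17 controls; default baselines are
plausible percent-of-parent locations for a paediatric panel of 12 subsets;
default effect signs contract the regulatory and memory compartments and
expand the follicular-helper-like and activated CD8 subsets, with
magnitudes (≈0.6–0.8 logit) chosen for testability — no published effect
sizes exist to calibrate against, only significance levels.

One latent severity per patient, Beta(2, 2) by default, couples the layers.
Clinical domains are Bernoulli with increasing affine probability in
severity. Cellular shifts keep their configured sign for every patient but
are attenuated with severity (multiplier $1 - 0.8\,s$): the model is a
cohort in which the clinically severest patients — under immunomodulatory
treatment pressure and effector exhaustion — show the least florid
inflammatory expansion. This single axis with opposed gradients is what
produces, simultaneously, a clear patient-vs-control IDS separation and an
inverse IDS–clinical_z correlation, the qualitative pattern the analysis
is designed to detect. `plant_correlation_flip` returns a config whose
cohorts carry a requested within-group correlation change for one subset
pair, the fixture for delta-network recovery.

What the generator does **not** emulate: event-level cytometry noise,
spillover or batch effects, age-structured reference ranges, missingness
mechanisms, or genotype-specific effect profiles. Passing tests therefore
demonstrate that the machinery recovers planted structure of the assumed
form, not that any particular clinical cohort has that structure.

## Problem sizes and determinism

Oracle-equivalence checks run the sizes that make brute force exact:
1,000 random AUC instances (n ≤ 30, with ties), 1,000 BH vectors (length ≤
12), 200 PAM instances (n ≤ 8) against exhaustive medoid search, full
Mann–Whitney enumeration for groups ≤ 6. Simulation checks use n = 500/500
for correlation-flip recovery and n = 100–300 elsewhere; bootstrap checks
use B = 200 (the implementation's floor) while the library default stays
B = 500. All randomness flows through explicit integer seeds — generation,
SOM training, bootstraps, CV folds, permutations — and the pipeline stamps
every artifact with the config hash and seed; wall-clock timestamps live
only in the manifest, so repeated runs are byte-identical.

## Known limitations

- The sample-level reading of metaclustering is a design choice; per-cell
  clustering of FCS events is out of scope.
- ΔIDS and Pro/Anti means follow the definitions above; other re-centering
  or weighting conventions exist and results are not interchangeable
  without the recorded metadata.
- Severity tiering requires k = 3; other k return untided clusters.
- DeLong CIs are asymptotic and can be wide or boundary-clipped at the
  cohort sizes typical of rare-disease studies.
- The greedy balance search explores a restricted path through balance
  space and can miss optima a full enumeration would find.
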