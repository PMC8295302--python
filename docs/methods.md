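# Methods

## Prognosis labels and cohort filtering

Each patient's label derives from 5-year disease-specific survival:
`disease_death` at time ≤ 60 months → *poor*, after 60 months → *good*;
alive and other-cause deaths are censored and stay *unlabeled*. The
60-month boundary is inclusive on the poor side ("within five years"
naturally includes the endpoint) and configurable. Samples with an unknown
event are treated as censored — the safest reading of the censoring rule.
Filtering proceeds in a fixed cascade (no expression → excluded; censored
→ unlabeled; labeled with any missing required clinical feature →
excluded) and logs every removal, so the identity
`labeled + unlabeled + excluded = input` is checkable. The stratified
train/test split rounds per-class test counts half-to-even and then
adjusts the largest class by ±1 so the total matches the rounded overall
target; the default test fraction is 0.2 and is configurable because only
the resulting counts, not the fraction, are conventionally reported.

## The core selector

The selector is unsupervised: it never reads prognosis labels and is run
on unlabeled + training samples only. Seven split criteria are supported.
ER/PR/HER2 split by IHC status (positive = group A); TN puts
ER−/PR−/HER2− samples in group A; HP requires ER+ *and* PR+ (the
conjunction reading of "ER+/PR+"; an OR variant is a config switch);
MKI67 and PLAU split at the cohort-median expression of that gene, ties
to the below-median group, because proliferation and uPA markers rarely
carry IHC statuses in clinical tables.

The ANOVA filter is the two-group one-way ANOVA (equivalently the
equal-variance t-test, F = t²), retaining genes with p < α; α defaults to
0.05 as no threshold is conventional. Genes constant in both groups with
equal means get p = 1. Group networks weight every interaction edge whose
endpoints survive the filter by the within-group Pearson correlation
(Spearman available); an undefined correlation (constant gene) becomes
weight 0 with a log entry.

The per-gene score is the degree-normalised sum of absolute edge-weight
differences between the two group networks (so scores live in [0, 2]); an
unnormalised-sum variant is kept as configuration. This is the minimal
formula that captures "how differently a gene interacts with its partners"
and makes the score comparable across hub and leaf genes. Genes absent
from the network, or isolated after filtering, score 0 and sort last — the
method is network-based by construction. Ranking is score-descending with
a lexicographic gene-symbol tie-break, tied scores receiving their average
rank.

## Ensembles

*Data perturbation* draws `floor(0.7·N)` samples without replacement five
times (both knobs configurable; the chosen setting is the one reported to
work best), runs the selector per subsample, and **sums** the score
tables; a gene filtered out in a replicate contributes 0 there. Subsamples
are stratified by the criterion's two groups to avoid group collapse at
small n, and an infeasible replicate is redrawn (at most 20 times) with a
log entry. *Function perturbation* converts each criterion's score table
to ranks and takes the **mean rank** per gene; gene universes are unioned,
a gene absent from one table receiving that table's worst rank + 1. The
*hybrid* ensemble applies data perturbation within each criterion and
rank-mean aggregation across criteria. Two reduction laws hold exactly and
are tested: one replicate at rate 1.0 reproduces the bare selector, and a
single-criterion hybrid reproduces data perturbation.

## Random validation of rankings

A ranking is scored by repeated stratified 3/4 : 1/4 re-splits of the
training partition. Per split, a logistic regression (L2, C = 1, features
z-scored on sub-train statistics only) is fitted on the top-k genes for
k = 1…50 and scored by validation AUC; the *summarized area* of one
iteration is the mean of the 50 AUC values — the same ordering as any
fixed-width quadrature, but unit-free and bounded in [0, 1]. Per-iteration
split seeds derive deterministically from the master seed, so methods
compared share identical splits and the one-tailed paired t-test
(t = d̄/(s_d/√n), upper tail of Student-t with n−1 df; zero-variance
differences map to p ∈ {0, ½, 1} by sign) is exactly paired. The default
mode ranks once on the full training data (measuring the *gene set's*
robustness on unseen splits); a re-rank-per-iteration mode measures
selection variability instead, since the original procedure is ambiguous
on this point. Hold-out test samples never enter stage-1 validation.

## Classifiers

Stage 2 trains logistic regression, RBF-SVM, random forest (scikit-learn),
a feed-forward DNN and a bimodal DNN on gene / clinical / combined feature
bundles. The gene features are the five established markers (ESR1, PGR,
ERBB2, MKI67, PLAU) plus the top-k selected genes, k defaulting to the
peak of the averaged top-k curve (smallest k at the maximum). Clinical
categoricals are one-hot encoded with an explicit `unknown` level;
everything is z-scored on training statistics only, replayed at prediction
time. Class imbalance is handled by class-weighted losses.

The neural nets are a compact numpy implementation: dense→ReLU stacks with
inverted dropout, a sigmoid head, class-weighted binary cross-entropy,
Adam, and early stopping on an inner stratified 20% split by AUC. The
bimodal variant processes the gene matrix (default hidden 64→32) and the
clinical matrix (16→8) in separate branches whose outputs concatenate into
a joint layer (16) before the sigmoid; these sizes, dropout (0.3), and
learning rate are grid-searchable defaults, not reported values.
Hyperparameters are chosen by stratified 4-fold cross-validation on mean
validation AUC, ties going to the first point in documented grid order.
Training is deterministic given the seed under single-threaded numpy.

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counting ½ — tested against brute-force pair
enumeration.

## Survival validation

The event is disease-specific death; alive/other-cause are right-censored.
Kaplan–Meier estimation, the two-group log-rank test and the Cox
proportional-hazards baseline (Breslow ties, standardized features,
per-unit coefficients reported) go through lifelines; degenerate log-rank
inputs (no events, zero variance) return (0, 1) by convention. Harrell's C
is implemented directly from its pairwise definition — a pair is
admissible iff the strictly earlier time is an observed event, risk ties
count ½ — because library versions add tied-time conventions beyond that
contract; lifelines serves as a cross-check on tie-free data. The survival
report splits samples at score ≥ 0.5 into predicted-poor/good groups and
emits both KM curves, 5-year survival per group, the log-rank χ²/p and the
C-index of the continuous scores; a single predicted group downgrades the
log-rank to a warning.

## The synthetic cohort generator

The generator emulates the *structure* of a breast-cancer microarray
cohort, not its biology. Each sample has a latent prognosis class (40%
poor). Expression is a Gaussian copula over the interaction network: a
per-class correlation matrix with `base_rho` (default 0.1) on every edge
and `base_rho ± delta_rho/2` on edges incident to the planted genes
(+ in poor, − in good), projected to the nearest positive-semidefinite
correlation matrix (spectrum clipped, diagonal renormalised) and sampled
via its Cholesky factor — giving direct control of the within-class edge
correlations that the selector's score measures. Infeasible settings
(`|base_rho| + delta_rho/2` ≥ 0.99) are rejected up front.

Every gene also carries a class mean-shift with random sign. Background
magnitudes are U(0.4, 0.8); planted genes receive an extra
`planted_shift_boost · delta_rho` (default 0.6 per unit). The coupling is
deliberate and serves two purposes: at `delta_rho = 0` planted and
background genes are *exactly* exchangeable (the null-calibration tests
rely on this), while at `delta_rho > 0` differential co-expression comes
with differential expression — as in real tumours — which is what lets the
ANOVA filter retain planted genes and lets random validation separate
selection methods by predictive power. Biomarker statuses are drawn with
class-dependent prevalences (ER+ 0.78 good / 0.42 poor; PR+ 0.74/0.40;
HER2+ 0.14/0.46; 3% unknown), and MKI67/PLAU get fixed poor-side shifts
(1.0 and 0.9) so their median splits align with prognosis. These
prevalences and shift ranges were calibrated once, during generator
development, to place the seven criteria in an informative-but-imperfect
regime — single criteria recover most but not all planted genes — and then
frozen. Survival is class-conditional exponential (means 40 / 150 months),
with a censoring rate of 0.35 realised as uniform truncation of the event
time and an alive/other-death event; clinical covariates mix
class-informative and noise columns plus an ordinal grade.

What the generator does **not** model: probe/batch effects, heavy-tailed
intensity noise, realistic network topology (edges are Erdős–Rényi),
copy-number or mutation structure, non-proportional hazards. Passing tests
therefore demonstrate that the pipeline recovers the *kind* of signal it
is designed for under controlled conditions — not performance on real
cohorts.

## Problem sizes and numerical choices

The default simulated conditions are 600 samples × 500 genes, mean network
degree 6, 20 planted genes, `delta_rho = 0.6`; recovery statistics average
5 seeds and stability comparisons use 30 random-validation iterations —
sizes chosen so the full acceptance run completes in about a minute on one
CPU while preserving the high feature-to-sample regime in spirit.
Correlations are clipped to [−1, 1] against floating-point drift;
undefined correlations become 0; iteration and replicate seeds spawn from
`numpy.random.SeedSequence` so every comparison is reproducible and
paired. The Cox fit declares rank-deficient design matrices an error
rather than silently dropping columns.

## Known limitations

The exact score formula of the original selector, its ANOVA threshold, the
original DNN layer sizes and hyperparameter grids are not recoverable from
the available description; the choices above are this package's own
defaults, flagged as such. The MKI67/PLAU split point (cohort median) is
likewise a documented convention. Real-data reproduction of published
figures is out of scope by design.
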