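# Methods

## What the simulator emulates

The generator stands in for a multi-ancestry genotype resource: five
ancestry labels (EUR, AMR, SAS, EAS, AFR), 500 biallelic SNPs with minor
allele frequencies in [0.05, 0.95], 10,000 EUR individuals and 2,000 per
non-EUR population. Two forms of inequality are built in. *Sample-size
inequality* comes from the 5:1 cohort ratio. *Distribution shift* comes
from per-SNP effect sizes: the DDP vector is `W' = ρW + √(1−ρ²)ζ'`, with ρ
following the distance-decay schedule `ρ_k = 0.8·(d0/d_k)^r`. At the four
printed distances this yields ρ ∈ {0.80, 0.77, 0.58, 0.54} for r = 0.5 and
{0.80, 0.74, 0.42, 0.36} for r = 1.0 — the grid of the SD compendium
(16 datasets at case:control 1:1; the SD* compendium repeats it at 1:4).

Allele-frequency divergence uses a Balding–Nichols beta draw around the
EUR frequency with spread parameter c, clipped to the admissible band.
c is calibrated by bisection + Monte-Carlo (20 profile draws per
candidate) until the expected L1 distance matches the target; at panel
sizes other than 500 SNPs the target scales proportionally so the per-SNP
divergence regime is unchanged.

**What the generator does not emulate:** linkage disequilibrium, admixture
tracts, genotyping error and missingness, covariate-driven confounding,
age/sex structure. Genotypes are independent across SNPs, so effective
information per SNP is higher than in real panels; small-cohort models
(Ind2) fit somewhat better here than on real LD-laden data. Passing tests
therefore demonstrate correctness of the machinery and reproduction of the
qualitative inequality/shift phenomena, not calibrated real-data effect
sizes.

## Liability model choices

The printed liability is `g = h·Σ w_j x_ij + a·√(1−h²)·ζ` with ζ "a
standard normal over [−1,1]" — a contradictory description; we read it as
a standard normal truncated to [−1,1] (a `truncated_noise=False` flag
restores the plain normal). Two normalizations make h² interpretable as
heritability: the weighted genotype score is standardized to zero mean and
unit variance within each population, and ζ is rescaled to unit variance
(the truncated distribution has variance ≈ 0.291, so a = 1/0.5396 ≈ 1.85).
With both in place Var(g) ≈ 1 and the squared correlation between g and
the genetic score equals h² — verified at n = 10,000 within ±0.03.

Thresholds are empirical quantiles of the realized liabilities, computed
independently per population, with strict `g > thr`; ties (measure-zero
for continuous g) fall to the control side. Case counts match the target
ratio exactly up to one individual.

An optional clinical-covariate mode (off by default) appends one
standard-normal continuous and one centred Bernoulli(0.5) covariate with
configurable liability effects, to exercise the clinical terms of the
linear transfer model on data where their ground truth is known.

## Preprocessing

Dosages are standardized per population using that population's training
split mean/sd (labels never touched). The location shift between
populations' dosage distributions is invisible to a linear score (it only
moves the intercept, and AUROC is computed within one population) but an
EUR-trained ReLU network scoring DDP individuals through EUR-centered
inputs loses most of its transferable signal. Per-population scaling —
the analogue of using population-specific allele frequencies in polygenic
scoring — restores naive-transfer behavior to the level the linear model
shows. Raw unstandardized dosages do not train at all under the step
sizes below.

## Predictors

*Logistic regression*: scikit-learn, L2 penalty (default strength 1.0 on
the likelihood scale), stochastic-average-gradient solver, tol 1e-6,
seeded. Non-convergence is warned about, never hidden.

*Neural network*: input K → dense 100 (ReLU) → dropout p = 0.5 → sigmoid,
implemented on NumPy. Glorot-uniform initialization (seeded), mini-batch
SGD with batch 32, Nesterov momentum 0.9, initial learning rate 0.25
decayed per update as lr_t = lr0/(1 + 0.003·t), at most 200 epochs, early
stopping monitored on validation accuracy with patience 200 and
best-epoch weight restoration. The loss is the summed binary
cross-entropy plus λ1|W| + λ2‖W‖² (λ1 = λ2 = 0.001) over the two weight
matrices; because batches optimize the *mean* cross-entropy, the penalty
coefficients are scaled by 1/n_train so the optimized objective matches
that sum form. Applying the penalties at full strength per batch instead
drives all hidden units dead on 2,000-individual cohorts. Two numerical
guards: mini-batch gradients are clipped to global norm 1.0 (without
clipping the 0.25 step with momentum 0.9 diverges within the first epoch
on 500 standardized features), and training aborts on non-finite loss.
The L1 subgradient at zero is taken as 0. Inference disables dropout and
is deterministic.

## Transfer learning

*Deep*: supervised fine-tuning continues mini-batch SGD from the
pretrained weights on target-domain data, all layers trainable, early
stopping on the target validation split. The decay schedule continues
from the pretraining step count — the behavior of refitting a compiled
model whose optimizer state persists. Restarting the schedule at the full
step size erases the source representation before the small target cohort
can be fit, leaving transfer no better than target-only training. The
pretrained model object is never mutated, which yields the package-level
Pareto guarantee: EUR-facing results (Ind1, Mix1) are byte-identical
whether or not any transfer run happens in the same session.

*Linear*: the target effect of SNP j is decomposed as β_j^pre + τ_j
(clinical terms γ_k^pre + δ_k analogously). The adjustments are estimated
by L2-penalized logistic regression with the pretrained linear predictor
as a fixed offset; the penalty shrinks toward the source model, infinite
penalty reproduces naive transfer, zero penalty reproduces a target-only
refit. Penalty strength is chosen on the target validation split from the
grid {0.01, 0.1, 1, 10, 100, 1000}. Note that this convex
shrinkage-toward-source estimator is statistically strong: in this
simulator's exactly linear world it attains roughly the deep-transfer
level, so the deep-vs-linear transfer difference D is near zero here
rather than clearly positive as it is for gradient-descent-style linear
transfer heuristics on real cohorts. See "Known limitations".

## Experiments and evaluation

Splits are 80/10/10 stratified jointly by ancestry and label, frozen per
dataset; replicate runs vary only model initialization and batch order,
making cross-experiment comparisons paired by run. Mix0/Mix1/Mix2 share
one pooled model per run; Ind1, NT and the TL pretraining stage share the
EUR model of the run. An access-auditing wrapper counts every label read
by (population, split); tests assert that naive transfer never touches
DDP training labels and that test labels are only read at evaluation.

Quality control (for user-supplied or exported dosage tables) drops SNPs
with missing rate > 20%, MAF < 0.05 or Hardy–Weinberg exact-test p below
a configurable floor (10⁻⁵ default; a chi-square flavor and a
controls-only mode are flags), drops samples with > 20% missing dosages,
prunes LD greedily in 50-SNP windows stepping by 5 at r² > 0.2 keeping
the lower-p member of each pair, and ranks features by one-way ANOVA F on
the training split only.

Metrics: AUROC (tie-aware), AUPR (step integration), Tjur's R² (case
minus control mean predicted probability), and threshold-dependent
sensitivity/specificity/PPV/NPV at the Youden-optimal threshold. The
threshold is tuned on the validation split of the evaluated population
and applied to its test split (a flag allows tuning on test for
exact-replication comparisons). Prevalence-adjusted predictive values
recompute PPV/NPV from sensitivity/specificity at a supplied population
prevalence. Rank-sum tests are exact (full enumeration) when both groups
have ≤ 12 observations and normal-approximate with tie correction
otherwise; signed-rank tests are exact up to 25 pairs.

## Problem sizes used by the shipped checks

The full compendium (16 datasets × 20 runs × 7 experiments × 2 model
kinds at 200 epochs) is a multi-hour computation. The shipped acceptance
checks use a desk-scale subset chosen once: SD1–SD4 (h² = 0.5, r = 0.5 —
the four ancestries at full cohort sizes and 500 SNPs), 5 runs, the
Ind1/Ind2/NT/TL experiments, neural-network training capped at 100 epochs
(validation-based restoration typically selects epochs well below that).
Statistical-recovery checks run at n = 10,000 with 50 effect-vector
draws. BLAS is pinned to one thread in tests and the acceptance script so
trained weights are bit-reproducible.

## Known limitations

- Independent-SNP genotypes make small-cohort fits stronger than on real
  data; disparity gaps are reproduced qualitatively, with smaller
  magnitudes than LD-laden cohorts show.
- The offset-penalized linear transfer is a stronger estimator than
  gradient-descent linear-transfer heuristics; consequently the
  deep-minus-linear transfer difference D is ≈ 0 in this synthetic world
  (deep transfer still clearly beats naive transfer and target-only
  training at strong shift).
- The Youden threshold, tuned on 10% validation splits, is noisy for the
  2,000-individual DDP cohorts; threshold-dependent metrics inherit that
  noise.
- No GPU path; the network is small enough that NumPy on one core trains
  an EUR model in seconds to tens of seconds.
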