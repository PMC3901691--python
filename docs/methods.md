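# Methods

## Problem and model

`dnabindpred` predicts whether a protein chain binds DNA from sequence-derived
information alone: the primary sequence, a predicted 3-state secondary
structure (H/E/C) with per-residue relative solvent accessibility (RSA), and
a PSI-BLAST position-specific scoring matrix (PSSM). The pipeline has four
stages:

1. **Encoding.** Each chain becomes a fixed vector of 1486 named descriptors
   in thirteen families (see below).
2. **Ranking.** A random forest orders descriptors by Gini importance
   (mean decrease in impurity); the top *k* (default 300) form the candidate
   pool.
3. **Wrapper selection.** Forward best-first search grows a subset from the
   pool, scoring every candidate set by the mean Matthews correlation
   coefficient (MCC) of Gaussian naive Bayes (GNB) under ten seeded runs of
   five-fold cross-validation.
4. **Classification.** GNB fitted on the selected descriptors produces a
   posterior probability of DNA binding, the real-valued output used for ROC
   analysis.

## Descriptor families

With residue types *x, x′* over the 20 amino acids, SS states *y* ∈ {C, H, E},
RSA cutoffs *h* ∈ {0.1, …, 0.5}, percentile thresholds *t* ∈ {0, 25, 50, 75,
100} and lags *m* ∈ {1, …, 10}:

| family | meaning | count |
|---|---|---|
| `Con_SS_y` | fraction of residues in SS state y | 3 |
| `AveRSA_Res_x`, `AveRSA_SS_y`, `AveRSA_Res_x_SS_y` | mean RSA over residue subsets | 20+3+60 |
| `AAC_Res_x`, `AAC_Res_x_SS_y` | composition, plain / SS-conditioned | 20+60 |
| `AAC_Res_x_Ex_h`, `AAC_Res_x_Bu_h` | composition of exposed (RSA ≥ h) / buried residues | 100+100 |
| `DIC_Res_xx′` | dipeptide composition (counts / (L−1)) | 400 |
| `AvePscore_AA_x`, `AvePscore_AA_x_Res_x′` | normalized-PSSM column means, plain / residue-conditioned | 20+400 |
| `Pscore_AA_x_P_t` | nearest-rank column percentiles | 100 |
| `AutoCC_AA_x_Lag_m` | lagged column auto-correlation | 200 |

Raw PSSM scores *s* are first mapped through the standard logistic
1/(1+e^(−s)), so every PSSM statistic lives in (0, 1). The auto-correlation
at lag *m* of a column series S with mean S̄ is

    r_m = Σ_{i=1}^{L−m} (S_i − S̄)(S_{i+m} − S̄) / Σ_{i=1}^{L} (S_i − S̄)²

normalized by the full-series sum of squares, which bounds it in [−1, 1].
Zero-variance columns give 0; lags ≥ L give 0 with a warning.

Numerical conventions, chosen for reproducibility and documented here because
upstream descriptions leave them open:

* conditional means/compositions over an empty residue subset are 0, not NaN;
* percentiles use the nearest-rank rule (no interpolation); t = 0 and t = 100
  are exactly the column minimum and maximum;
* descriptor order is fixed: families in the table's order, residue types in
  alphabetical one-letter order, then the secondary parameter; the name
  grammar (`family_param[_param]`) is parseable, and the parser also accepts
  published typographic variants (stray spaces, doubled/trailing underscores,
  the `DIP` alias of the dipeptide family).

## Classifier

GNB assumes class-conditionally independent Gaussian features:
P(y|x) ∝ P(y) Π_i N(x_i; µ_{y,i}, σ²_{y,i}). Priors are class frequencies;
means and variances are per-class maximum-likelihood estimates. Every
variance is floored by ε = 10⁻⁹ × (largest pooled per-feature variance) so
constant features cannot yield singular densities; all density arithmetic is
in log space because a 1486-term product underflows double precision. The
positive class is the larger training label; a posterior of exactly 0.5 is
classified positive (a deterministic, documented tie rule). Under this
smoothing convention the posteriors agree with scikit-learn's
`GaussianNB(var_smoothing=1e-9)` to 10⁻⁹, which the tests use as an
independent cross-check.

## Evaluation protocols

Sensitivity, specificity, accuracy and MCC are computed from a confusion
matrix; a zero MCC denominator gives 0 by convention, while an empty actual
class is an error. One *run* of n-fold CV shuffles the chains with a seed and
splits them into n folds whose sizes differ by at most one (stratification is
available but off by default, since plain random division is the protocol's
baseline). Within a run, confusion counts are pooled over folds and metrics
computed once; means and standard deviations are then taken across runs. The
jackknife (leave-one-out) test is an N-fold CV with a single deterministic
run. ROC curves sweep all score thresholds (ties grouped) and AUC is the
trapezoidal area, equal to the pairwise concordance statistic.

## Wrapper search

Step 1 selects the single pool descriptor with the largest mean MCC; every
later step adds the candidate maximizing the mean MCC of the augmented set.
The search tolerates temporary dips and stops after `patience` (default 10)
consecutive steps without improvement over the best mean MCC so far, or at
the step `budget`. The reported final set is the earliest trace prefix
attaining the maximal mean MCC. Ties between candidates are broken by pool
order, i.e. by the stage-1 Gini rank.

Each step scores its candidates on CV folds re-drawn deterministically from
(plan seed, step index) — `reseed_per_step=True`. Reusing one fixed fold set
for every step lets candidates that happen to suit those particular folds
accumulate, biasing the apparent MCC curve upward; per-step redraw removes
the fold-level component of that bias while the whole trace remains a pure
function of (matrix, pool, plan).

A limitation no within-dataset scoring can remove: in a finite sample of a
few hundred chains, a genuinely uninformative descriptor can carry a chance
class difference of ~0.1–0.2 pooled SD, which is real signal *inside that
dataset* and therefore indistinguishable from truth by cross-validation. In
consequence (i) on effect-free data, greedy selection inflates its final
apparent MCC to roughly 0.2–0.35 (the selected subset re-evaluated under
fresh folds scores near 0, which is the right way to audit a selection), and
(ii) recovered subsets mix true effects with a few such chance descriptors.
The planted-signal tests quantify this: with five 2.5-SD planted descriptors
among 50 noise descriptors at n = 300, the mean Jaccard overlap between the
selected set and the generative truth is about 0.6 (series means 0.55–0.78
across seed batches), with per-dataset values scattering from ~0.1 (a run
that ballooned with chance descriptors) to 1.0 (exact recovery). A planted
single descriptor, by contrast, is the top-5 Gini feature and the wrapper's
first selection essentially always.

## Synthetic data generator

The generator emulates every input kind so the pipeline is testable without
external programs: sequences from a background AA composition (uniform by
default), integer PSSM scores from a normal distribution (mean 0, SD 3,
rounded, clipped to [−10, 10]) — roughly the dynamic range of PSI-BLAST
log-odds, secondary structure from a first-order Markov chain (stay
probability 0.8, giving realistic run lengths), and RSA from a Beta
distribution with concentration 4. Default chain lengths are uniform on
[60, 120] (the benchmark's minimum-length convention at a desk-friendly
scale) with 100 chains per class.

A class *effect* shifts one generating parameter of the positive class so a
named descriptor's expected class difference equals a requested size in
pooled-SD units. The shift is found by Monte-Carlo bisection with common
random numbers on the one generative channel the descriptor depends on;
the realized standardized difference, measured on the encoded dataset, is
recorded in the truth annotation. Supported channels: PSSM column mean
(`AvePscore_AA_x`, `Pscore_AA_x_P_t`), AA frequency (`AAC_Res_x`), SS
stationary distribution (`Con_SS_y`), and per-residue-type RSA mean
(`AveRSA_Res_x`). Everything is reproducible from a single seed, down to
byte-identical files.

What the generator does **not** emulate: evolutionary correlation structure
within and between PSSM columns, sequence–structure coupling, length–label
dependence, or any real DNA-binding biology. Passing tests therefore
demonstrate the pipeline's statistical machinery (encoding identities,
recovery of class-mean effects, calibrated null behaviour), not predictive
performance on real proteins, which additionally requires PSI-BLAST profiles
and an SS/RSA predictor.

## Problem sizes used in the test suite

Simulated checks run at balanced n = 200–300 chains with 50-descriptor
candidate pools, 10 dataset seeds (20 for the selection-overlap estimate,
whose per-dataset scatter is large), ten 5-fold CV runs per evaluation, and
500-tree forests — small enough to run routinely, large enough that the
planted 2.5-SD effects are recovered reliably.

## Known limitations

* GNB's independence assumption is clearly violated by overlapping descriptor
  families (e.g. a column mean and its percentiles); the wrapper mitigates
  this by selecting small subsets but cannot remove it.
* CV-scored greedy selection admits chance descriptors at small n (above).
* The reference selected-feature table ships for taxonomy and significance
  counting; reproducing the benchmark's accuracy figures requires the
  original profile inputs, which are out of scope here.
* The ASA→RSA option uses the Tien et al. (2013) theoretical maximal-ASA
  values; predictors trained on other normalizations will shift buried/
  exposed compositions slightly.
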