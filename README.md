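# dnabindpred

Sequence-based prediction of DNA-binding proteins.

DNA-binding proteins (transcription factors, polymerases, repair enzymes,
nucleosome components) are central to gene regulation, but assigning the
binding function experimentally is slow and expensive. `dnabindpred`
implements a purely sequence-driven predictor: a protein chain, together
with its PSI-BLAST evolutionary profile (PSSM) and predicted secondary
structure / relative solvent accessibility, is encoded into **1486 named
descriptors**; a random forest ranks them by Gini importance; a forward
best-first wrapper search, scored by the cross-validated Matthews
correlation coefficient (MCC) of a **Gaussian naive Bayes** classifier,
selects a compact subset; and the fitted GNB model outputs a posterior
probability of DNA binding.

The descriptor set combines four signal sources. For residue types
*x, x′*, secondary-structure states *y* ∈ {C, H, E}, RSA cutoffs
*h* ∈ {0.1…0.5}, percentile thresholds *t* ∈ {0, 25, 50, 75, 100} and lags
*m* ∈ {1…10}:

* **SS content** — Con_SS_*y* (3);
* **average RSA** — AveRSA_Res_*x*, AveRSA_SS_*y*, AveRSA_Res_*x*_SS_*y*
  (83);
* **composition** — AAC_Res_*x*, SS-conditioned, buried/exposed at cutoff
  *h* (a residue with RSA ≥ *h* counts as exposed), and dipeptide
  composition DIC_Res_*xx′* (680);
* **PSSM statistics** over the logistic-normalized profile
  s ↦ 1/(1+e^(−s)) — column averages AvePscore_AA_*x*, residue-conditioned
  averages, nearest-rank percentiles Pscore_AA_*x*_P_*t*, and lagged
  auto-correlation coefficients AutoCC_AA_*x*_Lag_*m* ∈ [−1, 1] (720).

The GNB classifier assumes class-conditionally independent Gaussian
features, P(y|x) ∝ P(y) Π_i N(x_i; µ_{y,i}, σ²_{y,i}), with class-frequency
priors and smoothed maximum-likelihood variances; evaluation uses repeated
seeded 5-fold cross-validation, the jackknife test and ROC/AUC analysis.
`docs/methods.md` describes the model, its conventions and limitations.

The package is laid out as scikit-learn-style estimators
(`GaussianNaiveBayes`, `GiniImportanceRanker`, `ForwardBestFirstSelector`)
plus plain functions for encoding, evaluation, feature statistics and
synthetic data generation, and a `dnabindpred` command-line tool
(`simulate`, `encode`, `rank`, `select`, `train`, `predict`, `evaluate`,
`analyze`).

## Worked example

No external programs are needed: the synthetic generator emulates all three
input kinds (sequences, PSSM files, SS/RSA profiles) with controllable
class effects.

```python
from dnabindpred import (CVPlan, Effect, EffectConfig, GiniImportanceRanker,
                         forward_best_first, generate_dataset, run_cv)

# a small simulated study: one informative PSSM descriptor planted at 2 SD
ds = generate_dataset(EffectConfig(seed=7, n_pos=60, n_neg=60,
                                   effects=(Effect("AvePscore_AA_R", 2.0),)))
matrix = ds.encode()
print("encoded:", matrix.X.shape)

ranker = GiniImportanceRanker(n_trees=200, random_state=0).fit(
    matrix.X, matrix.y, feature_names=matrix.descriptor_names)
pool = ranker.top_k(30)
print("top of ranking:", pool[:3])

plan = CVPlan.from_seed(0, n_runs=10, n_folds=5)
trace = forward_best_first(matrix, pool, plan, budget=10, patience=5)
print("selected:", trace.selected)
print("search mean MCC at the peak: %.3f" % trace.best_score)

X_sel = matrix.values[trace.selected].to_numpy()
_, summary = run_cv(X_sel, matrix.y, CVPlan.from_seed(1, n_runs=10),
                    collect_scores=True)
print("fresh-fold 5x10 CV: MCC %.3f +/- %.3f, accuracy %.3f, AUC %.3f" % (
    summary["mean_mcc"], summary["std_mcc"], summary["mean_acc"],
    summary["mean_auc"]))
```

Output:

```
encoded: (120, 1486)
top of ranking: ['AvePscore_AA_R', 'Pscore_AA_R_P_50', 'Pscore_AA_R_P_25']
selected: ['AvePscore_AA_R', 'AvePscore_AA_Q_Res_F', 'AveRSA_Res_G', 'AvePscore_AA_H_Res_W', 'AvePscore_AA_I_Res_T', 'AvePscore_AA_A_Res_W', 'AvePscore_AA_K_Res_R', 'AutoCC_AA_N_Lag_9']
search mean MCC at the peak: 0.859
fresh-fold 5x10 CV: MCC 0.854 +/- 0.020, accuracy 0.927, AUC 0.951
```

The planted descriptor `AvePscore_AA_R` tops the Gini ranking (followed by
percentile descriptors of the same shifted PSSM column) and is the wrapper's
first selection; the remaining picks illustrate how a CV-scored wrapper also
admits a few descriptors whose class difference in this particular 120-chain
sample is real but accidental. Re-evaluating the selected subset under
fresh folds (seeds unrelated to the search) gives an honest performance
estimate — here MCC ≈ 0.85 against a Bayes-optimal ≈ 0.9 for a single
2-SD effect.

The same workflow from the shell:

```sh
dnabindpred simulate --seed 7 --n-pos 60 --n-neg 60 \
    --effect AvePscore_AA_R:2.0 --out data/
dnabindpred encode --manifest data/manifest.tsv --pssm-dir data/pssm \
    --profile-dir data/profiles --out features.tsv
dnabindpred rank --features features.tsv --out ranking.tsv
dnabindpred select --features features.tsv --ranking ranking.tsv \
    --top-k 30 --out-trace trace.tsv --out-set selected.json
dnabindpred train --features features.tsv --subset selected.json --out model.json
dnabindpred predict --model model.json --features features.tsv --out pred.tsv
```

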