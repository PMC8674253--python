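# normsmote

Oversampling for imbalanced binary biomedical tabular data: classic SMOTE and
a Normal-distribution variant that interpolates toward the minority-class
centroid, plus the evaluation metrics and distribution-preservation
diagnostics needed to choose its spread parameter.

## The problem

In clinical tabular datasets the diseased (positive) class is usually much
smaller than the healthy one. Classifiers trained on such data score high
overall accuracy while missing most positives — with 10 diseased among 100
samples, predicting "healthy" for everyone is 90% accurate with zero
sensitivity. Interpolation-based oversampling (SMOTE) mitigates this by
synthesising minority points, but because it interpolates between a minority
point and a random neighbour it tends to *marginalize*: points near the
minority boundary beget more boundary points, blurring the class border.

## The method

Work in min-max normalized feature space, `x' = (x − x_min)/(x_max − x_min)`.
Let `x'_center` be the per-feature mean of the minority rows and
`σ₀ = (σ₁⁰, …, σ_r⁰)` their per-feature sample standard deviations. A new
minority sample from source row `x'_i` is

```
p[j] = x'_i[j] + f_j · (x'_center[j] − x'_i[j]),   f_j ~ N(1, s·σ_j⁰)
```

with an independent Gaussian factor per feature. Since E[f] = 1, synthetic
points concentrate near the centroid (with `s = 1/3`, ~99.7% of factors fall
within σ₀ of 1), avoiding marginalization. Synthesis stops once the imbalance
ratio — minority count over majority count — reaches 0.7, and the synthetic
rows are fused with the normalized originals.

The spread scale `s ∈ {1, 2/3, 1/3}` is selected by distribution-preservation
diagnostics: the Euclidean distance between class centroids and the mean
per-feature sample variance, before vs after expansion. The scale whose
expanded data deviates least from the original tends to classify best.

Evaluation follows the standard protocol for this family of methods:
stratified 3:1 train/test split, stratified 5-fold cross-validation of a
random forest (Gini splitting, `⌊log₂ r⌋ + 1` candidate features per split),
five repeated expansions averaged, reporting accuracy, F-value (harmonic mean
of precision and sensitivity), G-mean (geometric mean of sensitivity and
specificity), and the mean per-tree out-of-bag error.

## Worked example

```python
from normsmote import (FixtureSpec, NormalSmoteConfig, make_gaussian_imbalanced,
                       expand, imbalance_ratio, preservation_comparison,
                       EvalProtocol, evaluate_expansion)

# imbalanced two-class Gaussian data, 45 positives vs 149 negatives
d = make_gaussian_imbalanced(FixtureSpec(n_minority=45, n_majority=149,
                                         r=8, separation=2.0, seed=100))
print(round(imbalance_ratio(d), 4))          # 0.302

res = expand(d, "normal", NormalSmoteConfig(sigma_scale=1.0, seed=7))
print(res.provenance["n_synthetic"],         # 60  (105/149 >= 0.7, 104/149 < 0.7)
      round(res.provenance["achieved_ratio"], 4))   # 0.7047

# spread-parameter selection: compare diagnostics across sigma scales
exps = [expand(d, "normal", NormalSmoteConfig(sigma_scale=s, seed=7))
        for s in (1/3, 2/3, 1.0)]
print(preservation_comparison(d, exps, labels=["1/3", "2/3", "1"],
                              scope="minority").round(6))

# classifier benefit
proto = EvalProtocol(cv_folds=5, expansion_repeats=5, ntree=100,
                     leakage_mode="paper", seed=0)
print(round(evaluate_expansion(d, "none", None, proto).mean.g_value, 4))      # 0.6636
print(round(evaluate_expansion(d, "normal", NormalSmoteConfig(sigma_scale=1.0),
                               proto).mean.g_value, 4))                        # 0.8654
```

The diagnostics table prints (minority scope):

```
          inter_class_distance  sample_variance  ...  best_sample_variance
original              0.364471         0.030775
1/3                   0.364926         0.013064
2/3                   0.365393         0.013196
1                     0.365872         0.013416                      True
```

Expansion barely moves the class-centroid distance (< 0.002 here) while the
minority variance shrinks — least at full scale, which the deviation columns
flag as the best-preserving choice. The G-mean rises from 0.66 to 0.87
because minority recall, the bottleneck on this fixture, improves.

The same pipeline is scriptable from the shell:

```
normsmote simulate --n-min 45 --n-maj 149 --r 8 --sep 2 --seed 5 --output raw.csv
normsmote expand --input raw.csv --label-col label --method normal \
    --sigma-scale 2/3 --seed 3 --output expanded.csv --provenance prov.json
normsmote evaluate --input raw.csv --label-col label --method normal --report eval.json
normsmote diagnose --input raw.csv --label-col label --expanded expanded.csv
```

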