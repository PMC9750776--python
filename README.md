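# mongoosenet

Heart-disease detection from tabular clinical data: quantile
normalization and mixed-type imputation, a two-stage similarity-cascade
feature selection, and a 1-D fire-module convolutional classifier whose
weights are trained by the **dwarf mongoose optimization algorithm
(DMOA)** — a gradient-free, population-based search — with split and
k-fold evaluation protocols. It is aimed at researchers studying
metaheuristic training of small clinical classifiers and at anyone who
needs a reproducible, leak-free baseline for cohort-style tabular data
(rows = patients, mixed numeric/categorical columns, `?` for missing,
outcome graded 0–4 and collapsed to normal/abnormal).

## The method

Given a cohort X (k patients × n attributes) with binary outcome y:

1. **Quantile normalization** equalizes the numeric columns: values are
   replaced by the mean-of-sorted-columns reference at their
   within-column rank (missing entries ignored and carried through).
2. **Imputation** fills missing numeric entries with the column mean and
   missing categorical entries with the modal category.
3. **Feature selection**: each column P is scored against y = R with the
   congruence coefficient J = ΣPR ⁄ √(ΣP²·ΣR²); the top o columns are
   re-scored with the Kumar–Hassebrook similarity
   M = ΣTV ⁄ (ΣT² + ΣV² − ΣTV) and the top z survive (n > o > z).
4. **Classification**: the z features enter a 1-D network — conv →
   fire modules (squeeze + width-1/width-3 expand convolutions) →
   max-pool → final conv → global average pool → softmax. Its flat
   weight vector is found by DMOA minimizing the training MSE
   b = (1/w)·Σ(B\* − B)² between the abnormal-class probability B and
   the label B\*; the pack alternates exploitation ("alpha") and
   exploration ("scout") moves with greedy acceptance, a decaying
   control factor D = (1 − U/HU)^(2U/HU), and periodic babysitter
   re-randomization.

Performance is reported as accuracy, sensitivity and specificity from
held-out confusion counts, under a stratified train-percentage split or
stratified k-fold CV with pooled counts. See `docs/methods.md` for every
convention and default.

## Worked example

```python
from mongoosenet import cleveland_like, generate, split_eval

# 300-patient synthetic cohort: 13 mixed attributes, 5 informative,
# effect size 1.5, 2% missing entries
data, truth = generate(cleveland_like(seed=7))

report = split_eval(data, train_fraction=0.9, seed=1)
print(report.to_dict())
```

```
{'protocol': 'split', 'setting': 0.9, 'seed': 1,
 'tp': 14, 'tn': 15, 'fp': 1, 'fn': 0,
 'accuracy': 0.9666666666666667, 'sensitivity': 1.0, 'specificity': 0.9375}
```

The 30 held-out patients split into 14 true positives, 15 true
negatives, 1 false positive and 0 false negatives: the pipeline detects
29/30 correctly (accuracy 0.967), finds every abnormal patient
(sensitivity 1.0) and clears 15 of 16 normals (specificity 0.94).
Everything — normalization statistics, imputation values, selected
features, network weights — was learned on the 270 training patients
only.

The same pipeline is scriptable from the shell:

```sh
mongoosenet pipeline -c config.yaml   # simulate → preprocess → select → train → evaluate
```

with per-stage subcommands (`simulate`, `preprocess`, `select`, `train`,
`evaluate`) that consume each other's CSV artifacts. Every run writes a
feature report, fitness trace, trained weights and evaluation reports
stamped with a config hash.

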