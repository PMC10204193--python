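# g0kit

Quantification of G0 arrest — quiescent, dormant or drug-tolerant
"persister" cell states — from bulk and single-cell cancer transcriptomes.

Tumours harbour varying fractions of cells that have exited the cell cycle
into G0, either spontaneously or in response to stresses such as serum
starvation, contact inhibition, CDK4/6 inhibition or MEK inhibition. These
cells evade antiproliferative therapy and seed relapse, but leave no single
marker to count them by. `g0kit` estimates the G0-arrest burden of a sample
or cell from expression of a signature of genes coherently up- or
down-regulated across all five forms of quiescence, and provides the
machinery around that estimate: signature construction and refinement from
differential-expression results, stress-programme subtyping, genomic
dependency modelling, and machine-learned reduction of the signature for
sparse single-cell data.

## The score

For an expression matrix standardised gene-wise across the cohort
(z<sub>ij</sub> = (x<sub>ij</sub> − μ<sub>i</sub>)/σ<sub>i</sub>), the
combined Z-score of sample *j* is

```
Z_up(j)  = Σ_{i ∈ G_U} z_ij / √|G_U|
Z_down(j) = Σ_{i ∈ G_D} z_ij / √|G_D|
G0(j)    = Z_up(j) − Z_down(j)
```

over the signature's up-regulated (G_U) and down-regulated (G_D) gene sets.
Higher scores mean a stronger G0-arrest signal; samples scoring above 0 are
called arrested by default. A mean-scaled variant
`G0m = (mean G_U − mean G_D) / mean G_H` (G_H a housekeeping set) and a
normalised-rank comparator are also provided, plus tumour-purity scaling
for bulk cohorts and ROC-AUC evaluation against known labels.

Downstream, the toolkit links the score to genomic features through an
ensemble elastic net (1000 refits on random 90% subsamples; only features
selected in *every* iteration are kept) summarised as a consensus linear
model with exact Shapley attributions, classifies the inducing stress
programme per sample (1-SD + t-test rule in bulk; kNN reference mapping in
PCA space for single cells), and reduces the signature by repeated
random-forest Gini importance with threshold sweeping and external
validation.

The vendored signature files (`g0_139_synthetic.tsv`, `g0_35_synthetic.tsv`,
`housekeeping_synthetic.tsv`) carry synthetic placeholder gene identifiers
with the published set sizes; supply your own two-column TSV or GMT files
to score real data.

## Worked example

Score a simulated single-cell cohort (200 cells, 40% arrested, effect size
3 log2 units on signature genes, 20% dropout) and compare calls to the
planted truth:

```python
from g0kit import (SimulationConfig, simulate_single_cell, generic_signature,
                   combined_zscore, call_states, proportion_arrested, evaluate_auc)

sig = generic_signature()
cfg = SimulationConfig(n_samples=200, effect_size=3.0, dropout_rate=0.2,
                       fraction_g0=0.4, seed=7)
cells, _, truth = simulate_single_cell(cfg, sig)

scores = combined_zscore(cells, sig)
labels = call_states(scores, threshold=0.0)
print(proportion_arrested(labels))
print(f"signature genes used: {scores.n_up_used} up, {scores.n_down_used} down")
print(f"AUC vs planted truth: {evaluate_auc(scores, truth.labels):.3f}")
```

```
  group  fraction_G0    n
0   all        0.465  200
signature genes used: 70 up, 69 down
AUC vs planted truth: 1.000
```

46.5% of cells are called arrested against a planted 40% (the zero
threshold is deliberately permissive; calibrate it per cohort), all 139
signature genes were found, and the score separates arrested from cycling
cells perfectly at this effect size.

The same pipeline is available from the shell:

```bash
g0kit simulate sc --seed 7 --out demo/
g0kit score --expr demo/matrix.mtx --out demo/scores.tsv
g0kit call --scores demo/scores.tsv --out demo/labels.tsv
g0kit auc --scores demo/scores.tsv --truth demo/truth.tsv
```

Other subcommands: `refine-signature`, `classify-stress`, `genomic-model`,
`shap`, `optimise-signature`.

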