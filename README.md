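# ispip — integrated structure-based protein interface prediction

Identifying which residues of a protein form its binding interface guides
mutagenesis, drug design against protein–protein interactions, and the
interpretation of interactomes. Individual structure-based predictors each
exploit one information source — template-based methods map interfaces from
structural neighbours, template-free methods learn from intrinsic
sequence/structure features, and docking-based methods count how often a
residue lands at the interface of poses docked against non-cognate
partners — and each fails on different queries. `ispip` is a
meta-classifier: it trains an integration model on the per-residue
likelihood scores x₁…x_k emitted by such orthogonal predictors and returns
a consensus interface likelihood that is more accurate, and markedly more
robust to one input failing, than any single input.

## The method

Given normalized input scores x = (x₁, …, x_k) ∈ [0,1]ᵏ per residue and
binary interface annotations y, four integration models are available:

* **logistic regression** — P(i | x) = 1 / (1 + exp(−(b₀ + Σⱼ bⱼxⱼ))), fit
  by maximum likelihood;
* **linear regression** — I(x) = b₀ + Σⱼ bⱼxⱼ, fit by ordinary least
  squares, clipped to [0, 1];
* **random forest** — 100 bootstrap trees of depth ≤ 10 (cost-complexity
  pruning α = 0); the likelihood is the mean terminal-node positive
  fraction;
* **gradient-boosted trees** — histogram-binned stagewise additive
  ensemble.

Hyperparameters are chosen by grouped five-fold cross-validation (proteins,
never residues, are the splitting unit), scored by the average per-protein
F-score. Binary calls use a **dynamic cutoff**: for a protein with R
surface-exposed residues, its N = round(6.1 · R^0.3) top-ranked residues
are called interfacial. Evaluation reports per-protein precision, recall,
F-score and MCC (averaged unweighted across proteins), pooled ROC and
precision–recall curves with trapezoidal AUC, and Kolmogorov–Smirnov
comparisons of per-protein F-score distributions.

The surrounding machinery is included: ground-truth annotation from complex
structures (a residue is interfacial when a heavy atom lies within 4.0 Å of
a partner chain), surface-residue counting from relative solvent
accessibility (Shrake–Rupley SASA over Tien et al. maxima), docking-pose
interface-frequency scoring (mean per-partner fraction of poses in which a
residue is at the 4.0 Å interface), and a synthetic benchmark generator
with tunable per-channel signal, inter-channel correlation and channel
failures.

## Worked example

```python
from ispip import (SyntheticConfig, generate_dataset, fit_logistic,
                   evaluate_model, ScoreTable, dynamic_cutoff)

train, _ = generate_dataset(SyntheticConfig(n_proteins=40, seed=0))
test, surface = generate_dataset(SyntheticConfig(n_proteins=10, seed=1))

model = fit_logistic(train)
print("coefficients:", model.coef_.round(3), "intercept:", round(model.intercept_, 3))

scored = ScoreTable(test.frame.assign(consensus=model.predict(test.X())),
                    predictors=test.predictors)
for column in ["template_based", "template_free", "docking", "consensus"]:
    avg = evaluate_model(scored, column, surface).averages
    print(f"{column:15s} F={avg['fscore']:.3f}  MCC={avg['mcc']:.3f}  PR-AUC={avg['pr_auc']:.3f}")
print("dynamic cutoff for R=100 surface residues:", dynamic_cutoff(100))
```

Output:

```
coefficients: [9.07  9.371 9.501] intercept: -16.16
template_based  F=0.460  MCC=0.421  PR-AUC=0.597
template_free   F=0.526  MCC=0.503  PR-AUC=0.618
docking         F=0.448  MCC=0.412  PR-AUC=0.556
consensus       F=0.660  MCC=0.663  PR-AUC=0.924
dynamic cutoff for R=100 surface residues: 24
```

The three synthetic input channels each reach F ≈ 0.45–0.53 on the held-out
proteins; the logistic consensus over them reaches F = 0.66 and lifts the
pooled PR-AUC from at best 0.62 to 0.92 — the integration, not any single
input, drives the gain. The near-equal positive coefficients show each
orthogonal channel contributing comparable evidence.

## Command line

```bash
ispip simulate --n-proteins 50 --seed 0 --out data/
ispip annotate --pdb complex.pdb --query-chain A --partner-chains B,C --cutoff 4.0
ispip dockpred --poses poses/ --query-chain A --partner-chain B
ispip train --model gbt --scores data/scores.tsv --surface data/surface.tsv --out model
ispip predict --model-file model.json --scores data/scores.tsv --out predictions.tsv
ispip evaluate --scores predictions.tsv --surface data/surface.tsv --column ispip
ispip run --out run/ --seed 0        # the full staged workflow + manifest
```

Score tables are tab-delimited text with columns
`protein_id  chain  resnum  icode  <predictor…>  label`.

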