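# Methods

## Problem setting

A query protein's interface residues are predicted from the per-residue
likelihood scores of k upstream structure-based predictors. The package
assumes each upstream score is already a (or normalizable to a) value in
[0, 1]; the integration layer never sees the structures the upstream
methods used, only their scores. Interface prediction is an imbalanced
binary problem — typically 10–20% of residues are interfacial — which
drives two choices throughout: MCC and PR-AUC are preferred summary
statistics, and classification uses a per-protein top-N rule rather than a
global probability threshold.

## Ground-truth annotation

A residue of the query chain is labelled interfacial when at least one of
its heavy atoms lies within a cutoff (default 4.0 Å) of any heavy atom of
a partner chain in the complex structure. Design choices:

* **Distance criterion only.** Contact "legitimacy" classifications (in the
  sense of Sobolev et al.'s complementarity analysis) are not reimplemented;
  the distance term dominates in practice, and `annotate_interface` accepts
  a `contact_filter` hook for callers who want a stricter rule.
* **Heavy atoms only** — 4.0 Å is a heavy-atom convention and most
  deposited structures lack hydrogens. Hydrogens are dropped at parse time
  (restorable via `keep_hydrogens`).
* Residue identity is `(chain, author residue number, insertion code)`,
  taken verbatim from the coordinate file; no renumbering.
* Waters are always excluded; other HETATM records are excluded by default;
  alternate locations resolve to the highest-occupancy conformer.

## Surface-exposed residue count R

R feeds the dynamic cutoff. Per-residue solvent-accessible surface area is
computed by the rolling-probe (Shrake–Rupley) method (probe 1.4 Å, 500
sphere points, element-based van der Waals radii), summed per residue, and
divided by the residue type's theoretical maximum (Tien et al. 2013;
glycine's maximum serves as the fallback for non-standard residues) to a
relative accessibility clipped to [0, 1]. A residue is surface-exposed when
its relative accessibility is at least the threshold, default **5%**.
"Surface-exposed" has no universal definition and the upstream convention
is not recoverable, so the threshold is a configuration knob; likewise
whether R is computed on the bound or unbound form is the caller's choice
of input structure (the package imposes neither).

## Docking-based channel

The docking channel scores residue r as the average over P non-cognate
partners of the fraction of that partner's docked poses in which r is at
the 4.0 Å interface. Conventions:

* Partners are weighted equally regardless of pose counts (mean of
  per-partner fractions) — matching a per-partner reading of the
  fixed-pose-count protocol (canonically 2000 poses × 13 partners). A
  pooled-pose mode (`pooled=True`) is provided; the two coincide at equal
  pose counts. Per-partner accumulation uses exact rational arithmetic so
  scores are bit-identical under any partner or pose reordering.
* Pose input is either one PDB per pose (`poses/<partner>/pose_*.pdb`) or a
  compact table of per-pose interface residues — the computation defined
  here is the aggregation, not the docking, and tests use the compact form.

## Integration models

Four families, all emitting a consensus likelihood in [0, 1] and all
following the scikit-learn estimator protocol:

| family | fit | free hyperparameters (default) |
|---|---|---|
| linear | ordinary least squares, output clipped to [0, 1] | none |
| logistic | maximum likelihood (near-unpenalized L2, C = 10⁶) | none |
| random forest | bootstrap classification trees, mean leaf fraction | 100 trees, depth 10, ccp α = 0 |
| gradient boosting | histogram-binned stagewise trees | log-loss or squared error; rate 0.1; 100 iterations; depth 3/6 |

Numerical choices: the linear model falls back to a light ridge penalty
(α = 10⁻⁶) on rank-deficient designs and degrades to intercept-only (with a
warning) on single-class labels; the logistic fit detects
(quasi-)separation by a coefficient-magnitude check (|b| > 30) and refits
at C = 1, keeping coefficients finite while preserving the score ordering;
the logistic linear predictor is clipped at ±500 before exponentiation;
boosting with zero iterations returns the constant base rate.

Clipping linear predictions to [0, 1] is a deliberate reading of "a
continuous interfacial likelihood between 0 and 1": OLS itself does not
bound its output, and ranking (the only downstream consumer) is unaffected
except among saturated residues.

## Cross-validation

Hyperparameters are selected by grouped k-fold CV (default k = 5): folds
partition **proteins**, never residues, so residues of one protein never
straddle folds and no information leaks through shared proteins. Each grid
point is scored by the mean held-out per-protein F-score under the dynamic
cutoff; ties prefer the simpler model (fewer trees, then fewer iterations,
then smaller depth); the winner is refit on all training proteins. A
protein whose held-out fold contains no positive residues contributes F = 0
and is flagged rather than dropped, keeping the objective defined.

For the regressions — whose parameters OLS/MLE determine in closed form, so
a "grid" is empty — an alternative procedure
(`cv_candidate_regression`) is provided that selects among the five
fold-fitted coefficient vectors by held-out F-score and returns the winning
candidate without refitting. Both readings of "CV-optimized regression
parameters" are legitimate; the default pipeline uses the refit-based
`cross_validate` because it uses all training data, and the candidate
variant exists for strict procedural comparability.

## Dynamic cutoff and metrics

N = 6.1 · R^0.3, rounded half-up (the power law itself never lands on .5
for integer R, so the half-up choice is inert; floor/ceil modes exist as
configuration). N is floored at 1 and classification saturates at the
protein's residue count. Ties at rank N break by row order in the table,
making calls deterministic.

Precision, recall, F and MCC follow their standard confusion-matrix
definitions; any metric with a zero denominator is defined as 0 **and
flagged**, so per-protein averages stay well defined while degenerate
proteins remain identifiable. Per-protein metrics are averaged unweighted
across proteins (an "average F-score" convention); curves instead pool
residues across proteins by default (per-protein curve averaging on a
common grid is available but off by default — pooling is the common
convention for benchmark-wide curves). The ROC/PR sweep visits every
distinct score as a threshold, from high to low; AUC is the trapezoidal
integral of the stored points; the PR curve is anchored at
(recall 0, precision of its first point) with no further interpolation.
Pooled ROC-AUC is verified in the tests to equal the Mann–Whitney rank
statistic U/(n₊n₋) to 10⁻¹⁰.

KS machinery: the one-sample test compares against a normal reference —
with explicit mean/sd the classical p-value is exact; with estimated
parameters it is conservative, and a Lilliefors-corrected variant is
available behind a flag. The two-sample test uses the asymptotic
distribution. AUC differences between two scorers on the same residues are
tested by a paired bootstrap over proteins (resampling proteins with
replacement, p = two-sided fraction of sign reversals) — a pragmatic
alternative to chi-squared AUC-comparison software, not a reimplementation
of it, and distinct from DeLong-style variance estimators (out of scope).

## Synthetic benchmark

The generator emulates the statistical structure the integration layer
relies on, with defaults chosen once as the study conditions:

* protein lengths uniform on 50–450 residues (the regime where
  docking-based scoring stays reliable);
* per-protein interface fraction Beta-distributed with mean 0.12
  (concentration 25), matching the small interfacial minority of real
  benchmarks;
* three channels with label-conditional Beta scores — Beta(4, 2) on
  interfacial vs Beta(2, 4) on non-interfacial residues defines a
  "moderate" channel (single-channel ROC-AUC ≈ 0.8); Beta is the natural
  family for bounded likelihood scores;
* inter-channel coupling through a Gaussian-copula shared latent factor
  with correlation ρ (ρ = 0: orthogonal inputs, the ideal for consensus
  methods; ρ → 1: redundant inputs, where integration gains shrink — a
  property of the generator used in tests, not an empirical claim about any
  particular real predictor);
* channel failures: with probability `failure_prob`, a (protein, channel)
  pair's scores are replaced by a label-independent mixture draw, emulating
  e.g. a template-based method with no usable structural neighbours.
  Failures use a dedicated random substream, so the same seed with and
  without failures differs only in the failed cells — the paired design
  the robustness experiment needs;
* R is fixed at 70% of the length — synthetic proteins have no geometry,
  so a typical surface fraction is asserted rather than computed.

What the generator does **not** emulate: spatial clustering of interface
residues along the chain, score calibration artefacts of real predictors,
protein-level correlation between length and interface fraction, and any
structure–score coupling. Tests passing on this benchmark therefore
demonstrate the correctness and the statistical behaviour of the
integration machinery — not the accuracy of any real upstream predictor.

An auxiliary generator produces an XOR-style interaction dataset (label =
exactly one of two channels above 0.5, 5% label noise, third channel pure
noise) on which no linear/logistic combination can succeed but
depth-limited trees can — used to separate model families.

## Problem sizes

The default test suite and the acceptance script run at desk scale chosen
to make every statistical assertion stable: the benchmark uses 130
proteins (100 train / 30 test, ≈ 32k residues), recovery simulations use
2 × 10⁴ residues, oracle-equivalence checks sweep up to 10⁴ scores, and
multi-seed properties use 5–10 seeds. These sizes are the package's own
experimental design.

## Known limitations

* The interface annotation is purely distance-based; a residue touching a
  partner via a crystallographic artefact contact is still labelled 1.
* SASA normalisation uses theoretical maxima for the 20 standard residues;
  non-standard residues inherit the glycine maximum, which overestimates
  their relative exposure.
* The logistic separation handling (refit at C = 1) changes coefficient
  magnitudes, not orderings; calibrated probabilities under separation are
  not meaningful in any case.
* `mmCIF` input is not supported; PDB-format text only.
* The bootstrap AUC-difference test assumes proteins are exchangeable;
  with very few test proteins its p-values are coarse (resolution 2/reps).
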