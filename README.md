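# cytorisk

Multigene prognostic-index pipeline for hormone-receptor-negative (HRneg)
breast cancer, built around distant recurrence (DR) as the time-to-event
endpoint.

Most clinical outcome predictors are informative only for hormone
receptor-positive disease; for HRneg and triple-negative tumors, prognostic
signal comes instead from immune/cytokine-linked gene sets. `cytorisk`
implements, as a tested and reusable library, the full analysis path for
deriving and evaluating such signatures on multi-site qPCR (ΔΔCT) cohorts:

* **qPCR normalization** — the ΔΔCT method (reference genes NUP214/PPIG, a
  universal calibrator RNA, a 40-cycle amplification cap that turns failed
  amplifications into explicit missing values), per-site median-centering
  before pooling, and QC (per-gene missingness report, dendrogram-branch ×
  site Fisher exact source-bias check).
* **Signature scoring** — equal-weight, sign-adjusted-mean indices with
  built-in definitions:

  - IR-7 = [SPP1 − (C1QA + HLA-F + IGLC2 + LY9 + TNFRSF17 + XCL2)] / 7
  - Buck-4 = [RGS4 − CLIC5 + CXCL13 + RPS28//FLJ46061] / 4
  - ICS (Integrated Cytokine Score)
    = [−CLIC5 + CXCL13 + HLA-F + TNFRSF17 + XCL2] / 5

  A sample missing any constituent gene gets no score (with the reason
  recorded); scores are Z-transformed per cohort (mean 0, SD 1, n−1
  denominator).
* **Survival statistics** — Cox proportional hazards (lifelines, Efron
  ties) with likelihood-ratio tests and Harrell's C (pair counting with a
  Noether-type CI), Kaplan-Meier estimation, the two-group log-rank test,
  and three dichotomizers: median split, constrained optimal cut-point
  (minimum log-rank P subject to ≥ 20% of samples per group), and fixed
  externally supplied thresholds for cross-cohort / cross-platform
  transfer.
* **Gene prioritization** — the three-criterion filter (training
  multivariate trend P < 0.15; validation univariate-or-multivariate trend
  P < 0.15; significance P < 0.05 in any of those models) that condenses a
  candidate roster to a high-priority subset.
* **Stepwise optimization** — forward selection over the IR-7 ∪ Buck-4 gene
  pool: at each step every unused gene is trialed in the enlarged index and
  the Cox likelihood-ratio P is minimized; the selected signature is the
  path prefix with the global minimum.
* **Survival-tree risk modeling** — CART-style recursive partitioning with
  exponential-model (Poisson) deviance, a ≥ 20-case terminal-node floor,
  and complexity-parameter selection by 10-fold cross-validation, matching
  R `rpart`'s survival method (verified against it in the test suite).
* **Synthetic cohorts** — a latent-factor generator emulating a pooled
  139-sample, three-site FFPE cohort (sites of 58/36/45 samples, median
  follow-up 3.7/8.98/13.65 years, ≈ 29% node-positive, calibrated
  missingness), so the whole pipeline is testable without external data.

Everything is exposed both as sklearn-style estimators
(`SignatureScorer`, `ForwardSignatureSelector`, `SurvivalTreeModel`, …)
and as plain functions, plus a `cytorisk` command-line interface.

## Worked example

```python
import cytorisk as cr

cohort = cr.generate_cohort(cr.default_ffpe_config(seed=9))
ir7 = cr.score_signature(cr.IR7, cohort.expression)
fit = cr.cox_fit(ir7.z.rename("IR-7"), cohort.outcome)
print(f"IR-7: HR/SD = {fit.hazard_ratios.iloc[0]:.2f} "
      f"({fit.ci_lower.iloc[0]:.2f}-{fit.ci_upper.iloc[0]:.2f}), "
      f"C = {fit.concordance:.2f}, n = {fit.n} ({fit.n_events} events)")

path = cr.forward_select(None, cohort.expression, cohort.outcome)
print(f"optimized signature: {path.selected.genes} (LR P = {path.best_p:.2g})")
```

Output:

```
IR-7: HR/SD = 1.80 (1.30-2.49), C = 0.66, n = 115 (43 events)
optimized signature: ['TNFRSF17', 'SPP1', 'HLA-F', 'RPS28//FLJ46061', 'LY9'] (LR P = 4.4e-05)
```

The first line evaluates the IR-7 index as a continuous predictor of
distant recurrence on a 139-sample synthetic cohort: each one-standard-
deviation increase in the index carries a 1.80-fold hazard, with a
concordance of 0.66 between index ordering and observed recurrence
ordering (24 samples scored missing because an IR-7 gene failed to
amplify).  The second line runs the forward-stepwise search over the
11-gene IR-7 ∪ Buck-4 pool: on this draw it selects a five-gene index
anchored by two of the generator's strong-loading genes plus three weaker
ones — at 139 samples the exact membership of the selected set varies
draw to draw, which is precisely the instability the selection-bias note
in the methods document describes.

The same workflow runs end to end from the shell:

```bash
cytorisk run-all --simulate --seed 1 --out results/
cytorisk simulate --seed 1 --out sim/
cytorisk tree --expression sim/expression.tsv --clinical sim/clinical.tsv --out tree.json
```

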