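# irdm — immunity-adjusted risk of distant metastasis for breast cancer

`irdm` implements an immunity-aware extension of nearest-centroid breast
cancer subtyping for a targeted 72-gene expression panel.  It is aimed at
translational researchers who want to (a) call molecular subtypes from bulk
or single-cell expression of the panel, (b) compute proliferation and
immunity signature scores, and (c) combine both with subtype correlations
into a 0–100 risk-of-distant-metastasis score that stratifies
distant-metastasis-free survival (DMFS).

## The model

**Signature scores.** For a sample with log2, median-centered expression
x<sub>g</sub>, the *unscaled* proliferation (19 genes) and immunity
(17 genes) scores are signature means, mapped to 0–100 by fixed affine
transforms and clipped:

    proliferation score = clip(38 · (ū_prolif + 1.35), 0, 100)
    immunity score      = clip(30 · (ū_imm    + 1.40), 0, 100)

Samples are *proliferation-high* when the scaled score ≥ 50 and *istrong*
(immunity-strong) when the scaled immunity score ≥ 42.

**Subtyping.** Six centroids — Basal, HER2E, Immuno, LumA, LumB, Normal —
are per-subtype mean profiles over the 66 non-housekeeper panel genes.  A
sample is assigned the subtype with the highest Spearman rank correlation ρ
to its profile (equivalently the lowest 1 − ρ distance).  Call confidence is
1 − p, with p the two-sided t-approximation p-value of the winning
correlation; calls below 95% confidence are labelled **Mixed**.  The Immuno
group captures tumors whose expression is dominated by infiltrating
lymphocytes rather than any intrinsic-subtype program.

**Risk score.** The unscaled iRDM score is a linear combination of the five
subtype correlations (Normal carries no weight), the proliferation score and
the immunity score (both divided by 100), with published Cox coefficients.
ER-negative *and* proliferation-high patients use branch A, where immunity
is five times more protective (−0.40 vs −0.08); everyone else uses branch B:

    u_B = 0.40·Basal + 0.48·HER2E − 0.06·Immuno − 0.46·LumA + 0.19·LumB
          + 0.24·prolif01 − 0.08·imm01

The displayed score is `clip(90·u + 50, 0, 100)`, cut at 33 and 50 into
low / intermediate / high risk.

The package also ships the targeted RNA-seq preprocessing chain (QC gates at
10 000 reads and 30% missing genes, transcript-length + CPM normalization,
log2, KNN imputation, median-centering/standardization) and a synthetic
cohort generator whose immunity axis is independent of subtype and whose
survival times follow a proportional-hazards law in the iRDM score — so the
whole workflow is testable without any data download.

## Worked example

```python
import irdm
from irdm.synthetic_data import CohortSpec, generate_cohort
from irdm.evaluate import km_logrank

cohort = generate_cohort(CohortSpec(n_samples=300, beta=1.0,
                                    baseline_hazard=0.1, seed=7))
panel  = irdm.default_panel()
scores = irdm.score_samples(cohort.matrix, panel)
calls, freq = irdm.batch_subtype(cohort.matrix, cohort.model)
risk   = irdm.score_risk(scores, calls, cohort.clinical)

res = km_logrank(cohort.clinical, risk["risk_group"])
print(f"log-rank chi2 = {res.statistic:.2f} (df {res.df}), p = {res.p_value:.3g}")
```

prints `log-rank chi2 = 10.36 (df 2), p = 0.00562`: the three risk groups
(149 low / 80 med / 71 high of 300 samples) separate survival, as expected
for a cohort generated with a positive hazard slope.  The first risk rows
look like

```
          branch  unscaled_irdm  irdm_score risk_group
S0000          B         -0.142      37.222        med
S0001          A         -0.028      47.458        med
S0002          B          0.654     100.000       high
```

S0002 is proliferation-high with a strong Basal correlation under branch B,
so its raw score 90·0.654 + 50 ≈ 108.9 clips to 100 — high risk.  The
subtype frequency table for the same cohort calls all six subtypes
(55 Basal, 41 HER2E, 53 Immuno, 57 LumA, 52 LumB, 42 Normal, 0 Mixed).

The same workflow is scriptable from the shell:

```bash
irdm simulate --out-dir sim --n 300 --seed 7
irdm score   --matrix sim/matrix.tsv --out scores.csv
irdm subtype --matrix sim/matrix.tsv --model sim/centroids.tsv --out calls.csv
irdm risk    --scores scores.csv --calls calls.csv --clinical sim/clinical.csv --out risk.csv
irdm evaluate --risk risk.csv --clinical sim/clinical.csv --out report/
```

## Notes

- The 17 immunity and 19 proliferation gene lists are the published
  signatures.  The basal/ER/HER2/invasion/housekeeper categories ship as
  documented placeholders from the PAM50 literature and should be replaced
  with your assay's actual lists via a JSON/YAML panel file (`irdm panel
  validate my_panel.json`).
- See `docs/methods.md` for the full model description, the synthetic
  generator's assumptions, and known limitations (including the statistical
  identifiability limits of refitting the small risk coefficients).
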