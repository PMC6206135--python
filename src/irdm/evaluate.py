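"""Results-layer analyses: survival stratification, TIL concordance,
single-cell heterogeneity.

Kaplan-Meier curves and the k-group log-rank test quantify how well subtype
or risk-group calls separate distant-metastasis-free survival; follow-up is
truncated at 10 years by default.  TIL concordance checks the pathology-
level validation of the immunity score (Pearson correlation of immunity
score with the pathologist's tumor-infiltrating-lymphocyte percentage, plus
a TIL-high/low x istrong/iweak cross-tabulation).  The heterogeneity summary
tabulates per-cell subtype calls within each tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panels_io import ExpressionMatrix
from .subtyping import MIXED, SUBTYPES, CentroidModel, batch_subtype

__all__ = [
    "StratificationResult",
    "km_logrank",
    "til_concordance",
    "heterogeneity_summary",
]


@dataclass
class StratificationResult:
    """KM curves per group plus the k-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # label -> (time, survival, at_risk)
    n_per_group: dict[str, int]
    statistic: float
    p_value: float
    df: int
    logrank_defined: bool = True


def _truncate(time: pd.Series, event: pd.Series, horizon: float):
    over = time > horizon
    return time.clip(upper=horizon), event.where(~over, 0).astype(int)


def km_logrank(
    clinical: pd.DataFrame,
    groups: pd.Series,
    horizon_years: float = 10.0,
) -> StratificationResult:
    """Kaplan-Meier curves and log-rank test across sample groups.

    ``groups`` maps sample id to a group label; samples missing from either
    input are dropped.  Needs at least two non-empty groups.  With zero
    events the KM curves are still returned but the log-rank statistic is
    flagged undefined.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = pd.Series(groups)
    common = clinical.index.intersection(groups.index)
    groups = groups.loc[common]
    time, event = _truncate(
        clinical.loc[common, "time_years"].astype(float),
        clinical.loc[common, "event"].astype(int),
        horizon_years,
    )
    labels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(labels) < 2:
        raise ValueError(f"need at least 2 non-empty groups, got {labels}")

    curves = {}
    n_per = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
        n_per[lab] = int(mask.sum())

    if event.sum() == 0:
        return StratificationResult(
            curves, n_per, float("nan"), float("nan"), len(labels) - 1, False
        )
    res = multivariate_logrank_test(time, groups, event)
    return StratificationResult(
        curves,
        n_per,
        float(res.test_statistic),
        float(res.p_value),
        len(labels) - 1,
        True,
    )


def til_concordance(
    clinical: pd.DataFrame,
    scores: pd.DataFrame,
    til_cutoff_pct: float = 50.0,
) -> dict:
    """Concordance of the immunity score with pathologist-assessed TIL %.

    Returns Pearson r with a 95% CI and p-value, n, and a cross-tabulation of
    TIL-high (til_pct > cutoff) vs istrong/iweak.  Requires >= 3 samples with
    both TIL and an immunity score.
    """
    common = clinical.index.intersection(scores.index)
    til = clinical.loc[common, "til_pct"].astype(float)
    imm = scores.loc[common, "imm_score"].astype(float)
    ok = til.notna() & imm.notna()
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 samples with TIL and immunity score, got {int(ok.sum())}")
    til, imm = til[ok], imm[ok]
    res = stats.pearsonr(til, imm)
    try:
        ci = res.confidence_interval(0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)
    except ValueError:  # degenerate (e.g. perfectly correlated) input
        ci_low = ci_high = float(res.statistic)
    til_group = np.where(til > til_cutoff_pct, "til_high", "til_low")
    imm_group = scores.loc[til.index, "imm_group"]
    crosstab = pd.crosstab(pd.Series(til_group, index=til.index), imm_group)
    return {
        "pearson_r": float(res.statistic),
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p_value": float(res.pvalue),
        "n": int(ok.sum()),
        "crosstab": crosstab,
    }


def heterogeneity_summary(
    cell_matrix: ExpressionMatrix,
    tumor_of: pd.Series,
    model: CentroidModel,
    min_coverage: float = 0.7,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-tumor subtype composition from per-cell centroid calls.

    Returns a DataFrame indexed by tumor with one count column per category
    (six subtypes + Mixed), ``n_cells``, and ``multi_subtype`` — True when at
    least two distinct non-Mixed subtypes co-occur in the tumor.
    """
    tumor_of = pd.Series(tumor_of)
    common = [c for c in cell_matrix.sample_ids if c in tumor_of.index]
    if not common:
        raise ValueError("no overlap between cell matrix and tumor assignment")
    sizes = tumor_of.loc[common].value_counts()
    if (sizes >= min_cells).sum() < 1:
        raise ValueError(f"need at least one tumor with >= {min_cells} cells")
    calls, _ = batch_subtype(cell_matrix, model, min_coverage=min_coverage)
    labels = calls.loc[common, "label"]
    cats = list(SUBTYPES) + [MIXED]
    rows = []
    for tumor, cells in tumor_of.loc[common].groupby(tumor_of.loc[common]).groups.items():
        sub = labels.loc[list(cells)]
        counts = sub.value_counts().reindex(cats, fill_value=0)
        non_mixed = [c for c in SUBTYPES if counts[c] > 0]
        rows.append(
            {
                "tumor_id": tumor,
                **{c: int(counts[c]) for c in cats},
                "n_cells": int(len(sub)),
                "multi_subtype": len(non_mixed) >= 2,
            }
        )
    return pd.DataFrame(rows).set_index("tumor_id")
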