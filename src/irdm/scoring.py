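"""Proliferation and immunity signature scores.

Each score is the arithmetic mean of a gene signature's log2 expression
values in a sample ("unscaled" score), mapped onto a 0-100 scale by a fixed
published affine transform and clipped to that range:

    proliferation score = clip(38 * (u + 1.35), 0, 100)
    immunity score      = clip(30 * (u + 1.40), 0, 100)

Samples are called proliferation-high when the scaled score is >= 50 and
immunity-strong ("istrong") when the scaled immunity score is >= 42; the
istrong boundary is treated inclusively, mirroring the explicit "larger or
equal" convention of the proliferation rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panels_io import ExpressionMatrix, GenePanel

__all__ = [
    "PROLIF_SLOPE",
    "PROLIF_OFFSET",
    "IMM_SLOPE",
    "IMM_OFFSET",
    "PROLIF_CUTOFF",
    "IMM_CUTOFF",
    "SampleScores",
    "unscaled_signature_score",
    "signature_scores",
    "scale_proliferation",
    "scale_immunity",
    "classify_groups",
    "score_samples",
]

PROLIF_SLOPE = 38.0
PROLIF_OFFSET = 1.35
IMM_SLOPE = 30.0
IMM_OFFSET = 1.40
#: Scaled-score cutoffs for group calls.
PROLIF_CUTOFF = 50.0
IMM_CUTOFF = 42.0


@dataclass
class SampleScores:
    """Signature scores and group calls for one sample."""

    unscaled_proliferation: float
    proliferation_score: float
    unscaled_immunity: float
    immunity_score: float
    proliferation_group: str = "unknown"
    immunity_group: str = "unknown"
    n_proliferation_genes: int = 0
    n_immunity_genes: int = 0


def signature_scores(
    m: ExpressionMatrix,
    genes: Sequence[str],
    min_fraction: float = 0.7,
) -> pd.DataFrame:
    """Per-sample mean expression of a gene signature.

    A sample's score is the mean over the signature genes that are present in
    the matrix and non-missing for that sample.  Samples covering less than
    ``min_fraction`` of the signature get a missing (NaN) score; the coverage
    fraction is always reported.

    Returns a DataFrame indexed by sample with columns ``score``, ``n_genes``
    and ``coverage``.
    """
    wanted = [g for g in genes if g in m.values.index]
    sub = m.values.loc[wanted] if wanted else m.values.iloc[:0]
    n_obs = sub.notna().sum(axis=0)
    score = sub.mean(axis=0, skipna=True)
    coverage = n_obs / len(genes) if len(genes) else n_obs * 0.0
    score = score.where(coverage >= min_fraction)
    return pd.DataFrame(
        {"score": score, "n_genes": n_obs.astype(int), "coverage": coverage}
    )


def unscaled_signature_score(
    m: ExpressionMatrix,
    genes: Sequence[str],
    sample: str,
    min_fraction: float = 0.7,
) -> float:
    """Unscaled signature score (mean expression) for a single sample.

    Returns NaN when signature coverage falls below ``min_fraction``.
    """
    return float(signature_scores(m, genes, min_fraction).loc[sample, "score"])


def _scale(u, slope: float, offset: float):
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise ValueError("unscaled score must be finite")
    out = np.clip(slope * (arr + offset), 0.0, 100.0)
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


def scale_proliferation(u):
    """Map an unscaled proliferation score onto [0, 100]: clip(38*(u+1.35))."""
    return _scale(u, PROLIF_SLOPE, PROLIF_OFFSET)


def scale_immunity(u):
    """Map an unscaled immunity score onto [0, 100]: clip(30*(u+1.4))."""
    return _scale(u, IMM_SLOPE, IMM_OFFSET)


def classify_groups(s: SampleScores) -> SampleScores:
    """Set proliferation-high/low and istrong/iweak calls on a score record.

    A missing scaled score yields group ``"unknown"``.
    """
    if np.isnan(s.proliferation_score):
        s.proliferation_group = "unknown"
    else:
        s.proliferation_group = "high" if s.proliferation_score >= PROLIF_CUTOFF else "low"
    if np.isnan(s.immunity_score):
        s.immunity_group = "unknown"
    else:
        s.immunity_group = "istrong" if s.immunity_score >= IMM_CUTOFF else "iweak"
    return s


def score_samples(
    m: ExpressionMatrix,
    panel: GenePanel,
    min_fraction: float = 0.7,
) -> pd.DataFrame:
    """Proliferation and immunity scores with group calls for every sample.

    Returns a DataFrame indexed by sample id with columns prolif_unscaled,
    prolif_score, prolif_group, imm_unscaled, imm_score, imm_group,
    n_prolif_genes, n_imm_genes.
    """
    if m.state == "raw_counts":
        raise ValueError("scores require log-scale expression, not raw counts")
    prolif = signature_scores(m, panel["proliferation"], min_fraction)
    imm = signature_scores(m, panel["immunity"], min_fraction)
    prolif_score = scale_proliferation(prolif["score"].to_numpy())
    imm_score = scale_immunity(imm["score"].to_numpy())
    out = pd.DataFrame(
        {
            "prolif_unscaled": prolif["score"],
            "prolif_score": prolif_score,
            "prolif_group": "unknown",
            "imm_unscaled": imm["score"],
            "imm_score": imm_score,
            "imm_group": "unknown",
            "n_prolif_genes": prolif["n_genes"],
            "n_imm_genes": imm["n_genes"],
        },
        index=m.values.columns,
    )
    ok = ~np.isnan(out["prolif_score"])
    out.loc[ok, "prolif_group"] = np.where(
        out.loc[ok, "prolif_score"] >= PROLIF_CUTOFF, "high", "low"
    )
    ok = ~np.isnan(out["imm_score"])
    out.loc[ok, "imm_group"] = np.where(
        out.loc[ok, "imm_score"] >= IMM_CUTOFF, "istrong", "iweak"
    )
    out.index.name = "sample_id"
    return out
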