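"""The iRDM (immunity-adjusted risk of distant metastasis) score.

The unscaled iRDM score is a linear combination of five subtype centroid
correlations (Basal, HER2E, Immuno, LumA, LumB — the Normal correlation
carries no coefficient), the proliferation score and the immunity score,
with published Cox-model coefficients.  Two coefficient sets exist:

  branch A — ER-negative AND proliferation-high patients, where immunity
             carries a five-fold larger protective weight (-0.40 vs -0.08);
  branch B — everyone else.

Because the published equations mix correlation-scale terms with 0-100
scores, this package divides both scaled scores by 100 (range [0, 1], same
magnitude as correlations) before applying the coefficients; this is the
package's documented interpretation and is configurable.  The unscaled score
is mapped to 0-100 via clip(90*u + 50) and cut at 33 and 50 into low /
intermediate / high risk groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panels_io import ExpressionMatrix, GenePanel
from .scoring import score_samples
from .subtyping import SUBTYPES, CentroidModel, SubtypeCall, batch_subtype

__all__ = [
    "RiskCoefficients",
    "RiskResult",
    "RefitResult",
    "select_branch",
    "unscaled_irdm",
    "scale_and_group",
    "compute_risk",
    "score_risk",
    "refit_coefficients",
    "infer_er_status",
]

#: Covariate order used by both equations and by refitting.
COVARIATES = ("basal", "her2e", "immuno", "luma", "lumb", "proliferation", "immunity")

_CORR_FOR = {"basal": "Basal", "her2e": "HER2E", "immuno": "Immuno",
             "luma": "LumA", "lumb": "LumB"}


@dataclass
class RiskCoefficients:
    """Published linear coefficients and scaling constants of the iRDM score."""

    branch_a: dict[str, float] = field(
        default_factory=lambda: {
            "basal": -0.02,
            "her2e": 0.16,
            "immuno": -0.34,
            "luma": 0.07,
            "lumb": 0.08,
            "proliferation": 0.09,
            "immunity": -0.40,
        }
    )
    branch_b: dict[str, float] = field(
        default_factory=lambda: {
            "basal": 0.40,
            "her2e": 0.48,
            "immuno": -0.06,
            "luma": -0.46,
            "lumb": 0.19,
            "proliferation": 0.24,
            "immunity": -0.08,
        }
    )
    scale_multiplier: float = 90.0
    scale_offset: float = 50.0
    cutoff_low_med: float = 33.0
    cutoff_med_high: float = 50.0
    #: Divisor applied to the 0-100 scores before the linear combination.
    score_divisor: float = 100.0

    def branch(self, which: str) -> dict[str, float]:
        if which == "A":
            return self.branch_a
        if which == "B":
            return self.branch_b
        raise ValueError(f"unknown branch {which!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskCoefficients":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RiskResult:
    """iRDM score for one sample."""

    branch: str
    unscaled_irdm: float
    irdm_score: float
    risk_group: str


def select_branch(er_status: str, proliferation_group: str) -> str:
    """Branch A for ER-negative, proliferation-high samples; B otherwise.

    Unknown ER status falls through to branch B (callers flag this).
    """
    if proliferation_group not in ("high", "low"):
        raise ValueError(f"proliferation group must be known, got {proliferation_group!r}")
    if er_status == "negative" and proliferation_group == "high":
        return "A"
    return "B"


def unscaled_irdm(
    call: SubtypeCall | Mapping[str, float],
    prolif01: float,
    imm01: float,
    branch: str,
    coef: RiskCoefficients | None = None,
) -> float:
    """Linear iRDM combination of subtype correlations and [0, 1] scores.

    ``prolif01`` and ``imm01`` are the scaled 0-100 scores divided by 100.
    The Normal correlation is not used.
    """
    coef = coef or RiskCoefficients()
    corr = call.correlations if isinstance(call, SubtypeCall) else call
    b = coef.branch(branch)
    total = 0.0
    for cov, sub in _CORR_FOR.items():
        if sub not in corr or corr[sub] is None or np.isnan(corr[sub]):
            raise ValueError(f"missing correlation for subtype {sub}")
        total += b[cov] * corr[sub]
    total += b["proliferation"] * prolif01 + b["immunity"] * imm01
    return total


def scale_and_group(u: float, coef: RiskCoefficients | None = None) -> tuple[float, str]:
    """Scale an unscaled iRDM score to 0-100 and assign the risk group.

    score = clip(90*u + 50, 0, 100); low < 33 <= med < 50 <= high.
    """
    coef = coef or RiskCoefficients()
    if not np.isfinite(u):
        raise ValueError("unscaled iRDM score must be finite")
    score = float(np.clip(coef.scale_multiplier * u + coef.scale_offset, 0.0, 100.0))
    if score < coef.cutoff_low_med:
        group = "low"
    elif score < coef.cutoff_med_high:
        group = "med"
    else:
        group = "high"
    return score, group


def compute_risk(
    call: SubtypeCall | Mapping[str, float],
    prolif_score: float,
    imm_score: float,
    er_status: str,
    proliferation_group: str,
    coef: RiskCoefficients | None = None,
) -> RiskResult:
    """Full single-sample iRDM: branch selection, equation, scaling, group."""
    coef = coef or RiskCoefficients()
    branch = select_branch(er_status, proliferation_group)
    u = unscaled_irdm(
        call,
        prolif_score / coef.score_divisor,
        imm_score / coef.score_divisor,
        branch,
        coef,
    )
    score, group = scale_and_group(u, coef)
    return RiskResult(branch, u, score, group)


def score_risk(
    scores: pd.DataFrame,
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    coef: RiskCoefficients | None = None,
) -> pd.DataFrame:
    """Batch iRDM over a cohort.

    ``scores`` comes from :func:`irdm.scoring.score_samples`, ``calls`` from
    :func:`irdm.subtyping.batch_subtype`, ``clinical`` provides er_status.
    Returns a DataFrame indexed by sample with columns branch, unscaled_irdm,
    irdm_score, risk_group and er_flagged (True when ER was unknown and the
    sample defaulted to branch B).
    """
    coef = coef or RiskCoefficients()
    samples = scores.index.intersection(calls.index).intersection(clinical.index)
    rows = []
    for s in samples:
        er = clinical.loc[s, "er_status"]
        pg = scores.loc[s, "prolif_group"]
        corr = {sub: calls.loc[s, f"corr_{sub}"] for sub in SUBTYPES}
        res = compute_risk(
            corr,
            scores.loc[s, "prolif_score"],
            scores.loc[s, "imm_score"],
            er,
            pg,
            coef,
        )
        rows.append(
            {
                "sample_id": s,
                "branch": res.branch,
                "unscaled_irdm": res.unscaled_irdm,
                "irdm_score": res.irdm_score,
                "risk_group": res.risk_group,
                "er_flagged": er == "unknown",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def infer_er_status(
    m: ExpressionMatrix, panel: GenePanel, random_state: int = 0
) -> pd.Series:
    """Fallback ER caller from the ER-category gene score.

    Fits a two-component 1-D Gaussian mixture to the per-sample mean of the
    ER-category genes and labels samples by the higher-mean component.
    Returns a Series of 'positive'/'negative'; callers should flag these as
    inferred, clinical ER status being the primary source.
    """
    from sklearn.mixture import GaussianMixture

    from .scoring import signature_scores

    er = signature_scores(m, panel["er"], min_fraction=0.5)["score"]
    x = er.dropna().to_numpy().reshape(-1, 1)
    if len(x) < 4:
        raise ValueError("too few samples with ER-gene coverage to infer status")
    gm = GaussianMixture(n_components=2, random_state=random_state).fit(x)
    pos_comp = int(np.argmax(gm.means_.ravel()))
    labels = gm.predict(er.dropna().to_numpy().reshape(-1, 1))
    out = pd.Series("unknown", index=er.index, dtype=object)
    out.loc[er.dropna().index] = np.where(labels == pos_comp, "positive", "negative")
    return out


@dataclass
class RefitResult:
    """Cox refit of the iRDM coefficients, per branch."""

    coefficients: RiskCoefficients
    se_a: dict[str, float]
    se_b: dict[str, float]
    n_a: int
    n_b: int
    events_a: int
    events_b: int


def refit_coefficients(
    m: ExpressionMatrix,
    clinical: pd.DataFrame,
    model: CentroidModel,
    panel: GenePanel,
    corr_cutoff: float = 0.7,
    horizon_years: float = 10.0,
    min_events: int = 10,
    coef: RiskCoefficients | None = None,
) -> RefitResult:
    """Refit the iRDM linear coefficients on a training cohort.

    Training samples are those whose winning-centroid Spearman correlation is
    at least ``corr_cutoff`` (high-confidence core of each subtype).
    Follow-up is truncated at ``horizon_years``.  A Cox proportional-hazards
    model of time-to-event on the five subtype correlations plus the two
    [0, 1] scores is fitted separately for branch A and branch B strata.
    """
    from lifelines import CoxPHFitter

    coef = coef or RiskCoefficients()
    scores = score_samples(m, panel)
    sub_model = model
    calls, _ = batch_subtype(m, sub_model)
    samples = scores.index.intersection(calls.index).intersection(clinical.index)
    if len(samples) == 0:
        raise ValueError("no overlapping samples between matrix and clinical table")

    corr_cols = {f"corr_{s}" for s in SUBTYPES}
    win = calls.loc[samples, [f"corr_{s}" for s in SUBTYPES]].max(axis=1)
    keep = samples[win.loc[samples] >= corr_cutoff]
    if len(keep) == 0:
        raise ValueError(
            f"no samples with winning-centroid correlation >= {corr_cutoff}"
        )

    time = clinical.loc[keep, "time_years"].astype(float)
    event = clinical.loc[keep, "event"].astype(int)
    over = time > horizon_years
    time = time.clip(upper=horizon_years)
    event = event.where(~over, 0)

    df = pd.DataFrame(
        {
            "basal": calls.loc[keep, "corr_Basal"],
            "her2e": calls.loc[keep, "corr_HER2E"],
            "immuno": calls.loc[keep, "corr_Immuno"],
            "luma": calls.loc[keep, "corr_LumA"],
            "lumb": calls.loc[keep, "corr_LumB"],
            "proliferation": scores.loc[keep, "prolif_score"] / coef.score_divisor,
            "immunity": scores.loc[keep, "imm_score"] / coef.score_divisor,
            "time": time,
            "event": event,
        }
    )
    branch = pd.Series(
        [
            select_branch(clinical.loc[s, "er_status"], scores.loc[s, "prolif_group"])
            for s in keep
        ],
        index=keep,
    )

    fitted = {}
    ses = {}
    info = {}
    for br in ("A", "B"):
        sub = df.loc[branch == br]
        n_events = int(sub["event"].sum())
        if n_events < min_events:
            raise ValueError(
                f"branch {br} has {n_events} events in the training subset; "
                f"need >= {min_events}"
            )
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(sub, duration_col="time", event_col="event")
        fitted[br] = {c: float(cph.params_[c]) for c in COVARIATES}
        ses[br] = {c: float(cph.standard_errors_[c]) for c in COVARIATES}
        info[br] = (len(sub), n_events)

    new = RiskCoefficients(
        branch_a=fitted["A"],
        branch_b=fitted["B"],
        scale_multiplier=coef.scale_multiplier,
        scale_offset=coef.scale_offset,
        cutoff_low_med=coef.cutoff_low_med,
        cutoff_med_high=coef.cutoff_med_high,
        score_divisor=coef.score_divisor,
    )
    return RefitResult(
        new, ses["A"], ses["B"], info["A"][0], info["B"][0], info["A"][1], info["B"][1]
    )
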