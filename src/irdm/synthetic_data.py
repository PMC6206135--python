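"""Synthetic cohorts with the statistical structure the iRDM analysis assumes.

The generator emulates what the real training cohorts look like after
processing — log2, gene-median-centered expression over the 72-gene panel —
with the structural features the method relies on built in explicitly:

* six subtype centroids with block-structured marker expression (basal, ER,
  HER2 and proliferation categories carry the subtype identity);
* an immunity axis that is *independent of subtype*: every sample receives a
  random immunity-gene displacement, and the five non-Immuno centroids share
  identical immunity-gene means, so high immune infiltration occurs within
  every subtype;
* proportional-hazards survival: each sample's event time is exponential
  with log-hazard ``beta * (unscaled iRDM score)``, with independent
  exponential censoring, so the Cox refit is a well-specified model;
* a targeted RNA-seq layer (multinomial read counts with transcript-length
  bias, optional dropout and under-sequenced samples) to exercise the
  preprocessing chain;
* per-tumor single-cell mixtures (several carcinoma subtypes plus infiltrating
  immune cells, heavy dropout) to exercise heterogeneity analysis.

Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panels_io import ExpressionMatrix, GenePanel, default_panel
from .risk import RiskCoefficients, select_branch, unscaled_irdm
from .scoring import score_samples
from .subtyping import SUBTYPES, CentroidModel, batch_subtype

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "make_centroids",
    "generate_cohort",
    "generate_counts",
    "generate_single_cells",
    "ER_POSITIVE_PROB",
]

#: P(ER positive | subtype). Documented config defaults, not literature claims.
ER_POSITIVE_PROB = {
    "Basal": 0.05,
    "HER2E": 0.50,
    "Immuno": 0.40,
    "LumA": 0.95,
    "LumB": 0.90,
    "Normal": 0.70,
}

# Block means (log2 units, centered scale) of each marker category per
# subtype.  These encode textbook marker biology: basal keratins high only in
# Basal, ER-axis genes high in luminal tumors, HER2-amplicon genes high in
# HER2E, immunity genes elevated only in the Immuno group.
_BLOCK_MEANS = {
    "basal": {"Basal": 1.5, "HER2E": -0.3, "Immuno": -0.3, "LumA": -0.5,
              "LumB": -0.5, "Normal": 0.2},
    "er": {"Basal": -1.0, "HER2E": -0.5, "Immuno": -0.3, "LumA": 1.2,
           "LumB": 0.8, "Normal": 0.0},
    "her2": {"Basal": -0.3, "HER2E": 1.8, "Immuno": -0.2, "LumA": -0.2,
             "LumB": 0.3, "Normal": -0.2},
    "invasion": {"Basal": 0.5, "HER2E": 0.5, "Immuno": 0.0, "LumA": -0.3,
                 "LumB": 0.2, "Normal": -0.2},
    "immunity": {"Basal": 0.0, "HER2E": 0.0, "Immuno": 1.5, "LumA": 0.0,
                 "LumB": 0.0, "Normal": 0.0},
}
_IMMUNO_IMMUNITY_MEAN = 1.5


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``proliferation_by_subtype`` gives the mean *unscaled* proliferation
    score (mean log2 proliferation-gene expression) per subtype; the defaults
    put Basal/HER2E/LumB above the proliferation-high boundary (u ~ -0.03 on
    the 0-100 scale's cutoff of 50) and LumA/Normal below it.
    """

    n_samples: int = 600
    subtype_proportions: tuple = (1 / 6,) * 6  # ordered like SUBTYPES
    noise_sd: float = 0.3  # per-gene Gaussian noise, log2 units
    immunity_shift_sd: float = 0.5  # per-sample immunity-axis displacement
    proliferation_by_subtype: dict = field(
        default_factory=lambda: {
            "Basal": 0.8, "HER2E": 0.5, "Immuno": 0.0,
            "LumA": -0.6, "LumB": 0.6, "Normal": -0.8,
        }
    )
    baseline_hazard: float = 0.05  # events per year at iRDM u = 0
    censoring_rate: float = 0.05  # independent exponential censoring, per year
    beta: float = 1.0  # log-hazard slope on the unscaled iRDM score
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != 6 or (props < 0).any():
            raise ValueError("subtype_proportions must be 6 nonnegative values")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("subtype_proportions must sum to 1")
        for name in ("noise_sd", "immunity_shift_sd", "baseline_hazard", "censoring_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticCohort:
    """Expression matrix + clinical table + ground truth from one draw."""

    matrix: ExpressionMatrix
    clinical: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec
    model: CentroidModel


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def make_centroids(spec: CohortSpec, panel: GenePanel | None = None) -> CentroidModel:
    """Deterministic six-centroid model over the subtyping genes.

    Marker blocks get subtype-specific means plus per-gene jitter.  The
    immunity-gene jitter is shared across all six subtypes, so the five
    non-Immuno centroids have *identical* immunity profiles and the Immuno
    centroid sits a constant step above them; the proliferation block's
    jitter is likewise shared so each centroid's mean proliferation equals
    the spec value exactly (up to a common offset).
    """
    panel = panel or default_panel()
    rng = _rng(spec.seed, 0)
    rows: dict[str, np.ndarray] = {}
    values = pd.DataFrame(
        0.0, index=panel.subtyping_genes, columns=list(SUBTYPES), dtype=float
    )
    for cat in panel.categories:
        if cat == "housekeeper":
            continue
        genes = panel[cat]
        if cat in ("immunity", "proliferation"):
            jitter = rng.normal(0.0, 0.25, size=len(genes))
            for sub in SUBTYPES:
                if cat == "immunity":
                    base = _BLOCK_MEANS["immunity"][sub]
                else:
                    base = spec.proliferation_by_subtype[sub]
                values.loc[genes, sub] = base + jitter
        else:
            for sub in SUBTYPES:
                base = _BLOCK_MEANS[cat][sub]
                values.loc[genes, sub] = base + rng.normal(0.0, 0.25, size=len(genes))
    return CentroidModel(values, meta={"synthetic": True, "seed": spec.seed})


def generate_cohort(
    spec: CohortSpec,
    model: CentroidModel | None = None,
    panel: GenePanel | None = None,
    coef: RiskCoefficients | None = None,
) -> SyntheticCohort:
    """Draw a cohort of expression profiles with clinical follow-up.

    Each sample is its subtype centroid plus independent Gaussian noise plus
    a sample-specific displacement of the immunity genes only; housekeeper
    genes are flat.  Gene rows are median-centered across the cohort (the
    state real processed datasets arrive in).  The "true" unscaled iRDM score
    is computed from the sample's own measured profile with the published
    coefficients, and survival follows an exponential proportional-hazards
    law with log-hazard ``beta * u``.
    """
    panel = panel or default_panel()
    model = model if model is not None else make_centroids(spec, panel)
    coef = coef or RiskCoefficients()
    rng = _rng(spec.seed, 1)
    n = spec.n_samples
    labels = rng.choice(
        len(SUBTYPES), size=n, p=np.asarray(spec.subtype_proportions, dtype=float)
    )
    subtype = np.array(SUBTYPES)[labels]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    genes = panel.all_genes
    hk = panel["housekeeper"]
    imm_genes = panel["immunity"]
    centroids = model.centroids.reindex(panel.subtyping_genes)
    vals = pd.DataFrame(0.0, index=genes, columns=sample_ids, dtype=float)
    vals.loc[panel.subtyping_genes] = centroids.to_numpy()[:, labels]
    vals.loc[hk] = np.tile(
        rng.normal(0.0, 0.1, size=(len(hk), 1)), (1, n)
    )
    vals += rng.normal(0.0, spec.noise_sd, size=vals.shape)
    delta = rng.normal(0.0, spec.immunity_shift_sd, size=n)
    vals.loc[imm_genes] += delta[np.newaxis, :]
    vals = vals.sub(vals.median(axis=1), axis=0)  # gene-median centering
    matrix = ExpressionMatrix(vals, state="centered_standardized")

    er = np.where(
        rng.uniform(size=n) < np.array([ER_POSITIVE_PROB[s] for s in subtype]),
        "positive",
        "negative",
    )

    scores = score_samples(matrix, panel)
    calls, _ = batch_subtype(matrix, model)
    u = np.empty(n)
    branch = np.empty(n, dtype=object)
    for j, s in enumerate(sample_ids):
        br = select_branch(er[j], scores.loc[s, "prolif_group"])
        corr = {sub: calls.loc[s, f"corr_{sub}"] for sub in SUBTYPES}
        u[j] = unscaled_irdm(
            corr,
            scores.loc[s, "prolif_score"] / coef.score_divisor,
            scores.loc[s, "imm_score"] / coef.score_divisor,
            br,
            coef,
        )
        branch[j] = br

    hazard = spec.baseline_hazard * np.exp(spec.beta * u)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # Pathologist TIL tracks the total immune infiltrate: the subtype-free
    # displacement plus the Immuno group's elevated baseline.
    imm_signal = delta + np.where(subtype == "Immuno", _IMMUNO_IMMUNITY_MEAN, 0.0)
    til = np.clip(30.0 + 40.0 * imm_signal + rng.normal(0.0, 10.0, size=n), 0.0, 100.0)

    clinical = pd.DataFrame(
        {
            "er_status": er,
            "time_years": time,
            "event": event,
            "til_pct": til,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "subtype": subtype,
            "branch": branch,
            "true_unscaled_irdm": u,
            "immunity_shift": delta,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(matrix, clinical, truth, spec, model)


def generate_counts(
    cohort: SyntheticCohort,
    depth: int = 1_000_000,
    dropout: float = 0.0,
    low_read_samples: Sequence[str] = (),
    low_depth: int = 5_000,
) -> "CountsTable":
    """Targeted RNA-seq read counts consistent with the cohort's expression.

    Per sample, reads are multinomial with probabilities proportional to
    ``2**expression * transcript_length``, so length- and library-
    normalization recovers the expression ranks.  ``dropout`` zeroes random
    entries (creating "missing" genes); samples listed in
    ``low_read_samples`` are sequenced at ``low_depth`` reads so they fall
    under the 10000-read QC bar.
    """
    from .preprocess import CountsTable

    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(cohort.spec.seed, 2)
    vals = cohort.matrix.values
    lengths = pd.Series(
        rng.uniform(500.0, 3000.0, size=vals.shape[0]), index=vals.index
    )
    counts = {}
    totals = {}
    low = set(low_read_samples)
    for s in vals.columns:
        d = low_depth if s in low else depth
        w = np.power(2.0, vals[s].to_numpy()) * lengths.to_numpy()
        p = w / w.sum()
        c = rng.multinomial(d, p)
        if dropout > 0:
            c = np.where(rng.uniform(size=c.size) < dropout, 0, c)
        counts[s] = c
        totals[s] = d
    table = pd.DataFrame(counts, index=vals.index)
    return CountsTable(table, lengths, pd.Series(totals))


def generate_single_cells(
    n_tumors: int,
    cells_per_tumor: tuple[int, int] = (12, 78),
    spec: CohortSpec | None = None,
    panel: GenePanel | None = None,
    model: CentroidModel | None = None,
    dropout: float = 0.5,
    immune_fraction: float = 0.3,
    noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Per-tumor single-cell mixtures over the subtyping genes.

    Every tumor mixes 2-3 distinct carcinoma subtypes (drawn from the five
    non-Immuno subtypes) plus an infiltrating immune-cell fraction whose
    profile is globally low except for high immunity-gene expression (a
    sub-fraction of actively dividing immune cells also expresses the
    proliferation genes).  ``dropout`` marks entries missing (zero-inflation
    typical of single-cell data).  Returns the cell matrix and per-cell truth
    (tumor id, cell type, subtype).
    """
    lo, hi = cells_per_tumor
    if not (1 <= lo <= hi):
        raise ValueError("invalid cells_per_tumor range")
    spec = spec or CohortSpec()
    panel = panel or default_panel()
    model = model if model is not None else make_centroids(spec, panel)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    rng = _rng(spec.seed, 3)
    genes = model.gene_ids
    imm_idx = [genes.index(g) for g in panel["immunity"] if g in genes]
    pro_idx = [genes.index(g) for g in panel["proliferation"] if g in genes]
    carcinoma_subtypes = [s for s in SUBTYPES if s != "Immuno"]

    cols = {}
    truth_rows = []
    for t in range(n_tumors):
        tumor = f"T{t:02d}"
        n_cells = int(rng.integers(lo, hi + 1))
        k = int(rng.integers(2, 4))
        subs = list(rng.choice(carcinoma_subtypes, size=k, replace=False))
        for c in range(n_cells):
            cell = f"{tumor}_C{c:03d}"
            if rng.uniform() < immune_fraction:
                prof = np.full(len(genes), -1.0)
                prof[imm_idx] = 1.5
                if rng.uniform() < 0.3:  # actively dividing immune cells
                    prof[pro_idx] = 1.0
                cell_type, sub = "immune", "Immuno"
            else:
                sub = subs[int(rng.integers(0, k))]
                prof = model.centroids[sub].to_numpy(dtype=float).copy()
                cell_type = "carcinoma"
            if sd > 0:
                prof = prof + rng.normal(0.0, sd, size=prof.size)
            if dropout > 0:
                prof = np.where(rng.uniform(size=prof.size) < dropout, np.nan, prof)
            cols[cell] = prof
            truth_rows.append(
                {"cell_id": cell, "tumor_id": tumor, "cell_type": cell_type,
                 "subtype": sub}
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=genes), state="cpm_log2"
    )
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return matrix, truth
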