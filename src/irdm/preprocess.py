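"""Targeted RNA-seq preprocessing: QC, normalization, imputation, centering.

Raw per-gene read counts from the 72-gene targeted assay are turned into an
analysis-ready matrix in four fixed stages:

1. ``qc_filter`` — drop samples with total reads <= 10000 or more than 30%
   of panel genes undetected (zero count);
2. ``normalize_counts`` — divide counts by transcript length, convert to
   counts-per-million within each sample, then log2(CPM + 1); zero counts
   become missing values for the imputation stage;
3. ``knn_impute`` — fill missing entries from the k nearest samples
   (Euclidean distance over shared observed genes, mean over neighbors);
4. ``center_standardize`` — gene rows median-centered and sample columns
   scaled to unit standard deviation, iterated to joint convergence.

Each stage checks the processing-state flag of its input, so stages cannot
be run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panels_io import ExpressionMatrix

__all__ = [
    "CountsTable",
    "READS_CUTOFF",
    "MISSING_CUTOFF",
    "qc_filter",
    "normalize_counts",
    "knn_impute",
    "center_standardize",
    "run_pipeline",
]

#: QC gates: total reads strictly above this, missing fraction strictly below.
READS_CUTOFF = 10_000
MISSING_CUTOFF = 0.30


@dataclass
class CountsTable:
    """Raw targeted RNA-seq counts with transcript lengths and read totals."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    transcript_lengths: pd.Series  # bases per gene
    total_reads: pd.Series | None = None  # per sample; defaults to column sums

    def __post_init__(self) -> None:
        if (self.counts.fillna(0) < 0).any().any():
            raise ValueError("counts must be nonnegative")
        self.transcript_lengths = self.transcript_lengths.reindex(self.counts.index)
        if self.transcript_lengths.isna().any():
            missing = list(self.transcript_lengths.index[self.transcript_lengths.isna()])
            raise ValueError(f"missing transcript lengths for: {missing[:5]}")
        if (self.transcript_lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        colsums = self.counts.sum(axis=0)
        if self.total_reads is None:
            self.total_reads = colsums
        else:
            self.total_reads = self.total_reads.reindex(self.counts.columns)
            if (self.total_reads.fillna(0) + 1e-9 < colsums).any():
                raise ValueError("total_reads cannot be below the column sums")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def qc_filter(
    t: CountsTable, panel_size: int = 72
) -> tuple[CountsTable, pd.DataFrame]:
    """Apply the per-sample QC gates; return passing samples and a report.

    A gene counts as "missing" in a sample when its read count is zero; panel
    genes absent from the table altogether count as missing in every sample.
    The report covers all input samples with pass/fail reasons.
    """
    zero_frac = (
        (t.counts.fillna(0) == 0).sum(axis=0) + (panel_size - t.counts.shape[0])
    ) / panel_size
    reads_ok = t.total_reads > READS_CUTOFF
    missing_ok = zero_frac < MISSING_CUTOFF
    reasons = []
    for s in t.sample_ids:
        r = []
        if not reads_ok[s]:
            r.append(f"total reads {int(t.total_reads[s])} <= {READS_CUTOFF}")
        if not missing_ok[s]:
            r.append(f"missing gene fraction {zero_frac[s]:.3f} >= {MISSING_CUTOFF}")
        reasons.append("; ".join(r))
    report = pd.DataFrame(
        {
            "total_reads": t.total_reads.astype(int),
            "missing_gene_fraction": zero_frac,
            "pass": reads_ok & missing_ok,
            "reasons": reasons,
        },
        index=pd.Index(t.sample_ids, name="sample_id"),
    )
    keep = report.index[report["pass"]]
    passed = CountsTable(
        t.counts.loc[:, keep].copy(),
        t.transcript_lengths.copy(),
        t.total_reads.loc[keep].copy(),
    )
    return passed, report


def normalize_counts(t: CountsTable) -> ExpressionMatrix:
    """Length-normalize, library-normalize to CPM, then log2(CPM + 1).

    value(g, s) = log2(1 + 1e6 * (count/length) / sum_g'(count/length)).
    Zero-count entries become missing (NaN) for downstream imputation.
    """
    rate = t.counts.div(t.transcript_lengths, axis=0)
    lib = rate.sum(axis=0)
    dead = lib.index[lib <= 0]
    if len(dead):
        raise ValueError(f"samples with all-zero counts: {list(dead)}")
    cpm = rate.div(lib, axis=1) * 1e6
    vals = np.log2(1.0 + cpm)
    vals = vals.where(t.counts > 0)  # zeros -> missing
    return ExpressionMatrix(vals.astype(float), state="cpm_log2")


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries from the k nearest samples.

    Distances are Euclidean over genes observed in both samples; each missing
    entry is replaced by the mean of the gene's values in the k nearest
    samples.  Observed entries are never altered.  Requires per-gene missing
    fraction < 30%.
    """
    from sklearn.impute import KNNImputer

    if m.state != "cpm_log2":
        raise ValueError(f"knn_impute expects state 'cpm_log2', got {m.state!r}")
    vals = m.values
    if not vals.isna().any().any():
        return ExpressionMatrix(vals.copy(), state=m.state)
    gene_missing = vals.isna().mean(axis=1)
    bad = gene_missing.index[gene_missing >= MISSING_CUTOFF]
    if len(bad):
        raise ValueError(
            f"genes with >= 30% missing values cannot be imputed: {list(bad[:5])}"
        )
    obs = vals.notna()
    shared = obs.T.astype(int) @ obs.astype(int)  # samples x samples
    np.fill_diagonal(shared.values, 0)
    isolated = shared.index[(shared == 0).all(axis=1)]
    if len(isolated):
        raise ValueError(
            f"samples sharing no observed genes with any other: {list(isolated)}"
        )
    imputer = KNNImputer(n_neighbors=min(k, m.n_samples - 1), weights="uniform")
    filled = imputer.fit_transform(vals.to_numpy(dtype=float).T).T
    out = vals.copy()
    out.loc[:, :] = np.where(vals.notna(), vals, filled)
    return ExpressionMatrix(out, state=m.state)


def center_standardize(
    m: ExpressionMatrix, tol: float = 1e-10, max_iter: int = 500
) -> ExpressionMatrix:
    """Median-center gene rows and scale sample columns to unit SD.

    A single row-then-column pass cannot leave both constraints satisfied, so
    the pair of steps (center rows, then standardize columns) is iterated
    until every row median is 0 and every column SD is 1 within tolerance
    (successive normalization; converges rapidly in practice).
    """
    if m.state != "cpm_log2":
        raise ValueError(f"center_standardize expects state 'cpm_log2', got {m.state!r}")
    vals = m.values.to_numpy(dtype=float).copy()
    if np.isnan(vals).any():
        raise ValueError("center_standardize requires a fully imputed matrix")
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize columns")
    cols = list(m.values.columns)
    flat0 = np.where(vals.std(axis=0, ddof=1) <= 0)[0]
    if len(flat0):
        raise ValueError(
            f"zero-variance sample column(s): {[cols[i] for i in flat0[:5]]}"
        )
    for _ in range(max_iter):
        vals -= np.median(vals, axis=1, keepdims=True)
        sd = vals.std(axis=0, ddof=1, keepdims=True)
        flat = np.where(sd.ravel() <= 0)[0]
        if len(flat):
            raise ValueError(
                f"zero-variance sample column(s): {[cols[i] for i in flat[:5]]}"
            )
        vals /= sd
        row_ok = np.abs(np.median(vals, axis=1)).max() <= tol
        col_ok = np.abs(vals.std(axis=0, ddof=1) - 1.0).max() <= tol
        if row_ok and col_ok:
            break
    else:
        raise RuntimeError("center_standardize did not converge")
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, state="centered_standardized")


def run_pipeline(
    t: CountsTable, panel_size: int = 72, k: int = 10
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Full chain: qc_filter -> normalize_counts -> knn_impute -> center_standardize."""
    passed, report = qc_filter(t, panel_size=panel_size)
    if passed.counts.shape[1] == 0:
        raise ValueError("all samples failed QC")
    normalized = normalize_counts(passed)
    imputed = knn_impute(normalized, k=k)
    final = center_standardize(imputed)
    return final, report
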