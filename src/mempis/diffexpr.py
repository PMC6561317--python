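"""Differential expression of EC-level transcript counts.

This module produces the over-expressed EC sets that constrain the subnetwork
MILP: upper-quartile normalization, per-EC fold changes against a reference
treatment, Benjamini-Hochberg adjustment, and strict-threshold selection
(padj < 0.1 and log2FC > 1 by default).

Count matrices are plain :class:`pandas.DataFrame` objects with EC identifiers
as the index and sample identifiers as columns; the sample design is a
DataFrame with columns ``sample``, ``site``, ``treatment``, ``replicate``.

The raw p-value engine is pluggable.  The built-in default is a two-sample
Welch t-test on log2(normalized count + pseudocount) — a declared stand-in for
a negative-binomial count model: users with DESeq2 (or similar) output can
bypass it entirely by reading a precomputed differential table with
:func:`read_differential_table` (columns ``ec``, ``baseMean``,
``log2FoldChange``, ``lfcSE``, ``pvalue``, ``padj``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialRecord",
    "SelectionCriteria",
    "DISPLAY_PRESET",
    "upper_quartile_normalize",
    "bh_adjust",
    "welch_log_t",
    "differential_table",
    "select_overexpressed",
    "rank_top_abundant",
    "records_to_frame",
    "frame_to_records",
    "read_differential_table",
    "write_differential_table",
    "validate_counts",
    "validate_design",
]

#: Pseudocount added to normalized means before taking log2 fold changes,
#: avoiding infinities when one group is all-zero with few replicates.
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DifferentialRecord:
    """One EC's differential-expression result."""

    ec: str
    base_mean: float
    log2fc: float
    lfc_se: float
    pvalue: float
    padj: float


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for calling an EC over-expressed (strict inequalities).

    Defaults are FDR < 0.1 combined with expression more than two times
    higher in the treatment than the reference (log2 FC > 1).
    """

    fdr_max: float = 0.1
    log2fc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.log2fc_min < 0:
            raise ValueError(f"log2fc_min must be >= 0, got {self.log2fc_min}")


#: Stricter report-level filter (FC > 1.5, padj < 0.05) offered as a preset;
#: not the default evidence rule.
DISPLAY_PRESET = SelectionCriteria(fdr_max=0.05, log2fc_min=float(np.log2(1.5)))


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate feature (EC) identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def validate_design(design: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    required = {"sample", "site", "treatment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    if counts is not None:
        absent = set(counts.columns) - set(design["sample"])
        if absent:
            raise ValueError(f"count matrix samples not in design: {sorted(absent)}")


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by the 75th percentile of its nonzero counts.

    The per-sample factors are rescaled by their geometric mean so the output
    stays on a common count-like scale.  Percentiles use linear interpolation.
    """
    validate_counts(counts)
    arr = counts.to_numpy(dtype=float)
    uq = np.empty(arr.shape[1])
    for j, sample in enumerate(counts.columns):
        nonzero = arr[:, j][arr[:, j] > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        uq[j] = np.percentile(nonzero, 75)
    scale = np.exp(np.mean(np.log(uq)))  # geometric mean of the quartiles
    out = arr / uq[np.newaxis, :] * scale
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def welch_log_t(treatment: np.ndarray, reference: np.ndarray) -> float:
    """Two-sample Welch t-test on log2(x + pseudocount); the built-in stand-in
    p-value engine for normalized counts."""
    a = np.log2(np.asarray(treatment, dtype=float) + PSEUDOCOUNT)
    b = np.log2(np.asarray(reference, dtype=float) + PSEUDOCOUNT)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def differential_table(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("dry", "control"),
    test: Callable[[np.ndarray, np.ndarray], float] = welch_log_t,
    normalize: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> list[DifferentialRecord]:
    """Per-EC differential expression for ``contrast = (treatment, reference)``.

    base_mean is the mean normalized count over all samples; log2fc compares
    group means of normalized counts with a pseudocount; padj is BH over all
    tested ECs.
    """
    validate_counts(counts)
    validate_design(design, counts)
    treatment, reference = contrast
    design = design.set_index("sample")
    for label in (treatment, reference):
        if label not in set(design["treatment"]):
            raise ValueError(f"unknown treatment label {label!r}")
    t_samples = [s for s in counts.columns if design.loc[s, "treatment"] == treatment]
    r_samples = [s for s in counts.columns if design.loc[s, "treatment"] == reference]
    if not t_samples or not r_samples:
        raise ValueError(f"empty contrast group for {contrast}")

    norm = upper_quartile_normalize(counts) if normalize else counts.astype(float)
    t_arr = norm[t_samples].to_numpy()
    r_arr = norm[r_samples].to_numpy()

    base_mean = norm.to_numpy().mean(axis=1)
    mean_t = t_arr.mean(axis=1)
    mean_r = r_arr.mean(axis=1)
    log2fc = np.log2(mean_t + pseudocount) - np.log2(mean_r + pseudocount)

    # SE of the log2 mean difference, from the per-sample log2 values.
    lt = np.log2(t_arr + pseudocount)
    lr = np.log2(r_arr + pseudocount)
    var_t = lt.var(axis=1, ddof=1) if lt.shape[1] > 1 else np.zeros(len(norm))
    var_r = lr.var(axis=1, ddof=1) if lr.shape[1] > 1 else np.zeros(len(norm))
    lfc_se = np.sqrt(var_t / max(lt.shape[1], 1) + var_r / max(lr.shape[1], 1))

    pvals = np.array([test(t_arr[i], r_arr[i]) for i in range(len(norm))])
    padj = bh_adjust(pvals)
    return [
        DifferentialRecord(
            ec=str(ec),
            base_mean=float(base_mean[i]),
            log2fc=float(log2fc[i]),
            lfc_se=float(lfc_se[i]),
            pvalue=float(pvals[i]),
            padj=float(padj[i]),
        )
        for i, ec in enumerate(norm.index)
    ]


def select_overexpressed(
    records: Iterable[DifferentialRecord],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> set[str]:
    """ECs with padj strictly below fdr_max AND log2fc strictly above log2fc_min."""
    return {
        rec.ec
        for rec in records
        if rec.padj < criteria.fdr_max and rec.log2fc > criteria.log2fc_min
    }


def rank_top_abundant(
    counts: pd.DataFrame,
    n: int,
    samples: Sequence[str] | None = None,
    normalize: bool = True,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[list[str], pd.DataFrame]:
    """Top-``n`` ECs by total normalized abundance, with a per-sample log2
    fold-change matrix against each EC's mean over the selected samples.

    Ties in abundance break lexicographically by EC string; ``n`` larger than
    the feature count returns everything.  This is the heat-map input; any
    clipping to a display range is left to the renderer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    norm = upper_quartile_normalize(counts) if normalize else counts.astype(float)
    if samples is not None:
        norm = norm[list(samples)]
    totals = norm.sum(axis=1)
    order = sorted(norm.index, key=lambda ec: (-totals[ec], str(ec)))
    top = order[: min(n, len(order))]
    sub = norm.loc[top]
    row_mean = sub.mean(axis=1)
    log2fc = np.log2(sub.add(pseudocount)).sub(
        np.log2(row_mean + pseudocount), axis=0
    )
    return top, log2fc


_TABLE_COLUMNS = ["ec", "baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj"]


def records_to_frame(records: Iterable[DifferentialRecord]) -> pd.DataFrame:
    rows = [
        (r.ec, r.base_mean, r.log2fc, r.lfc_se, r.pvalue, r.padj) for r in records
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DifferentialRecord]:
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    return [
        DifferentialRecord(
            ec=str(row.ec),
            base_mean=float(row.baseMean),
            log2fc=float(row.log2FoldChange),
            lfc_se=float(row.lfcSE),
            pvalue=float(row.pvalue),
            padj=float(row.padj),
        )
        for row in frame.itertuples()
    ]


def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    """Read an externally computed differential table (e.g. DESeq2 output
    reshaped to the documented column schema)."""
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_differential_table(
    records: Iterable[DifferentialRecord], path: str | Path
) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
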