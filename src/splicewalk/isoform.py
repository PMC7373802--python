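"""Isoform fraction computation and isoform-switch detection.

An isoform's fraction (IF) is its share of the total abundance of its gene
in one sample; a switch is a shift of that share between tumor and normal
conditions. The switch statistic here is a two-sided Welch t-test on the
per-sample IF values, Benjamini–Hochberg corrected across all testable
isoforms; significance requires |dIF| > 0.1 and q < 0.05, with dIF the
difference of condition means (tumor minus normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator

from .coexpression import bh_adjust

CONDITIONS = ("tumor", "normal")
DIF_THRESHOLD = 0.1
Q_THRESHOLD = 0.05


@dataclass
class ExpressionMatrix:
    """Isoform-level abundances with sample conditions and an isoform→gene map."""

    values: pd.DataFrame  # isoforms x samples, nonnegative
    condition: pd.Series  # per-sample label in {tumor, normal}
    iso2gene: pd.Series  # isoform id -> gene id

    def __post_init__(self) -> None:
        vals = self.values
        if (vals.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not vals.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(vals.columns)
            if self.condition.isna().any():
                missing = self.condition.index[self.condition.isna()].tolist()
                raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if set(self.condition.unique()) != set(CONDITIONS):
            raise ValueError("both tumor and normal conditions must be present")
        unmapped = vals.index.difference(self.iso2gene.index)
        if len(unmapped):
            raise ValueError(f"isoforms without gene mapping: {list(unmapped[:5])}")

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene_of(self) -> pd.Series:
        return self.iso2gene.reindex(self.values.index)


def read_expression(
    expr_path: str | Path, condition_path: str | Path, iso2gene_path: str | Path
) -> ExpressionMatrix:
    """Load expression TSV (first column isoform id), condition TSV and map TSV."""
    vals = pd.read_csv(expr_path, sep="\t", index_col=0)
    cond = pd.read_csv(
        condition_path, sep="\t", header=None, names=["sample", "condition"], index_col=0
    )["condition"]
    i2g = pd.read_csv(
        iso2gene_path, sep="\t", header=None, names=["isoform", "gene"], index_col=0
    )["gene"]
    return ExpressionMatrix(values=vals, condition=cond, iso2gene=i2g)


def drop_all_nil_isoforms(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Discard isoforms whose abundance is zero in every sample."""
    keep = (expr.values != 0).any(axis=1)
    if not keep.any():
        warnings.warn("all isoforms are zero across all samples", stacklevel=2)
    return ExpressionMatrix(
        values=expr.values.loc[keep],
        condition=expr.condition,
        iso2gene=expr.iso2gene,
    )


def isoform_fraction(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample isoform fractions; NaN where the gene total is zero.

    For each gene and sample the fractions of its isoforms sum to 1 whenever
    the gene has nonzero total abundance in that sample.
    """
    gene = expr.gene_of()
    totals = expr.values.groupby(gene, sort=False).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = expr.values / totals
    return frac.where(totals > 0)


def switch_test(
    if_matrix: pd.DataFrame,
    condition: pd.Series,
    iso2gene: pd.Series,
    min_per_condition: int = 2,
) -> pd.DataFrame:
    """Welch t-test of tumor vs normal isoform fractions per isoform.

    Returns a DataFrame with isoform_id, gene_id, dIF, p_value, q_value and
    direction ("gain" if dIF > 0 else "loss"). Isoforms with fewer than
    ``min_per_condition`` defined IF values in either condition are kept with
    missing p (untested) and excluded from the BH universe.
    """
    condition = condition.reindex(if_matrix.columns)
    tmask = (condition == "tumor").to_numpy()
    nmask = (condition == "normal").to_numpy()
    if tmask.sum() < min_per_condition or nmask.sum() < min_per_condition:
        raise ValueError("need at least two samples per condition")
    X = if_matrix.to_numpy(dtype=float)
    tum, nor = X[:, tmask], X[:, nmask]
    n_t = np.sum(~np.isnan(tum), axis=1)
    n_n = np.sum(~np.isnan(nor), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(np.where(np.isnan(tum), np.nan, tum), axis=1)
        mean_n = np.nanmean(np.where(np.isnan(nor), np.nan, nor), axis=1)
        dif = mean_t - mean_n
        res = st.ttest_ind(tum, nor, axis=1, equal_var=False, nan_policy="omit")
        pvals = np.asarray(res.pvalue, dtype=float)
    testable = (n_t >= min_per_condition) & (n_n >= min_per_condition) & np.isfinite(pvals)
    # zero-variance pairs with identical means: no evidence of change
    degenerate = (
        (n_t >= min_per_condition)
        & (n_n >= min_per_condition)
        & ~np.isfinite(pvals)
        & np.isclose(np.nan_to_num(dif), 0.0)
    )
    pvals = np.where(degenerate, 1.0, pvals)
    testable = testable | degenerate
    qvals = np.full_like(pvals, np.nan)
    if testable.any():
        qvals[testable] = bh_adjust(pvals[testable])
    out = pd.DataFrame(
        {
            "isoform_id": if_matrix.index,
            "gene_id": iso2gene.reindex(if_matrix.index).to_numpy(),
            "dIF": dif,
            "p_value": np.where(testable, pvals, np.nan),
            "q_value": qvals,
            "direction": np.where(dif > 0, "gain", "loss"),
        }
    ).reset_index(drop=True)
    return out


def filter_switches(
    results: pd.DataFrame,
    dif_threshold: float = DIF_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Keep significant switches: |dIF| > 0.1 and q < 0.05 (two-sided)."""
    mask = (results["dIF"].abs() > dif_threshold) & (results["q_value"] < q_threshold)
    return results.loc[mask.fillna(False)].reset_index(drop=True)


class IsoformSwitchTester(BaseEstimator):
    """Detect tumor/normal isoform switches from an expression matrix.

    ``fit`` drops all-zero isoforms, computes isoform fractions, runs the
    per-isoform Welch test with BH correction, and applies the significance
    filter.

    Parameters
    ----------
    dif_threshold : float, default 0.1
        Minimum absolute difference in mean isoform fraction.
    q_threshold : float, default 0.05
        BH-adjusted significance level.
    min_per_condition : int, default 2
        Minimum defined IF values per condition for an isoform to be tested.

    Attributes
    ----------
    if_matrix_ : isoform-fraction DataFrame
    results_ : full per-isoform statistics
    significant_ : rows passing both thresholds
    """

    def __init__(
        self,
        dif_threshold: float = DIF_THRESHOLD,
        q_threshold: float = Q_THRESHOLD,
        min_per_condition: int = 2,
    ):
        self.dif_threshold = dif_threshold
        self.q_threshold = q_threshold
        self.min_per_condition = min_per_condition

    def fit(self, expr: ExpressionMatrix, y: None = None) -> "IsoformSwitchTester":
        expr = drop_all_nil_isoforms(expr)
        self.if_matrix_ = isoform_fraction(expr)
        self.results_ = switch_test(
            self.if_matrix_,
            expr.condition,
            expr.iso2gene,
            min_per_condition=self.min_per_condition,
        )
        self.significant_ = filter_switches(
            self.results_, self.dif_threshold, self.q_threshold
        )
        return self
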