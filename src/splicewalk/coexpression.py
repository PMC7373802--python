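"""Signed lncRNA–target co-expression edges from Pearson correlation.

All lncRNA × target pairs are scored with Pearson r and a two-sided p-value
from the t-transform (t = r·sqrt(n-2)/sqrt(1-r²), n-2 df, exact under
bivariate normality); pairs with zero variance in either profile are
undefined and excluded before Benjamini–Hochberg correction over the full
tested set. The network keeps pairs with |r| > 0.75 and q < 0.05; the sign
of r labels the lncRNA an activator (r > 0) or inhibitor (r < 0) of its
target.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .network import Layer

R_THRESHOLD = 0.75
Q_THRESHOLD = 0.05


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, clipped to [0,1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


def pearson_network(lnc_expr: pd.DataFrame, target_expr: pd.DataFrame) -> pd.DataFrame:
    """Score every lncRNA × target pair with Pearson r and a two-sided p.

    Both matrices are features × samples over identical sample columns.
    Pairs where either profile has zero variance get r = NaN and are flagged
    ``defined = False`` (excluded from multiple-testing downstream).
    """
    if not lnc_expr.columns.equals(target_expr.columns):
        raise ValueError("lncRNA and target matrices must share sample columns")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation testing")
    X = lnc_expr.to_numpy(dtype=float)
    Y = target_expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xs, ys)
    R = np.clip(R, -1.0, 1.0)
    defined = np.outer(xs > 0, ys > 0)
    R[~defined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R**2))
    pmat = 2.0 * st.t.sf(np.abs(tstat), df=n - 2)
    pmat = np.where(np.isfinite(R) & (np.abs(R) >= 1.0), 0.0, pmat)
    lnc_ids = np.repeat(lnc_expr.index.to_numpy(), target_expr.shape[0])
    tgt_ids = np.tile(target_expr.index.to_numpy(), lnc_expr.shape[0])
    out = pd.DataFrame(
        {
            "lnc_id": lnc_ids,
            "target_id": tgt_ids,
            "r": R.ravel(),
            "p_value": pmat.ravel(),
            "defined": defined.ravel(),
        }
    )
    out.loc[~out["defined"], "p_value"] = np.nan
    out["q_value"] = np.nan
    tested = out["defined"].to_numpy()
    if tested.any():
        out.loc[tested, "q_value"] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["role"] = np.where(out["r"] > 0, "activator", "inhibitor")
    out.loc[~out["defined"], "role"] = pd.NA
    return out


def threshold_edges(
    edges: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    weight_by_abs_r: bool = False,
) -> Layer:
    """Build the co-expression layer from pairs with |r| > 0.75 and q < 0.05.

    Edge weights default to binary 1.0; ``weight_by_abs_r`` carries |r|
    instead.
    """
    keep = edges.loc[
        edges["defined"].fillna(False)
        & (edges["r"].abs() > r_threshold)
        & (edges["q_value"] < q_threshold)
    ]
    layer_edges: dict[tuple[str, str], float] = {}
    for row in keep.itertuples():
        w = abs(row.r) if weight_by_abs_r else 1.0
        u, v = (row.lnc_id, row.target_id)
        key = (u, v) if u < v else (v, u)
        layer_edges[key] = w
    return Layer(name="coexpression", edges=layer_edges)


class CoexpressionNetwork(BaseEstimator):
    """Estimator wrapper: fit on (lncRNA, target) expression, emit the layer.

    Attributes
    ----------
    edges_ : all scored pairs with r, p, q, role
    layer_ : thresholded co-expression Layer
    """

    def __init__(
        self,
        r_threshold: float = R_THRESHOLD,
        q_threshold: float = Q_THRESHOLD,
        weight_by_abs_r: bool = False,
    ):
        self.r_threshold = r_threshold
        self.q_threshold = q_threshold
        self.weight_by_abs_r = weight_by_abs_r

    def fit(
        self, lnc_expr: pd.DataFrame, target_expr: pd.DataFrame
    ) -> "CoexpressionNetwork":
        self.edges_ = pearson_network(lnc_expr, target_expr)
        self.layer_ = threshold_edges(
            self.edges_,
            r_threshold=self.r_threshold,
            q_threshold=self.q_threshold,
            weight_by_abs_r=self.weight_by_abs_r,
        )
        return self


def write_correlation_edges(edges: pd.DataFrame, path) -> None:
    cols = ["lnc_id", "target_id", "r", "p_value", "q_value", "role"]
    edges.loc[:, cols].to_csv(path, sep="\t", index=False)
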