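"""Bootstrap ROC evaluation of a ranking against curated gene lists.

True positives (TPG) are hugely outnumbered by the true-negative pool, so
each repetition samples a balanced negative set of size |TPG| without
replacement, computes the AUC by the Mann–Whitney rank formulation
(average-rank convention under ties), and the final performance is the mean
over repetitions (10 by default). The rank cutoff is chosen where the
ROC slope dTPR/dFPR over successive rank windows drops suddenly relative to
the steepest slope seen so far.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.metrics import roc_curve as _sk_roc_curve

DEFAULT_REPS = 10


@dataclass
class EvalResult:
    auc_per_rep: list[float]
    mean_auc: float
    roc_points: list[np.ndarray] = field(default_factory=list)  # per rep, (m, 2) FPR/TPR
    chosen_n: int | None = None


def rank_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie), via average ranks."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = st.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """Step ROC points (FPR, TPR) from scores and binary labels.

    Ties are rendered as diagonal segments (all tied items enter together).
    The curve starts at (0, 0) and ends at (1, 1).
    """
    y = np.asarray(labels)
    if len(set(np.unique(y))) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def trapezoid_auc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def bootstrap_auc(
    scores: Mapping[str, float] | pd.Series,
    tpg: Iterable[str],
    tng_pool: Iterable[str],
    reps: int = DEFAULT_REPS,
    rng_seed: int | None = None,
) -> EvalResult:
    """Balanced-subsample ROC evaluation of scored nodes.

    Per repetition, |TPG| negatives are drawn from the pool without
    replacement and the Mann–Whitney AUC of TPG vs the sample is computed;
    the reported performance is the mean over repetitions.
    """
    scores = pd.Series(scores)
    tpg = list(dict.fromkeys(tpg))
    pool = list(dict.fromkeys(tng_pool))
    overlap = set(tpg) & set(pool)
    if overlap:
        raise ValueError(f"TPG and TNG pool overlap: {sorted(overlap)[:5]}")
    if len(pool) < len(tpg):
        raise ValueError("negative pool smaller than the positive set")
    missing = [i for i in tpg + pool if i not in scores.index]
    if missing:
        raise ValueError(f"unscored ids: {missing[:5]}")
    rng = np.random.default_rng(rng_seed)
    pos = scores.loc[tpg].to_numpy()
    pool_scores = scores.loc[pool].to_numpy()
    aucs: list[float] = []
    curves: list[np.ndarray] = []
    for _ in range(reps):
        neg = pool_scores[rng.choice(len(pool), size=len(tpg), replace=False)]
        aucs.append(rank_auc(pos, neg))
        pts = roc_points(
            np.concatenate([pos, neg]),
            np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)]),
        )
        curves.append(pts)
    return EvalResult(auc_per_rep=aucs, mean_auc=float(np.mean(aucs)), roc_points=curves)


def select_cutoff(
    labels_in_rank_order: Sequence[int],
    window: int = 10,
    drop_ratio: float = 0.1,
) -> tuple[int, bool]:
    """Choose the top-n rank cutoff where the ROC slope suddenly drops.

    Walking down the ranking in windows of ``window`` ranks, the slope
    dTPR/dFPR of each window is compared with the steepest slope seen so
    far; the cutoff is the last rank before the first sustained drop below
    ``drop_ratio`` times that maximum. Windows with no false positives have
    infinite slope; for the running maximum they are regularized with a
    half-count false-positive floor so that one stray negative cannot mask
    the elbow. A drop must persist for two consecutive windows (or reach the
    end of the list) to count, which keeps noisy uniform rankings from
    triggering spurious elbows.

    Returns ``(chosen_n, found)``; when no drop is found, ``chosen_n`` is the
    full list length, ``found`` is False, and a warning is issued.
    """
    y = np.asarray(labels_in_rank_order, dtype=int)
    n_total = y.size
    if n_total < 2 * window:
        raise ValueError("need at least two windows of ranked items")
    P = int(y.sum())
    N = int(n_total - P)
    if P == 0 or N == 0:
        raise ValueError("labels must contain both classes")
    n_windows = n_total // window
    tp = np.array([y[i * window : (i + 1) * window].sum() for i in range(n_windows)])
    fp = window - tp
    reg_slope = (tp / P) / (np.maximum(fp, 0.5) / N)

    max_so_far = reg_slope[0]
    i = 1
    while i < n_windows:
        threshold = drop_ratio * max_so_far
        dropped = reg_slope[i] < threshold
        sustained = dropped and (i + 1 >= n_windows or reg_slope[i + 1] < threshold)
        if sustained:
            return i * window, True
        max_so_far = max(max_so_far, reg_slope[i])
        i += 1
    warnings.warn(
        "ROC slope never dropped below the elbow threshold; returning full length",
        stacklevel=2,
    )
    return n_total, False


def evaluate_ranking(
    ranked: pd.DataFrame,
    tpg: Iterable[str],
    tng_pool: Iterable[str],
    reps: int = DEFAULT_REPS,
    rng_seed: int | None = None,
    window: int = 10,
    drop_ratio: float = 0.1,
) -> EvalResult:
    """Bootstrap AUC plus rank-cutoff selection on a ranking table."""
    scores = ranked.set_index("id")["score"]
    result = bootstrap_auc(scores, tpg, tng_pool, reps=reps, rng_seed=rng_seed)
    tpg_set = set(tpg)
    labels = ranked["id"].isin(tpg_set).to_numpy().astype(int)
    if labels.sum() and (labels == 0).sum() and len(labels) >= 2 * window:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.chosen_n, _ = select_cutoff(labels, window=window, drop_ratio=drop_ratio)
    return result
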