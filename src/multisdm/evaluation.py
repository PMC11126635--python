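"""Performance statistics: ranks, top-k accuracy, AUC, validation.

The headline statistic is the rank of the observed taxon in the
prediction for its record — rank 1 means the model put the observed
taxon first. Because the test set is taxonomically balanced, summaries
are weighted by per-taxon training counts so that scores represent
typical field observations rather than the balanced design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score

__all__ = [
    "observed_rank",
    "weighted_summary",
    "topk_accuracy",
    "auc",
    "species_and_site_auc",
    "phenology_validation",
    "dominance_validation",
]


def observed_rank(predictions, observed, ties: str = "average"):
    """Rank of the observed taxon in each prediction vector.

    rank = 1 + #{strictly higher} plus, under the default average-rank
    convention, half of the remaining ties; ``optimistic`` counts ties as
    beaten, ``pessimistic`` as beating.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    o = np.atleast_1d(np.asarray(observed, dtype=int))
    po = p[np.arange(len(p)), o][:, None]
    higher = (p > po).sum(axis=1)
    tied = (p == po).sum(axis=1) - 1  # excluding the observed item itself
    if ties == "average":
        r = 1.0 + higher + tied / 2.0
    elif ties == "optimistic":
        r = 1.0 + higher
    elif ties == "pessimistic":
        r = 1.0 + higher + tied
    else:
        raise ValueError("ties must be average|optimistic|pessimistic")
    return r if r.size > 1 else float(r[0])


def weighted_summary(values, weights=None):
    """Weighted mean and weighted median of a statistic.

    The weighted median is the smallest value whose cumulative weight
    reaches half the total; unit weights reproduce the ordinary
    statistics.
    """
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must align")
    mean = float(np.sum(w * v) / np.sum(w))
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    median = float(v[order][np.searchsorted(cw, 0.5 * cw[-1])])
    return {"weighted_mean": mean, "weighted_median": median}


def topk_accuracy(predictions, observed, ks=(1, 5, 10, 20), weights=None):
    """Fraction of records whose observed taxon ranks within the top k.

    Uses the tie-average rank; optional per-record weights give the
    training-count-weighted accuracies.
    """
    ranks = np.atleast_1d(observed_rank(predictions, observed))
    w = np.ones_like(ranks) if weights is None else np.asarray(weights, float)
    return {
        int(k): float(np.sum(w * (ranks <= k)) / np.sum(w)) for k in ks
    }


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    Equals the all-pairs count with ties scored 1/2. NaN when only one
    class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = stats.rankdata(s, method="average")
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def species_and_site_auc(summary: np.ndarray, presence: np.ndarray):
    """Column-wise (species-by-species) and row-wise (site-by-site) AUC.

    ``summary`` and ``presence`` are aligned site x taxon matrices: the
    annual prediction summary and the observed presence/absence. The
    species view discriminates occupied from unoccupied sites per taxon;
    the site view discriminates a site's present taxa from the full
    taxon list, including never-observed taxa. Undefined entries
    (single-class) are NaN.
    """
    s = np.asarray(summary, dtype=float)
    p = np.asarray(presence).astype(bool)
    if s.shape != p.shape:
        raise ValueError("summary and presence matrices must align")
    species = np.array([auc(s[:, j], p[:, j]) for j in range(s.shape[1])])
    sites = np.array([auc(s[i, :], p[i, :]) for i in range(s.shape[0])])
    return species, sites


def phenology_validation(
    t_peak: np.ndarray,
    bloom: pd.DataFrame,
    cell_size: float = 1.0,
    origin=(0.0, 0.0),
):
    """Compare a peak-timing map against dated full-bloom records.

    ``bloom`` needs columns x, y, doy. Records falling on masked pixels
    are dropped. Returns median bias (predicted minus observed, days),
    Spearman rank correlation over the matched pairs (NaN when
    degenerate, e.g. a constant prediction), and the pair count.
    """
    col = np.floor((bloom["x"].to_numpy() - origin[0]) / cell_size).astype(int)
    row = np.floor((bloom["y"].to_numpy() - origin[1]) / cell_size).astype(int)
    inside = (
        (row >= 0)
        & (row < t_peak.shape[0])
        & (col >= 0)
        & (col < t_peak.shape[1])
    )
    pred = np.full(len(bloom), np.nan)
    pred[inside] = t_peak[row[inside], col[inside]]
    ok = ~np.isnan(pred)
    obs = bloom["doy"].to_numpy(dtype=float)[ok]
    pred = pred[ok]
    if len(pred) == 0:
        return {"bias": float("nan"), "spearman_r": float("nan"), "n": 0}
    bias = float(np.median(pred - obs))
    if len(pred) < 2 or np.all(pred == pred[0]) or np.all(obs == obs[0]):
        r = float("nan")
    else:
        r = float(stats.spearmanr(pred, obs).statistic)
    return {"bias": bias, "spearman_r": r, "n": int(len(pred))}


def _corner_adjacent_mean(weighted: np.ndarray, row, col):
    """Mean weighted probability over the 4 pixels adjacent to a corner.

    ``weighted`` is (taxa, rows, cols); (row, col) index the pixel
    up-right of the corner, so the block is [row-1:row+1, col-1:col+1].
    """
    r0, r1 = max(row - 1, 0), min(row + 1, weighted.shape[1])
    c0, c1 = max(col - 1, 0), min(col + 1, weighted.shape[2])
    return weighted[:, r0:r1, c0:c1].reshape(weighted.shape[0], -1).mean(axis=1)


def dominance_validation(
    weighted_probs: np.ndarray,
    taxa: list,
    sites: pd.DataFrame,
    observed: pd.Series | np.ndarray,
    cell_size: float = 1.0,
    origin=(0.0, 0.0),
    corner_sited: bool = False,
):
    """Top-1 accuracy and per-taxon F1 of dominance predictions at sites.

    ``weighted_probs`` is the (taxa, rows, cols) bias-corrected (or raw)
    mean-probability stack; ``sites`` needs columns x, y. With
    ``corner_sited`` the four pixels adjacent to each site's corner
    coordinate are averaged before the argmax, matching validation plots
    whose coordinates fall exactly on cell corners. F1 is the harmonic
    mean of precision and recall per taxon, 0 when precision + recall is
    0; taxa neither predicted nor observed are excluded.
    """
    obs = np.asarray(observed)
    col = np.floor((sites["x"].to_numpy() - origin[0]) / cell_size).astype(int)
    row = np.floor((sites["y"].to_numpy() - origin[1]) / cell_size).astype(int)
    pred_idx = np.empty(len(sites), dtype=int)
    for i in range(len(sites)):
        if corner_sited:
            vec = _corner_adjacent_mean(weighted_probs, row[i], col[i])
        else:
            vec = weighted_probs[:, row[i], col[i]]
        pred_idx[i] = int(np.argmax(vec))
    pred = np.asarray(taxa, dtype=object)[pred_idx]
    accuracy = float(np.mean(pred == obs))
    active = sorted(set(obs) | set(pred))
    f1 = f1_score(obs, pred, labels=active, average=None, zero_division=0.0)
    per_taxon = pd.DataFrame(
        {
            "taxon": active,
            "f1": f1,
            "n_observed": [int(np.sum(obs == t)) for t in active],
            "n_correct": [
                int(np.sum((obs == t) & (pred == t))) for t in active
            ],
        }
    )
    return {"top1_accuracy": accuracy, "per_taxon": per_taxon}
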