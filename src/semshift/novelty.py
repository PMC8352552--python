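"""Embedding-space novelty detection over a windowed, embedded corpus.

Four strategies, all consuming only an :class:`~semshift.embedding.EmbeddedCorpus`:

T1  minimum-distance novelty: a document is potentially novel when its
    minimum Euclidean distance E-min to every document in a comparator
    collection (cumulative past by default) exceeds the relatedness
    threshold S-rel.
T2  trend membership: a T1-novel document belongs to an emerging trend
    when its k-th nearest neighbour inside its own window is closer than
    its k-th nearest neighbour in the past (default k = 3); the old/new
    k-neighbourhood distance ratio quantifies how trend-like it is.
Y1  centroid trajectory: per-window mean vectors and the Euclidean hop
    lengths between consecutive means; long hops suggest a directional
    shift of the field.  A 2-D PCA projection is provided for plotting
    only — hop lengths are always measured in the full space.
Y2  novel-proportion series: per window, the fraction of documents that
    are T1-novel against the cumulative past.

The shipped default thresholds (S-rel = 2.3, S-unrel = 4.0) are the
published calibration for 700-d BioSentVec title embeddings; any other
embedder should be recalibrated (``calibrate_thresholds``), and using the
preset with a different embedder logs a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted

from .embedding import EmbeddedCorpus

logger = logging.getLogger(__name__)

COMPARATORS = ("cumulative_past", "previous_window")


@dataclass(frozen=True)
class Thresholds:
    """Distance thresholds: pairs below s_rel are very likely related,
    pairs above s_unrel very unlikely related."""

    s_rel: float = 2.3
    s_unrel: float = 4.0
    provenance: str = "biosentvec-calibrated"

    def __post_init__(self) -> None:
        if not 0 < self.s_rel < self.s_unrel:
            raise ValueError("require 0 < s_rel < s_unrel")


#: the named preset calibrated on BioSentVec title embeddings
BIOSENTVEC_THRESHOLDS = Thresholds(2.3, 4.0, "biosentvec-calibrated")


def _maybe_warn_preset(ec: EmbeddedCorpus, thresholds: Thresholds) -> None:
    if thresholds.provenance == "biosentvec-calibrated" and "biosentvec" not in ec.embedder_tag.lower():
        logger.warning(
            "using BioSentVec-calibrated thresholds (s_rel=%.3g) with embedder %r; recalibrate for this embedder",
            thresholds.s_rel,
            ec.embedder_tag,
        )


def e_min(query: np.ndarray, ids: list[str], vectors: np.ndarray) -> tuple[float, str]:
    """Minimum Euclidean distance from ``query`` to a comparator collection.

    Returns (distance, nearest id); exact ties go to the lexicographically
    smallest id.
    """
    if len(ids) == 0:
        raise ValueError("comparator collection is empty")
    d = np.linalg.norm(np.asarray(vectors, dtype=float) - np.asarray(query, dtype=float), axis=1)
    best = d.min()
    nearest = min(i for i, v in zip(ids, d) if v == best)
    return float(best), nearest


class MinDistanceNovelty(BaseEstimator):
    """Strategy T1 as an outlier-detector-style estimator.

    ``fit`` stores the comparator collection; ``decision_function`` returns
    E-min for each query vector; ``predict`` returns the novelty flags
    (E-min > s_rel, strict by default).
    """

    def __init__(self, s_rel: float = 2.3, strict: bool = True):
        self.s_rel = s_rel
        self.strict = strict

    def fit(self, X, y=None, ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("comparator collection must be a non-empty 2-D array")
        self.comparator_X_ = X
        self.comparator_ids_ = list(ids) if ids is not None else [f"ref{i:06d}" for i in range(len(X))]
        order = np.argsort(np.array(self.comparator_ids_, dtype=object))
        self.comparator_X_ = self.comparator_X_[order]
        self.comparator_ids_ = [self.comparator_ids_[i] for i in order]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "comparator_X_")
        D = pairwise_distances(np.asarray(X, dtype=float), self.comparator_X_, metric="euclidean")
        return D.min(axis=1)

    def nearest(self, X) -> tuple[np.ndarray, list[str]]:
        """E-min and the nearest comparator id for each query row."""
        check_is_fitted(self, "comparator_X_")
        D = pairwise_distances(np.asarray(X, dtype=float), self.comparator_X_, metric="euclidean")
        # ids are sorted at fit time, so argmin's first hit is the smallest id
        idx = D.argmin(axis=1)
        return D[np.arange(len(D)), idx], [self.comparator_ids_[i] for i in idx]

    def kth_distance(self, X, k: int) -> np.ndarray:
        """Distance to the k-th nearest comparator point (NaN if k too large)."""
        check_is_fitted(self, "comparator_X_")
        D = pairwise_distances(np.asarray(X, dtype=float), self.comparator_X_, metric="euclidean")
        if k > D.shape[1]:
            return np.full(len(D), np.nan)
        return np.sort(D, axis=1)[:, k - 1]

    def predict(self, X) -> np.ndarray:
        e = self.decision_function(X)
        return e > self.s_rel if self.strict else e >= self.s_rel


def _comparator_indices(ec: EmbeddedCorpus, window: int, comparator: str) -> np.ndarray:
    if comparator not in COMPARATORS:
        raise ValueError(f"comparator must be one of {COMPARATORS}")
    if comparator == "cumulative_past":
        mask = ec.past_mask(window)
    else:
        mask = ec.window_mask(window - 1) if window > 0 else np.zeros(len(ec.doc_ids), bool)
    if not mask.any():
        raise ValueError(f"empty comparator collection for window {window} ({comparator})")
    return np.flatnonzero(mask)


def t1_novel(
    ec: EmbeddedCorpus,
    window: int,
    comparator: str = "cumulative_past",
    thresholds: Thresholds = BIOSENTVEC_THRESHOLDS,
) -> pd.DataFrame:
    """Strategy T1 report for one window, sorted by E-min descending.

    Columns: doc_id, window, e_min, nearest_past_id, is_novel.
    """
    _maybe_warn_preset(ec, thresholds)
    ref = _comparator_indices(ec, window, comparator)
    cur = np.flatnonzero(ec.window_mask(window))
    det = MinDistanceNovelty(s_rel=thresholds.s_rel).fit(
        ec.vectors[ref], ids=[ec.doc_ids[i] for i in ref]
    )
    emin, nearest = det.nearest(ec.vectors[cur])
    df = pd.DataFrame(
        {
            "doc_id": [ec.doc_ids[i] for i in cur],
            "window": window,
            "e_min": emin,
            "nearest_past_id": nearest,
            "is_novel": emin > thresholds.s_rel,
        }
    )
    return df.sort_values(["e_min", "doc_id"], ascending=[False, True], ignore_index=True)


def most_novel_per_window(
    ec: EmbeddedCorpus, comparator: str = "cumulative_past",
    thresholds: Thresholds = BIOSENTVEC_THRESHOLDS,
) -> pd.DataFrame:
    """For each window after the first, the document farthest (by E-min)
    from all prior documents; ties go to the smallest doc id."""
    if ec.n_windows < 2:
        raise ValueError("need at least 2 windows")
    rows = []
    for w in range(1, ec.n_windows):
        if not ec.window_mask(w).any():
            continue
        rep = t1_novel(ec, w, comparator, thresholds)
        top = rep.iloc[0]
        rows.append({"window": w, "doc_id": top.doc_id, "e_min": float(top.e_min)})
    return pd.DataFrame(rows)


def t2_trend(
    ec: EmbeddedCorpus,
    window: int,
    k: int = 3,
    comparator: str = "cumulative_past",
    thresholds: Thresholds = BIOSENTVEC_THRESHOLDS,
    require_t1: bool = True,
) -> pd.DataFrame:
    """Strategy T2 report: per-document k-neighbourhood densities and trend flags.

    d_k_new is the distance to the k-th nearest same-window neighbour
    (self excluded); d_k_old the distance to the k-th nearest comparator
    document.  is_trend requires the T1 novelty flag (unless
    ``require_t1=False``) and d_k_new < d_k_old.  Documents whose
    neighbourhood is smaller than k get NaN entries rather than aborting.
    """
    t1 = t1_novel(ec, window, comparator, thresholds).set_index("doc_id")
    ref = _comparator_indices(ec, window, comparator)
    cur = np.flatnonzero(ec.window_mask(window))
    cur_ids = [ec.doc_ids[i] for i in cur]
    Xcur = ec.vectors[cur]

    old = MinDistanceNovelty().fit(ec.vectors[ref], ids=[ec.doc_ids[i] for i in ref])
    d_old = old.kth_distance(Xcur, k)

    # within-window k-th neighbour with self excluded
    if len(cur) >= 2:
        D = pairwise_distances(Xcur, Xcur, metric="euclidean")
        np.fill_diagonal(D, np.inf)
        D.sort(axis=1)
        d_new = D[:, k - 1] if k <= len(cur) - 1 else np.full(len(cur), np.nan)
        d_new = np.where(np.isfinite(d_new), d_new, np.nan)
    else:
        d_new = np.full(len(cur), np.nan)

    emin = t1.loc[cur_ids, "e_min"].to_numpy()
    passed_t1 = t1.loc[cur_ids, "is_novel"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d_old / d_new
    defined = np.isfinite(d_new) & np.isfinite(d_old) & (d_new > 0)
    is_trend = defined & (d_new < d_old) & (passed_t1 if require_t1 else True)
    df = pd.DataFrame(
        {
            "doc_id": cur_ids,
            "window": window,
            "e_min": emin,
            "is_novel": passed_t1,
            "d_k_new": d_new,
            "d_k_old": d_old,
            "ratio": ratio,
            "is_trend": is_trend,
            "k": k,
        }
    )
    return df.sort_values(["ratio", "doc_id"], ascending=[False, True], ignore_index=True)


class CentroidTrajectory(BaseEstimator):
    """Strategy Y1: per-window mean vectors and inter-window hop lengths.

    Fitted attributes: ``window_means_`` (DataFrame, one row per non-empty
    window), ``hops_`` (DataFrame with from/to window, hop length in full
    space, and a spans_gap flag where empty windows were skipped), and
    ``projection_2d_`` (PCA of the window means, plotting aid only).
    """

    def fit(self, ec: EmbeddedCorpus, y=None):
        windows, means = [], []
        for w in range(ec.n_windows):
            mask = ec.window_mask(w)
            if not mask.any():
                logger.warning("window %d empty; skipped in trajectory", w)
                continue
            windows.append(w)
            means.append(ec.vectors[mask].mean(axis=0))
        if len(windows) < 2:
            raise ValueError("need at least 2 non-empty windows")
        M = np.vstack(means)
        self.window_means_ = pd.DataFrame(M, index=pd.Index(windows, name="window"))
        hops = []
        for a, b in zip(windows[:-1], windows[1:]):
            hops.append(
                {
                    "from_window": a,
                    "to_window": b,
                    "hop_length": float(
                        np.linalg.norm(
                            self.window_means_.loc[b].to_numpy() - self.window_means_.loc[a].to_numpy()
                        )
                    ),
                    "spans_gap": b - a > 1,
                }
            )
        self.hops_ = pd.DataFrame(hops)
        n_comp = min(2, M.shape[0], M.shape[1])
        proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(M)
        if n_comp < 2:
            proj = np.hstack([proj, np.zeros((len(proj), 2 - n_comp))])
        self.projection_2d_ = pd.DataFrame(proj, index=self.window_means_.index, columns=["pc1", "pc2"])
        return self


def y1_trajectory(ec: EmbeddedCorpus) -> CentroidTrajectory:
    """Fit strategy Y1 on an embedded corpus."""
    return CentroidTrajectory().fit(ec)


def y2_proportions(
    ec: EmbeddedCorpus,
    thresholds: Thresholds = BIOSENTVEC_THRESHOLDS,
    strict: bool = True,
) -> pd.DataFrame:
    """Strategy Y2: per window (after the first), the proportion of its
    documents whose E-min against the cumulative past exceeds s_rel.

    Columns: window, novel, total, proportion.
    """
    _maybe_warn_preset(ec, thresholds)
    if ec.n_windows < 2:
        raise ValueError("need at least 2 windows")
    rows = []
    for w in range(1, ec.n_windows):
        cur = np.flatnonzero(ec.window_mask(w))
        if len(cur) == 0:
            continue
        past = _comparator_indices(ec, w, "cumulative_past")
        det = MinDistanceNovelty(s_rel=thresholds.s_rel, strict=strict).fit(ec.vectors[past])
        flags = det.predict(ec.vectors[cur])
        rows.append(
            {"window": w, "novel": int(flags.sum()), "total": len(cur), "proportion": flags.mean()}
        )
    return pd.DataFrame(rows)


def calibrate_thresholds(
    distances,
    labels=None,
    fdr: float = 0.01,
    quantiles: tuple[float, float] = (0.05, 0.5),
) -> dict:
    """Derive candidate (s_rel, s_unrel) from pairwise title distances.

    Labeled mode (labels: 1 = related, 0 = unrelated): s_rel is the largest
    distance at which the false-discovery rate among pairs at or below it
    (fraction unrelated) stays under ``fdr``; s_unrel the smallest distance
    above which fewer than ``fdr`` of pairs are related.  Unlabeled mode
    returns distance quantiles as candidates and flags them as requiring
    human review; unlabeled calibration is never auto-applied.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 100:
        raise ValueError("need at least 100 pairwise distances to calibrate")
    if labels is None:
        cands = np.quantile(d, quantiles)
        return {
            "s_rel": float(cands[0]),
            "s_unrel": float(max(cands[1], np.nextafter(cands[0], np.inf))),
            "mode": "unlabeled-quantiles",
            "requires_review": True,
            "quantiles": list(quantiles),
        }
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("labeled calibration needs both related and unrelated pairs")
    order = np.argsort(d, kind="stable")
    d_sorted, y_sorted = d[order], y[order]
    # FDR below each cut: fraction of unrelated among pairs <= d_i
    n_below = np.arange(1, len(d) + 1)
    fdr_below = np.cumsum(1 - y_sorted) / n_below
    # cut points sit on related-pair distances: the threshold certifies
    # relatedness up to a distance actually observed for a related pair
    ok = np.flatnonzero((fdr_below < fdr) & (y_sorted == 1))
    if len(ok) == 0:
        raise ValueError("no threshold achieves the requested FDR")
    i = ok.max()
    # place the threshold between the last certified related pair and the
    # next observed distance, so it covers the separating gap
    s_rel = float(d_sorted[i] if i + 1 == len(d) else 0.5 * (d_sorted[i] + d_sorted[i + 1]))
    # related fraction strictly above each cut
    n_above = len(d) - n_below
    rel_above = (np.cumsum(y_sorted[::-1])[::-1] - y_sorted) / np.maximum(n_above, 1)
    ok_hi = np.flatnonzero((rel_above < fdr) & (n_above > 0) & (y_sorted == 0))
    if len(ok_hi):
        j = ok_hi.min()
        s_unrel = float(d_sorted[j] if j == 0 else 0.5 * (d_sorted[j - 1] + d_sorted[j]))
    else:
        s_unrel = float(d_sorted[-1])
    if s_unrel <= s_rel:
        s_unrel = float(np.nextafter(s_rel, np.inf))
    return {
        "s_rel": s_rel,
        "s_unrel": s_unrel,
        "mode": "labeled-fdr",
        "requires_review": False,
        "fdr": fdr,
        "fdr_at_s_rel": float(fdr_below[ok.max()]),
    }


class TrendDetector(BaseEstimator):
    """Strategy T2 as an estimator: ``fit`` computes per-window trend
    reports (``reports_``, window index -> DataFrame)."""

    def __init__(self, k: int = 3, s_rel: float = 2.3, s_unrel: float = 4.0,
                 comparator: str = "cumulative_past", require_t1: bool = True):
        self.k = k
        self.s_rel = s_rel
        self.s_unrel = s_unrel
        self.comparator = comparator
        self.require_t1 = require_t1

    def fit(self, ec: EmbeddedCorpus, y=None):
        th = Thresholds(self.s_rel, self.s_unrel, "user")
        self.reports_ = {}
        for w in range(1, ec.n_windows):
            if not ec.window_mask(w).any():
                continue
            self.reports_[w] = t2_trend(
                ec, w, k=self.k, comparator=self.comparator,
                thresholds=th, require_t1=self.require_t1,
            )
        return self


class NovelProportion(BaseEstimator):
    """Strategy Y2 as an estimator: ``fit`` computes ``proportions_``."""

    def __init__(self, s_rel: float = 2.3, strict: bool = True):
        self.s_rel = s_rel
        self.strict = strict

    def fit(self, ec: EmbeddedCorpus, y=None):
        th = Thresholds(self.s_rel, max(self.s_rel * 2, self.s_rel + 1), "user")
        self.proportions_ = y2_proportions(ec, th, strict=self.strict)
        return self
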