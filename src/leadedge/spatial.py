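"""Per-ROI spatial statistics: nearest-distance maps, neighborhood windows,
composition clustering, and neighbor fractions.

Each ROI is an isolated coordinate frame (a separate acquisition); no
distance ever crosses ROIs.  The neighborhood window of a cell is the cell
itself plus its k-1 nearest same-ROI neighbors by Euclidean distance
(default k = 26, i.e. 25 neighbors), with distance ties broken by ascending
cell_id so results are deterministic.  Window composition vectors (fractions
over labels, center included) are the substrate for k-means neighborhood
clustering; neighbor fractions pool the 25 non-center members only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodWindows:
    """Per-cell neighbor index lists (positional into the source table).

    ``neighbors[i]`` holds the ordered positional indices of cell i's
    nearest same-ROI neighbors (length ``min(k - 1, n_roi - 1)``); the
    center is not in its own list but belongs to its own window.
    """

    k: int
    neighbors: list[np.ndarray]
    cell_ids: pd.Index


@dataclass
class NeighborhoodModel:
    """k-means clustering of window composition vectors."""

    n_clusters: int
    centroids: np.ndarray
    assignments: np.ndarray
    labels: list[str]
    seed: int


def _check_label(t: pd.DataFrame, field: str, label: str) -> None:
    if field not in t.columns:
        raise ValidationError(f"label field '{field}' absent from table")
    if label not in set(t[field]):
        raise ValidationError(f"label '{label}' not present in '{field}'")


def closest_distance_map(
    t: pd.DataFrame, target_label: str, target_field: str = "cell_type"
) -> pd.Series:
    """Distance from every cell to the nearest target-labeled cell.

    Computed within each ROI with the cell itself excluded; NaN where the
    ROI has no target cells (or no *other* target cell, for cells of the
    target label).
    """
    _check_label(t, target_field, target_label)
    out = np.full(len(t), np.nan)
    for _, idx in t.groupby("roi_id").indices.items():
        sub = t.iloc[idx]
        is_target = (sub[target_field] == target_label).to_numpy()
        targets = sub.loc[is_target, ["x", "y"]].to_numpy(dtype=float)
        if len(targets) == 0:
            continue
        tree = cKDTree(targets)
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        # nearest two targets: the first may be the query cell itself
        dist, nbr = tree.query(xy, k=min(2, len(targets)))
        dist = np.atleast_2d(dist.T).T
        if len(targets) == 1:
            d = dist[:, 0].copy()
            d[is_target] = np.nan  # the sole target's nearest is itself
        else:
            target_pos = np.flatnonzero(is_target)
            self_rank = np.zeros(len(sub), dtype=int)
            self_rank[target_pos] = 1  # skip self-match for target cells
            d = dist[np.arange(len(sub)), self_rank]
        out[idx] = d
    return pd.Series(out, index=t.index, name=f"dist_to_{target_label}")


def roi_mean_distances(
    t: pd.DataFrame,
    source_field: str = "cell_type",
    target_field: str = "cell_type",
) -> pd.DataFrame:
    """Per-ROI mean closest distance for every ordered (source, target) pair.

    A (roi, source, target) row is present only when the ROI holds at least
    one source cell and the distance is defined (>= 1 target cell, excluding
    the source cell itself when the labels coincide).
    """
    for f in {source_field, target_field}:
        if f not in t.columns:
            raise ValidationError(f"label field '{f}' absent from table")
    rows = []
    target_labels = sorted(set(t[target_field]))
    for target in target_labels:
        dist = closest_distance_map(t, target, target_field=target_field)
        frame = pd.DataFrame(
            {
                "roi_id": t["roi_id"].to_numpy(),
                "source": t[source_field].to_numpy(),
                "dist": dist.to_numpy(),
            }
        )
        grouped = frame.groupby(["roi_id", "source"], sort=True)["dist"]
        agg = grouped.agg(["mean", "count", "size"]).reset_index()
        for _, r in agg.iterrows():
            if r["count"] == 0:  # distance undefined in this ROI
                continue
            rows.append(
                {
                    "roi_id": r["roi_id"],
                    "source": r["source"],
                    "target": target,
                    "mean_distance": float(r["mean"]),
                    "n_source": int(r["size"]),
                }
            )
    return pd.DataFrame(rows)


def knn_windows(t: pd.DataFrame, k: int = 26) -> NeighborhoodWindows:
    """The k-1 nearest same-ROI neighbors of every cell.

    Distance ties at the window edge are broken by ascending ``cell_id``.
    ROIs with fewer than k cells yield truncated windows with a warning.
    """
    if k < 2:
        raise ConfigError("window size k must be >= 2")
    neighbors: list[np.ndarray | None] = [None] * len(t)
    for roi, idx in t.groupby("roi_id").indices.items():
        sub = t.iloc[idx]
        n = len(sub)
        if n < k:
            logger.warning(
                "ROI '%s' has %d cells < window size %d; windows truncated",
                roi, n, k,
            )
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        m = min(k - 1, n - 1)
        tree = cKDTree(xy)
        # query extra candidates so boundary ties can be re-ordered by id
        n_query = min(n, k + 4)
        dist, nbr = tree.query(xy, k=n_query)
        dist = np.atleast_2d(dist)
        nbr = np.atleast_2d(nbr)
        for row in range(n):
            d, cand = dist[row], nbr[row]
            keep = cand != row
            d, cand = d[keep], cand[keep]
            if m > 0 and len(d) > m and np.isclose(d[m - 1], d[m]):
                # tie spans the cutoff: fall back to the full candidate list
                d = np.hypot(*(xy - xy[row]).T)
                cand = np.arange(n)
                keep = cand != row
                d, cand = d[keep], cand[keep]
            order = np.lexsort((ids[cand], d))
            chosen = cand[order[:m]]
            neighbors[idx[row]] = idx[chosen]
    return NeighborhoodWindows(
        k=k,
        neighbors=[np.asarray(nb, dtype=int) for nb in neighbors],
        cell_ids=pd.Index(t["cell_id"]),
    )


def window_composition(
    w: NeighborhoodWindows, t: pd.DataFrame, label_field: str = "cell_type"
) -> pd.DataFrame:
    """Fraction of each label within every window (center included)."""
    if label_field not in t.columns:
        raise ValidationError(f"label field '{label_field}' absent from table")
    labels = t[label_field].to_numpy()
    if pd.isna(labels).any():
        raise ValidationError(f"unset labels in '{label_field}'")
    categories = sorted(set(labels))
    cat_index = {c: i for i, c in enumerate(categories)}
    codes = np.array([cat_index[v] for v in labels])
    comp = np.zeros((len(t), len(categories)))
    for i, nb in enumerate(w.neighbors):
        members = np.append(nb, i)
        counts = np.bincount(codes[members], minlength=len(categories))
        comp[i] = counts / len(members)
    return pd.DataFrame(comp, columns=categories, index=t.index)


def cluster_neighborhoods(
    comp: pd.DataFrame, n_clusters: int, seed: int = 0
) -> NeighborhoodModel:
    """k-means over composition rows (10 restarts, best inertia kept)."""
    if n_clusters < 2:
        raise ConfigError("n_clusters must be >= 2")
    if n_clusters > len(comp):
        raise ConfigError("n_clusters exceeds the number of cells")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assignments = km.fit_predict(comp.to_numpy()) + 1  # clusters 1..K
    return NeighborhoodModel(
        n_clusters=n_clusters,
        centroids=km.cluster_centers_,
        assignments=assignments,
        labels=list(comp.columns),
        seed=seed,
    )


def neighbor_fraction(
    w: NeighborhoodWindows,
    t: pd.DataFrame,
    source_subtype: str,
    target_type: str,
    source_field: str = "fb_subtype",
    target_field: str = "cell_type",
) -> float:
    """Pooled share of target-type cells among source cells' neighbors.

    Counts only the non-center window members of every source cell, pooled
    across ROIs; NaN when there are no source cells.
    """
    for f in {source_field, target_field}:
        if f not in t.columns:
            raise ValidationError(f"label field '{f}' absent from table")
    sources = np.flatnonzero((t[source_field] == source_subtype).to_numpy())
    if len(sources) == 0:
        return float("nan")
    target = (t[target_field] == target_type).to_numpy()
    hits = 0
    total = 0
    for i in sources:
        nb = w.neighbors[i]
        hits += int(target[nb].sum())
        total += len(nb)
    return hits / total if total else float("nan")
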