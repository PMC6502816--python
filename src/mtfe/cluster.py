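"""Hierarchical clustering of samples and partition-agreement scoring.

Samples (columns) are clustered agglomeratively on Manhattan distances of the
row-scaled matrix.  The agglomeration is implemented here rather than taken
from scipy so that ties in the merge order are broken deterministically (the
pair whose sorted member ids are lexicographically smallest merges first) and
missing entries can use pairwise-complete distances rescaled by the shared
coordinate count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_core import InputError


@dataclass
class ClusteringResult:
    """Merge table (scipy-style), leaf order and the settings used."""

    merges: np.ndarray  # (n-1, 4): idx_a, idx_b, height, size
    leaf_order: list[str]
    sample_ids: list[str]
    metric: str = "manhattan"
    linkage: str = "complete"
    row_scaled: bool = True
    constant_rows: list[str] | None = None

    def labels_at_k(self, k: int) -> dict[str, int]:
        """Flat cluster labels obtained by undoing the last k-1 merges."""
        n = len(self.sample_ids)
        if not 1 <= k <= n:
            raise InputError(f"k must be in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for step in range(n - k):
            a, b = int(self.merges[step, 0]), int(self.merges[step, 1])
            node = n + step
            parent[find(a)] = node
            parent[find(b)] = node
        roots: dict[int, int] = {}
        out = {}
        for i, s in enumerate(self.sample_ids):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            out[s] = roots[r]
        return out


def scale_rows(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center each row to mean 0 and scale to sample sd 1 (missing-aware).

    Constant rows map to all-zeros and are returned in the flag list.
    """
    X = frame.to_numpy(dtype=float)
    n = np.sum(~np.isnan(X), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(X, axis=1, keepdims=True)
        centered = X - mean
        ss = np.nansum(centered**2, axis=1)
    sd = np.full(X.shape[0], np.nan)
    ok = n >= 2
    sd[ok] = np.sqrt(ss[ok] / (n[ok] - 1))
    constant = ok & (sd == 0)
    sd_safe = np.where(constant | ~ok, 1.0, sd)
    scaled = centered / sd_safe[:, None]
    scaled[constant] = np.where(np.isnan(X[constant]), np.nan, 0.0)
    flagged = [str(frame.index[i]) for i in np.flatnonzero(constant)]
    return pd.DataFrame(scaled, index=frame.index, columns=frame.columns), flagged


def manhattan_distances(frame: pd.DataFrame) -> np.ndarray:
    """Pairwise Manhattan distances between columns, pairwise-complete.

    With missing entries, the sum of absolute differences over shared
    coordinates is rescaled by (total rows / shared rows).  A column pair
    sharing no coordinates is an error.
    """
    X = frame.to_numpy(dtype=float)
    P, n = X.shape
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[:, i] & obs[:, j]
            shared = int(both.sum())
            if shared == 0:
                raise InputError(
                    f"columns {frame.columns[i]!r} and {frame.columns[j]!r} share no observations"
                )
            d = np.sum(np.abs(X[both, i] - X[both, j]))
            D[i, j] = D[j, i] = d * (P / shared)
    return D


def hclust_manhattan(
    matrix,
    linkage: str = "complete",
    scale: bool = True,
) -> ClusteringResult:
    """Agglomerative clustering of samples on Manhattan distance.

    Rows are z-scaled first (unless ``scale=False``).  At equal merge
    distances the pair whose sorted member-id tuple is lexicographically
    smallest merges first, making results reproducible across platforms.
    """
    frame = matrix.to_frame() if hasattr(matrix, "to_frame") else pd.DataFrame(matrix)
    n = frame.shape[1]
    if n < 2:
        raise InputError("clustering needs at least two samples")
    if linkage not in {"complete", "single", "average"}:
        raise InputError(f"unsupported linkage {linkage!r}")
    constant_rows: list[str] = []
    if scale:
        frame, constant_rows = scale_rows(frame)
    D = manhattan_distances(frame)
    sample_ids = [str(c) for c in frame.columns]
    # active cluster bookkeeping: node id, member ids (sorted), size
    active: dict[int, dict] = {
        i: {"members": (sample_ids[i],), "size": 1} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    merges = np.zeros((n - 1, 4))
    next_id = n
    leaf_children: dict[int, tuple[int, int]] = {}
    for step in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            key = (d, tuple(sorted(active[i]["members"] + active[j]["members"])))
            if best is None or key < best[0]:
                best = (key, (i, j))
        (d_best, _), (a, b) = best
        merges[step] = [a, b, d_best, active[a]["size"] + active[b]["size"]]
        leaf_children[next_id] = (a, b)
        new = {
            "members": tuple(sorted(active[a]["members"] + active[b]["members"])),
            "size": active[a]["size"] + active[b]["size"],
        }
        for other in list(active):
            if other in (a, b):
                continue
            da = dist[tuple(sorted((a, other)))]
            db = dist[tuple(sorted((b, other)))]
            if linkage == "complete":
                dn = max(da, db)
            elif linkage == "single":
                dn = min(da, db)
            else:  # average (UPGMA)
                sa, sb = active[a]["size"], active[b]["size"]
                dn = (sa * da + sb * db) / (sa + sb)
            dist[tuple(sorted((next_id, other)))] = dn
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del active[a], active[b]
        active[next_id] = new
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = leaf_children[node]
        return leaves(a) + leaves(b)

    leaf_order = [sample_ids[i] for i in leaves(2 * n - 2)] if n > 1 else sample_ids
    return ClusteringResult(
        merges=merges,
        leaf_order=leaf_order,
        sample_ids=sample_ids,
        linkage=linkage,
        row_scaled=scale,
        constant_rows=constant_rows,
    )


def partition_agreement(
    result: ClusteringResult, k: int, labels: dict[str, object]
) -> tuple[float, dict[int, float]]:
    """Cut the tree at k clusters; return ARI against labels + per-cluster purity."""
    n = len(result.sample_ids)
    if not 2 <= k <= n:
        raise InputError(f"k must be in [2, {n}], got {k}")
    assignment = result.labels_at_k(k)
    samples = result.sample_ids
    pred = [assignment[s] for s in samples]
    truth = [labels[s] for s in samples]
    ari = float(adjusted_rand_score(truth, pred))
    purity: dict[int, float] = {}
    frame = pd.DataFrame({"cluster": pred, "label": truth})
    for c, grp in frame.groupby("cluster"):
        purity[int(c)] = float(grp["label"].value_counts().iloc[0] / len(grp))
    return ari, purity
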