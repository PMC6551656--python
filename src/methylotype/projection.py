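"""PCA with reference projection, complete-linkage clustering, FAB tables.

The central trick is *reference-basis projection*: fit a PCA on reference
methylomes (e.g. sorted hematopoietic differentiation stages), then project
query cohort samples onto the reference basis vectors, so each query lands
in the coordinate system spanned by normal differentiation rather than by
its own cohort variance. Hierarchical clustering uses euclidean distances
with complete linkage and a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAModel",
    "pca_fit",
    "pca_project",
    "Dendrogram",
    "hclust_complete",
    "cut_tree",
    "fab_distribution",
    "cross_cluster",
]

FAB_CLASSES = tuple(f"M{i}" for i in range(8))


@dataclass
class PCAModel:
    """A fitted PCA basis for projecting new samples.

    ``center`` (and optionally ``scale``) are per-probe statistics of the
    fitting matrix; ``basis`` holds orthonormal loading vectors as rows
    (components x probes), each oriented so its largest-magnitude element
    is positive; ``explained`` is the fraction of variance per component.
    """

    probe_ids: pd.Index
    center: np.ndarray
    scale: np.ndarray | None
    basis: np.ndarray
    explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]


def pca_fit(
    x: pd.DataFrame, scale_unit: bool = False, n_components: int | None = None
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit a PCA on a samples x probes matrix; returns (model, scores).

    Probes with any missing value are dropped (reported via a warning);
    under unit scaling, zero-variance probes are dropped too. Computed by
    singular value decomposition of the per-probe-centered (and optionally
    unit-variance-scaled) matrix. With all components kept, the scores and
    basis reconstruct the input exactly.
    """
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    keep = x.notna().all(axis=0)
    if not keep.all():
        import warnings

        warnings.warn(f"{(~keep).sum()} probes with missing values dropped from PCA")
        x = x.loc[:, keep]

    vals = x.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    centered = vals - center
    scale = None
    if scale_unit:
        sd = centered.std(axis=0, ddof=1)
        ok = sd > 0
        if not ok.all():
            import warnings

            warnings.warn(f"{(~ok).sum()} zero-variance probes dropped under unit scaling")
            x = x.loc[:, x.columns[ok]]
            centered = centered[:, ok]
            center = center[ok]
            sd = sd[ok]
        scale = sd
        centered = centered / scale

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(x.shape[0] - 1, vt.shape[0]) if n_components is None else n_components
    u, s, vt = u[:, :k], s[:k], vt[:k]

    # deterministic sign: largest-|.| loading of each component positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    var = s**2
    total = (centered**2).sum()
    explained = var / total if total > 0 else np.zeros_like(var)

    model = PCAModel(
        probe_ids=x.columns.copy(), center=center, scale=scale, basis=vt, explained=explained
    )
    scores = pd.DataFrame(
        u * s, index=x.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return model, scores


def pca_project(model: PCAModel, q: pd.DataFrame) -> pd.DataFrame:
    """Project query samples (samples x probes) onto a fitted basis.

    The query must cover the model's probe set (by id; column order is
    irrelevant). Scores are ``(q - center) [/ scale] @ basis.T`` — the same
    transform the fitting samples received, so projecting the training
    data reproduces its fitted scores.
    """
    missing = model.probe_ids.difference(q.columns)
    if len(missing):
        raise KeyError(
            f"query lacks {len(missing)} model probes, e.g. {list(missing[:3])}"
        )
    vals = q[model.probe_ids].to_numpy(dtype=float)
    centered = vals - model.center
    if model.scale is not None:
        centered = centered / model.scale
    scores = centered @ model.basis.T
    return pd.DataFrame(
        scores, index=q.index, columns=[f"PC{i + 1}" for i in range(model.n_components)]
    )


@dataclass
class Dendrogram:
    """Agglomerative merge history over n items.

    ``merges`` has n-1 rows (left, right, height, size): cluster ids < n
    are leaves, id n + k is the cluster created at step k (the scipy
    linkage convention). Heights are nondecreasing under complete linkage.
    """

    items: list
    merges: np.ndarray  # (n-1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list:
        """Left-to-right leaf order of the tree."""
        n = len(self.items)

        def walk(node: int) -> list:
            if node < n:
                return [node]
            left, right = int(self.merges[node - n, 0]), int(self.merges[node - n, 1])
            return walk(left) + walk(right)

        return [self.items[i] for i in walk(2 * n - 2)] if n > 1 else list(self.items)

    def to_json_dict(self) -> dict:
        return {
            "items": [str(i) for i in self.items],
            "merges": [[int(a), int(b), float(h), int(s)] for a, b, h, s in self.merges],
        }


def hclust_complete(x: pd.DataFrame) -> Dendrogram:
    """Euclidean complete-linkage agglomerative clustering of the rows.

    At every step the pair of clusters with the smallest maximum pairwise
    distance is merged; ties are broken by the smallest (lexicographic)
    pair of cluster ids, which makes the merge history deterministic.
    NaN features are rejected.
    """
    vals = x.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN features are not allowed in clustering")
    n = len(vals)
    if n < 2:
        raise ValueError("need at least two items")

    sq = (vals**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (vals @ vals.T), 0.0)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.sqrt(d2[i, j]))

    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                d = dist[key]
                if best is None or d < best[0] or (d == best[0] and key < best[1]):
                    best = (d, key)
        d, (i, j) = best
        new = next_id
        next_id += 1
        # complete linkage: distance to the union is the max of the parts
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(new, k), max(new, k))] = max(dik, djk)
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = sizes[i] + sizes[j]
        merges[step] = (i, j, d, sizes[new])
    return Dendrogram(items=list(x.index), merges=merges)


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Flat cluster labels obtained by undoing the last k-1 merges."""
    n = len(dendrogram.items)
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of items")
    parent = {}
    for step in range(n - 1 - (k - 1)):
        a, b = int(dendrogram.merges[step, 0]), int(dendrogram.merges[step, 1])
        parent[a] = n + step
        parent[b] = n + step

    def root(node: int) -> int:
        while node in parent:
            node = parent[node]
        return node

    roots = {}
    labels = []
    for i in range(n):
        r = root(i)
        labels.append(roots.setdefault(r, len(roots)))
    return pd.Series(labels, index=dendrogram.items, name="cluster")


def fab_distribution(sheet: pd.DataFrame, group_by: str = "idh_status") -> pd.DataFrame:
    """Per-group FAB class proportion table.

    Proportions are over samples with a known FAB class; NA-labelled
    samples are excluded from the denominator and reported in an ``n_na``
    column alongside per-class counts.
    """
    known = sheet["fab_class"].isin(FAB_CLASSES)
    rows = []
    for group, sub in sheet.groupby(group_by, sort=True):
        counts = sub.loc[known.loc[sub.index], "fab_class"].value_counts()
        total = int(counts.sum())
        row = {"group": group, "n": total, "n_na": int(len(sub) - total)}
        for fab in FAB_CLASSES:
            c = int(counts.get(fab, 0))
            row[f"count_{fab}"] = c
            row[f"prop_{fab}"] = c / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def cross_cluster(
    reference: pd.DataFrame,
    query: pd.DataFrame,
    probe_ids,
    stage_labels=None,
) -> dict:
    """Cluster one dataset on probes selected from another's contrast.

    ``reference`` is probes x samples; ``probe_ids`` is the probe
    selection (e.g. the top differentially methylated probes of the query
    cohort's mutant contrast). Returns the complete-linkage dendrogram of
    the reference samples on those probes and, when ``stage_labels`` maps
    sample -> known stage, the mean silhouette of the stages as a
    separation score.
    """
    ids = pd.Index(probe_ids)
    ids = ids.intersection(reference.index)
    if len(ids) < 2:
        raise ValueError("probe selector yields fewer than two usable probes")
    mat = reference.loc[ids].T  # samples x probes
    dend = hclust_complete(mat)
    out = {"dendrogram": dend, "n_probes": int(len(ids))}
    if stage_labels is not None:
        from sklearn.metrics import silhouette_score

        labels = pd.Series(stage_labels).loc[mat.index]
        if labels.nunique() >= 2:
            out["silhouette"] = float(
                silhouette_score(mat.to_numpy(), labels.to_numpy(), metric="euclidean")
            )
        else:
            out["silhouette"] = np.nan
    return out
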