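"""Unsupervised sleep-phenotype landscape: embed, cluster, divide, regroup.

Subjects' 21 standardized indexes are embedded into 3-D (UMAP by default) and
density-clustered with DBSCAN.  The process is applied divisively: each
accepted cluster is re-standardized, re-embedded and re-clustered, a split
being accepted only when it yields at least two children of size >= 20, down
to a maximum depth of three rounds.  The resulting leaves are then regrouped
by Ward's hierarchical method on their mean z-profiles, constrained within
each first-layer cluster so the top-level relationships survive.  A separate
branch isolates subjects extreme (outside the central 95.44%, i.e. beyond
the 2.28th percentiles) in any of six designated indexes and re-clusters
just those.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default six indexes screened for percentile outliers.
DEFAULT_OUTLIER_INDEXES = [
    "wt_long_mn",
    "st_long_sd",
    "st_short_mn",
    "sleep_percentage_mn",
    "phase_mn",
    "period",
]


@dataclass
class ZMatrix:
    """Column-standardized index table with stored means/SDs for inversion."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def inverse(self) -> pd.DataFrame:
        return self.values * self.sds + self.means


def zscore(table: pd.DataFrame) -> ZMatrix:
    """Standardize each column to mean 0, SD 1 (sample SD, n-1 denominator).

    Zero-variance columns are set to 0 with a warning rather than dropped, so
    the column registry stays aligned with the index table.
    """
    if len(table) < 2:
        raise ValueError("need at least two subjects")
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite entries in the index table")
    means = table.mean()
    sds = table.std(ddof=1)
    zero = sds == 0
    if zero.any():
        warnings.warn(f"zero-variance columns set to 0: {list(table.columns[zero])}")
    safe = sds.replace(0, 1.0)
    z = (table - means) / safe
    z.loc[:, zero] = 0.0
    return ZMatrix(z, means, sds)


def embed(
    Z: ZMatrix | pd.DataFrame,
    method: str = "umap",
    out_dim: int = 3,
    seed: int = 0,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
    **kwargs,
) -> np.ndarray:
    """Reduce the standardized table to ``out_dim`` dimensions.

    Methods: ``pca`` | ``tsne`` | ``umap`` | ``pca+umap``; UMAP is the
    default as it gives the most interpretable density structure.  All
    methods are deterministic for a fixed seed.
    """
    X = (Z.values if isinstance(Z, ZMatrix) else Z).to_numpy(dtype=float)
    n = X.shape[0]
    if n < out_dim + 1:
        raise ValueError("need more subjects than embedding dimensions")
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=out_dim, random_state=seed).fit_transform(X)
    if method == "tsne":
        from sklearn.manifold import TSNE

        return TSNE(n_components=out_dim, random_state=seed, init="pca", **kwargs).fit_transform(X)
    if method in ("umap", "pca+umap"):
        import umap

        if method == "pca+umap":
            from sklearn.decomposition import PCA

            X = PCA(n_components=min(10, X.shape[1]), random_state=seed).fit_transform(X)
        reducer = umap.UMAP(
            n_components=out_dim,
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=seed,
            **kwargs,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*n_jobs value 1.*")
            warnings.filterwarnings("ignore", message=".*n_neighbors is larger.*")
            return reducer.fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


def auto_eps(embedding: np.ndarray, min_samples: int = 20, scale: float = 1.5) -> float:
    """DBSCAN radius from the k-distance heuristic.

    ``scale`` times the median distance to the ``min_samples``-th nearest
    neighbour: dense regions stay connected while gaps many times larger than
    the typical within-cluster spacing still separate clusters.
    """
    from sklearn.neighbors import NearestNeighbors

    k = min(min_samples, len(embedding) - 1)
    dists, _ = NearestNeighbors(n_neighbors=k + 1).fit(embedding).kneighbors(embedding)
    med = float(np.median(dists[:, -1]))
    return scale * med if med > 0 else 1e-12


def density_cluster(
    embedding: np.ndarray, eps: float | str = "auto", min_samples: int = 20
) -> np.ndarray:
    """DBSCAN labels on the embedding; noise points get label -1.

    ``eps="auto"`` uses the k-distance heuristic of :func:`auto_eps`, the
    standard way of reading the radius off the data when no calibrated value
    is available.
    """
    from sklearn.cluster import DBSCAN

    if eps == "auto":
        eps = auto_eps(embedding, min_samples)
    if not eps > 0:
        raise ValueError("eps must be positive")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(embedding)


@dataclass
class ClusterNode:
    """One node of the divisive hierarchy."""

    members: np.ndarray  # positional indices into the table
    depth: int
    node_id: str
    children: list["ClusterNode"] = field(default_factory=list)
    noise: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Divisive hierarchy; leaves carry the final sub-cluster labels."""

    root: ClusterNode
    index: pd.Index  # subject ids, aligned to positions

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def labels(self) -> pd.Series:
        """Leaf label per subject; noise dropped at any level gets -1."""
        lab = np.full(len(self.index), -1, dtype=object)
        for i, leaf in enumerate(self.leaves()):
            lab[leaf.members] = leaf.node_id
        return pd.Series(lab, index=self.index, name="cluster")

    def first_layer(self) -> list[ClusterNode]:
        return self.root.children if self.root.children else [self.root]

    def to_dict(self) -> dict:
        def conv(node: ClusterNode) -> dict:
            return {
                "id": node.node_id,
                "depth": node.depth,
                "members": [str(self.index[i]) for i in node.members],
                "noise": [str(self.index[i]) for i in node.noise],
                "children": [conv(c) for c in node.children],
            }

        return conv(self.root)


def divisive_cluster(
    table: pd.DataFrame,
    max_depth: int = 3,
    min_child_size: int = 20,
    seed: int = 0,
    method: str = "umap",
    eps: float | str = "auto",
    min_samples: int = 20,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
) -> ClusterTree:
    """Repeated standardize -> embed -> DBSCAN, divisively.

    At each node the member rows are re-standardized, embedded and density
    clustered.  A split is accepted only when at least two resulting clusters
    have ``min_child_size`` or more members; clusters below that size are
    folded into the largest accepted sibling (keeping the partition property)
    and DBSCAN noise is recorded on the node and excluded from its children.
    """
    if len(table) < 2 * min_child_size:
        raise ValueError("table smaller than two minimal children")
    root = ClusterNode(members=np.arange(len(table)), depth=0, node_id="root")

    def split(node: ClusterNode) -> None:
        if node.depth >= max_depth or node.members.size < 2 * min_child_size:
            return
        sub = table.iloc[node.members]
        with warnings.catch_warnings():
            # constant columns are expected once a node is nearly pure
            warnings.filterwarnings("ignore", message="zero-variance columns")
            Z = zscore(sub)
        emb = embed(Z, method=method, seed=seed, n_neighbors=n_neighbors, min_dist=min_dist)
        labels = density_cluster(emb, eps=eps, min_samples=min_samples)
        uniq = [u for u in np.unique(labels) if u != -1]
        groups = {u: node.members[labels == u] for u in uniq}
        accepted = [u for u in uniq if groups[u].size >= min_child_size]
        if len(accepted) < 2:
            return
        largest = max(accepted, key=lambda u: groups[u].size)
        for u in uniq:
            if u not in accepted:
                groups[largest] = np.concatenate([groups[largest], groups[u]])
        node.noise = node.members[labels == -1]
        for j, u in enumerate(accepted):
            child = ClusterNode(
                members=np.sort(groups[u]),
                depth=node.depth + 1,
                node_id=f"{node.node_id}.{j}" if node.node_id != "root" else str(j + 1),
            )
            node.children.append(child)
            split(child)

    split(root)
    return ClusterTree(root, table.index)


def ward_regroup(
    tree: ClusterTree,
    Z: ZMatrix,
    n_groups: int | dict[str, int] = 2,
) -> pd.Series:
    """Ward-regroup the tree's leaves within each first-layer cluster.

    Leaf clusters are represented by their mean z-profiles and agglomerated
    with Ward linkage; the dendrogram is cut at ``n_groups`` groups per
    first-layer cluster (capped at the available leaf count).  Labels are
    hierarchical: first-layer clusters are numbered by size (``1`` largest)
    and subgroups suffixed ``a``, ``b``, ...; leaves from different
    first-layer clusters are never merged.  Noise keeps label ``noise``.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    zvals = Z.values.to_numpy(dtype=float)
    first = sorted(tree.first_layer(), key=lambda nd: -nd.members.size)
    labels = pd.Series("noise", index=tree.index, name="cluster", dtype=object)
    for rank, top in enumerate(first, start=1):
        leaves = [lf for lf in tree.leaves() if _descends(top, lf)]
        k = n_groups[top.node_id] if isinstance(n_groups, dict) else n_groups
        if k > len(leaves):
            raise ValueError(f"requested {k} groups but cluster {top.node_id} has {len(leaves)} leaves")
        if len(leaves) == 1 or k == 1:
            groups = np.ones(len(leaves), dtype=int)
        else:
            profiles = np.vstack([zvals[lf.members].mean(axis=0) for lf in leaves])
            link = linkage(profiles, method="ward")
            groups = fcluster(link, t=k, criterion="maxclust")
        n_sub = groups.max()
        for leaf, g in zip(leaves, groups):
            name = str(rank) if n_sub == 1 else f"{rank}{chr(ord('a') + g - 1)}"
            labels.iloc[leaf.members] = name
    return labels


def _descends(ancestor: ClusterNode, node: ClusterNode) -> bool:
    if ancestor is node:
        return True
    return any(_descends(child, node) for child in ancestor.children)


def select_outliers(
    table: pd.DataFrame,
    indexes: list[str] | None = None,
    pct: float = 2.28,
) -> pd.Series:
    """Flag subjects extreme in ANY of the named indexes.

    A subject is flagged when an index value falls at or below its ``pct``-th
    percentile or at or above its ``100-pct``-th percentile (linear
    interpolation, boundaries inclusive).
    """
    indexes = DEFAULT_OUTLIER_INDEXES if indexes is None else indexes
    if not 0 < pct <= 50:
        raise ValueError("pct must be in (0, 50]")
    unknown = [c for c in indexes if c not in table.columns]
    if unknown:
        raise ValueError(f"unknown index names: {unknown}")
    mask = pd.Series(False, index=table.index)
    for col in indexes:
        vals = table[col].to_numpy(dtype=float)
        lo = np.percentile(vals, pct)
        hi = np.percentile(vals, 100.0 - pct)
        mask |= (table[col] <= lo) | (table[col] >= hi)
    return mask


def outlier_cluster(
    table: pd.DataFrame,
    seed: int = 0,
    method: str = "umap",
    eps: float | str = "auto",
    min_samples: int = 20,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
) -> pd.Series:
    """Re-cluster the outlier subset alone: zscore -> embed -> DBSCAN."""
    if len(table) == 0:
        raise ValueError("empty outlier subset")
    if len(table) < min_samples:
        raise ValueError("outlier subset smaller than min_samples")
    if table.nunique().sum() == len(table.columns):  # all rows identical
        return pd.Series(0, index=table.index, name="cluster")
    Z = zscore(table)
    emb = embed(Z, method=method, seed=seed, n_neighbors=n_neighbors, min_dist=min_dist)
    labels = density_cluster(emb, eps=eps, min_samples=min_samples)
    return pd.Series(labels, index=table.index, name="cluster")


@dataclass
class ClusterProfile:
    label: object
    size: int
    mean_z: pd.Series
    representative: object  # subject id nearest the centroid


def cluster_profiles(labels: pd.Series, Z: ZMatrix) -> list[ClusterProfile]:
    """Per-cluster size, mean z-profile and centroid-nearest representative.

    Noise labels (-1 or "noise") are excluded; representative ties resolve to
    the lowest subject id.
    """
    profiles = []
    zdf = Z.values
    for label in sorted(set(labels) - {-1, "noise"}, key=str):
        members = labels.index[labels == label]
        sub = zdf.loc[members]
        centroid = sub.mean(axis=0)
        dists = np.linalg.norm(sub.to_numpy() - centroid.to_numpy(), axis=1)
        best = min(range(len(members)), key=lambda i: (round(float(dists[i]), 12), members[i]))
        profiles.append(
            ClusterProfile(
                label=label,
                size=len(members),
                mean_z=centroid,
                representative=members[best],
            )
        )
    return profiles


def evaluate_recovery(labels, truth_labels) -> float:
    """Adjusted Rand index between recovered and true partitions.

    Noise assignments (-1 or "noise") are excluded pairwise before scoring.
    """
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(labels, dtype=object)
    b = np.asarray(truth_labels, dtype=object)

    def not_noise(arr):
        return np.array([x != -1 and x != "noise" for x in arr], dtype=bool)

    keep = not_noise(a) & not_noise(b)
    if not keep.any():
        raise ValueError("no non-noise pairs to compare")
    return float(adjusted_rand_score(a[keep].astype(str), b[keep].astype(str)))
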