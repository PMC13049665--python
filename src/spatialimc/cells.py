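"""Single-cell features, PhenoGraph-style clustering, phenotype annotation.

Cells are read out of a labeled segmentation mask (area, centroid, per-marker
mean intensity), clustered in marker space by the PhenoGraph construction —
a k-nearest-neighbor graph whose edges are re-weighted by the Jaccard overlap
of the endpoints' neighbor sets, partitioned by Louvain modularity
maximization — and clusters are mapped to named phenotypes by marker
high/low gating rules.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .io import ImageStack, LabelMask
from .panel import Panel

DEFAULT_K_NEIGHBORS = 30


def extract_features(img: ImageStack, mask: LabelMask, panel: Panel | None = None) -> pd.DataFrame:
    """One row per labeled cell: area, centroid (μm), per-marker mean intensity.

    Means are taken over the cell's mask pixels for every measured (non-ignore)
    marker, so downstream per-cell spillover compensation sees the full
    channel vector.  Centroids follow the pixel-center convention:
    ``(mean pixel index + 0.5) * pixel_size``.  An empty mask yields an
    empty (0-row) table, not an error.
    """
    panel = panel if panel is not None else img.panel
    if img.shape_yx != mask.labels.shape:
        raise ValueError(
            f"image {img.shape_yx} and mask {mask.labels.shape} shapes differ"
        )
    markers = panel.measured_markers
    columns = [
        "cell_id",
        "roi_id",
        "centroid_x_um",
        "centroid_y_um",
        "area_um2",
        *(f"mean_{m}" for m in markers),
    ]
    labels = mask.labels
    if labels.max() == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns}).astype(
            {"cell_id": int, "roi_id": str}
        )

    flat = labels.ravel()
    idx = np.flatnonzero(flat)  # only cell pixels contribute to any statistic
    vals = flat[idx]
    n_bins = int(vals.max()) + 1
    counts = np.bincount(vals, minlength=n_bins)
    present = np.flatnonzero(counts[1:]) + 1

    h, w = labels.shape
    yy, xx = np.divmod(idx, w)
    sum_y = np.bincount(vals, weights=yy, minlength=n_bins)
    sum_x = np.bincount(vals, weights=xx, minlength=n_bins)
    px = img.pixel_size_um
    data = {
        "cell_id": present,
        "roi_id": img.roi_id,
        "centroid_x_um": (sum_x[present] / counts[present] + 0.5) * px,
        "centroid_y_um": (sum_y[present] / counts[present] + 0.5) * px,
        "area_um2": counts[present] * px**2,
    }
    chans = img.pixels.reshape(img.n_channels, -1)
    for m in markers:
        ch = chans[panel.index_of(m)][idx].astype(float)
        sums = np.bincount(vals, weights=ch, minlength=n_bins)
        data[f"mean_{m}"] = sums[present] / counts[present]
    return pd.DataFrame(data)


@dataclass
class ClusterModel:
    """A fitted PhenoGraph clustering: graph, partition and its modularity."""

    k_neighbors: int
    graph: ig.Graph
    labels: np.ndarray  # community id per cell, in table row order
    modularity: float
    seed: int
    method: str = "louvain"

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))


def _jaccard_graph(x: np.ndarray, k: int) -> tuple[ig.Graph, np.ndarray]:
    """kNN graph with Jaccard edge weights over directed kNN sets incl. self."""
    n = x.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n - 1)).fit(x)
    ind = nn.kneighbors(return_distance=False)  # excludes self; shape (n, k)
    sets = np.hstack([np.arange(n)[:, None], ind])  # self + k nearest, size k+1

    rows = np.repeat(np.arange(n), sets.shape[1])
    a = sparse.csr_matrix(
        (np.ones(sets.size, dtype=np.int32), (rows, sets.ravel())), shape=(n, n)
    )
    a.data[:] = 1  # collapse duplicates, if any
    inter = (a @ a.T).tocsr()
    adj = a + a.T
    adj.setdiag(0)
    adj.eliminate_zeros()
    overlap = inter.multiply(adj > 0).tocoo()
    sel = overlap.row < overlap.col
    ei, ej, iv = overlap.row[sel], overlap.col[sel], overlap.data[sel]
    set_size = sets.shape[1]
    weights = iv / (2.0 * set_size - iv)  # |A∩B| / |A∪B|
    keep = weights > 0
    edges = np.column_stack([ei[keep], ej[keep]])
    g = ig.Graph(n=n, edges=edges.tolist())
    g.es["weight"] = weights[keep].tolist()
    return g, weights[keep]


def cluster_phenograph(
    table: pd.DataFrame,
    markers: list[str],
    k: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
    method: str = "louvain",
) -> ClusterModel:
    """PhenoGraph clustering of cells on normalized marker expression.

    Steps: (1) Euclidean kNN graph in marker space; (2) edges re-weighted by
    the Jaccard overlap of the endpoints' kNN sets (directed sets including
    self); (3) community detection by Louvain modularity maximization with a
    fixed seed (``method="leiden"`` for the Leiden refinement instead).

    Cells are processed in a canonical (lexicographic-by-feature) vertex
    order, so the partition depends only on the set of points, not on the
    table's row order; community ids may still differ between orderings.

    If the table holds fewer than ``k + 1`` cells, ``k`` is reduced to
    ``n - 1`` with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if method not in ("louvain", "leiden"):
        raise ValueError(f"unknown clustering method {method!r}")
    cols = [f"mean_{m}" if f"mean_{m}" in table.columns else m for m in markers]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"marker columns missing from table: {missing}")
    x = table[cols].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n < k + 1:
        warnings.warn(f"only {n} cells; reducing k from {k} to {n - 1}")
        k = n - 1

    canonical = np.lexsort(x.T[::-1])
    g, _ = _jaccard_graph(x[canonical], k)
    if method == "louvain":
        state = random.Random(int(seed))
        ig.set_random_number_generator(state)
        part = g.community_multilevel(weights="weight")
    else:
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights="weight",
            seed=int(seed),
            n_iterations=2,
        )
    sorted_labels = np.asarray(part.membership)
    modularity = float(g.modularity(sorted_labels, weights="weight"))
    labels = np.empty(n, dtype=sorted_labels.dtype)
    labels[canonical] = sorted_labels
    g = g.permute_vertices(canonical.tolist())  # graph vertex i == table row i
    return ClusterModel(
        k_neighbors=k, graph=g, labels=labels, modularity=modularity, seed=int(seed), method=method
    )


@dataclass(frozen=True)
class PhenotypeRule:
    """Marker high/low gate mapping a cluster to a named phenotype.

    A cluster matches when every ``required_high`` marker's mean normalized
    expression is at least ``threshold_high`` and every ``required_low``
    marker's is at most ``threshold_low``.
    """

    phenotype_name: str
    required_high: tuple[str, ...]
    required_low: tuple[str, ...] = ()
    threshold_high: float = 0.25
    threshold_low: float = 0.15

    def __post_init__(self) -> None:
        overlap = set(self.required_high) & set(self.required_low)
        if overlap:
            raise ValueError(f"markers required both high and low: {sorted(overlap)}")
        if not self.required_high:
            raise ValueError("a phenotype rule needs at least one required-high marker")


def default_phenotype_rules() -> tuple[PhenotypeRule, ...]:
    """Gating rules for the canonical immune/tumor/stroma populations.

    Priority order matters: more specific signatures first (M2 macrophages
    before generic macrophages).  Two rules share the name ``stromal``
    because either alpha-SMA or collagen identifies stromal cells.
    """
    r = PhenotypeRule
    return (
        r("CD8_T", ("CD3", "CD8a")),
        r("CD4_T", ("CD3", "CD4")),
        r("B", ("CD20",)),
        r("M2_macrophage", ("CD68", "CD204")),
        r("macrophage", ("CD68",)),
        r("NK", ("CD7",), ("CD3",)),
        r("tumor", ("CA19-9",)),
        r("stromal", ("aSMA",)),
        r("stromal", ("collagen",)),
    )


def _validate_rules(rules) -> None:
    seen = set()
    for rule in rules:
        key = (frozenset(rule.required_high), frozenset(rule.required_low))
        if key in seen:
            raise ValueError(
                f"two phenotype rules with identical requirements: {sorted(key[0])} high, "
                f"{sorted(key[1])} low"
            )
        seen.add(key)


def cluster_mean_matrix(table: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Mean normalized expression per (cluster, marker) — the heatmap matrix."""
    cols = [f"mean_{m}" for m in markers]
    out = table.groupby("cluster_id")[cols].mean()
    out.columns = markers
    return out


def annotate_clusters(
    model: ClusterModel,
    table: pd.DataFrame,
    rules=None,
) -> pd.DataFrame:
    """Assign a phenotype to every cell via its cluster's mean expression.

    Per cluster, the mean normalized expression of each marker is computed
    and the first rule (in priority order) whose requirements are met gives
    the cluster's phenotype; unmatched clusters become ``"other"``.  All
    cells inherit their cluster's phenotype.
    """
    rules = tuple(rules) if rules is not None else default_phenotype_rules()
    _validate_rules(rules)
    out = table.copy()
    out["cluster_id"] = model.labels
    marker_cols = {c[len("mean_"):]: c for c in out.columns if c.startswith("mean_")}
    means = out.groupby("cluster_id")[list(marker_cols.values())].mean()

    def _match(row) -> str:
        for rule in rules:
            ok = True
            for m in rule.required_high:
                col = marker_cols.get(m)
                if col is None or row[col] < rule.threshold_high:
                    ok = False
                    break
            if ok:
                for m in rule.required_low:
                    col = marker_cols.get(m)
                    if col is not None and row[col] > rule.threshold_low:
                        ok = False
                        break
            if ok:
                return rule.phenotype_name
        return "other"

    cluster_phenotype = {cid: _match(means.loc[cid]) for cid in means.index}
    out["phenotype"] = out["cluster_id"].map(cluster_phenotype)
    return out
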