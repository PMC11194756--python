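"""Downstream analysis in the curated component latent space.

Spots are clustered on a shared-nearest-neighbor graph built from their
component weight columns (modularity-based community detection with a
resolution parameter), embedded in 2-D with UMAP, summarized as smooth
density rasters of selected signal, and subset by cluster, density or
explicit id — the workflow used to, e.g., isolate and re-analyze spots
dominated by a particular signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .composition import CompositionMatrix
from .decomposition import Decomposition
from .io import Workspace

logger = logging.getLogger("spotica")


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-spot integers, contiguous from 0
    resolution: float
    components_used: list
    neighbors: int
    metric: str = "euclidean"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _weight_matrix(d: Decomposition, components: list) -> np.ndarray:
    idx = [d.index_of(c) for c in components]
    W = d.weights[:, idx]
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite spot weights")
    return W


def _snn_graph(W: np.ndarray, neighbors: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = W.shape[0]
    k = min(neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(W)
    knn = nn.kneighbors_graph(W, mode="connectivity")
    knn = knn + sp.eye(n, format="csr")
    shared = (knn @ knn.T).tocoo()  # counts of common neighbors
    deg = k + 1
    jac = shared.data / (2 * deg - shared.data)
    mask = (shared.row < shared.col) & (jac > 1e-9)
    return sp.coo_matrix(
        (jac[mask], (shared.row[mask], shared.col[mask])), shape=(n, n)
    ).tocsr()


def cluster_spots(
    d: Decomposition,
    components: list | None = None,
    resolution: float = 1.0,
    neighbors: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Community detection on the SNN graph of selected component weights.

    Uses modularity optimization (Leiden with the RB configuration null model,
    whose resolution parameter matches the usual Louvain resolution) on a
    Jaccard-weighted shared-nearest-neighbor graph.  Deterministic per seed.
    """
    import igraph
    import leidenalg

    if components is None:
        components = d.selected()
    if len(components) < 2:
        raise ValueError("need at least 2 components for clustering")
    W = _weight_matrix(d, components)
    g = _snn_graph(W, neighbors)
    coo = g.tocoo()
    graph = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    # relabel contiguously by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterResult(
        labels=labels,
        resolution=resolution,
        components_used=list(components),
        neighbors=neighbors,
    )


def embed_spots(
    d: Decomposition,
    components: list | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D UMAP embedding of the selected component weight columns."""
    import umap

    if components is None:
        components = d.selected()
    W = _weight_matrix(d, components)
    if W.shape[0] < 5:
        raise ValueError("need at least 5 spots to embed")
    reducer = umap.UMAP(
        n_components=2,
        random_state=seed,
        n_neighbors=min(n_neighbors, W.shape[0] - 1),
        min_dist=min_dist,
        unique=True,  # duplicate spots get identical coordinates
    )
    coords = reducer.fit_transform(W)
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=float)


def _default_bandwidth(coords: np.ndarray) -> float:
    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    dist, _ = nn.kneighbors(coords)
    med = float(np.median(dist[:, 1]))
    return 2.0 * med if med > 0 else 1.0


def density_map(
    c: CompositionMatrix,
    parts: list,
    coords: np.ndarray,
    grid_n: int = 200,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Gaussian-kernel interpolated raster of summed part abundances.

    The per-spot scalar is the sum of the selected parts' relative
    abundances; each grid node takes the kernel-weighted average of nearby
    spots' scalars.  The raster is normalized to max 1.  Bandwidth defaults
    to twice the median nearest-neighbor spot spacing.
    """
    missing = set(parts) - set(c.part_ids)
    if missing:
        raise KeyError(f"parts {sorted(missing)} not in the composition")
    idx = [c.part_ids.index(p) for p in parts]
    signal = c.values[:, idx].sum(axis=1)
    if signal.sum() == 0:
        raise ValueError("selected parts carry no signal")
    coords = np.asarray(coords, dtype=float)
    if bandwidth is None:
        bandwidth = _default_bandwidth(coords)
    gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_n)
    gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_n)
    raster = np.zeros((grid_n, grid_n))
    # row chunks keep the (grid_n^2 x n_spots) kernel matrix bounded
    for i0 in range(0, grid_n, 32):
        sub = gy[i0 : i0 + 32]
        dx2 = (gx[None, :, None] - coords[None, None, :, 0]) ** 2
        dy2 = (sub[:, None, None] - coords[None, None, :, 1]) ** 2
        w = np.exp(-0.5 * (dx2 + dy2) / bandwidth**2)
        wsum = w.sum(axis=2)
        with np.errstate(invalid="ignore"):
            raster[i0 : i0 + 32] = np.where(wsum > 0, (w * signal).sum(axis=2) / wsum, 0.0)
    peak = raster.max()
    if peak > 0:
        raster /= peak
    return raster


def spot_density(c: CompositionMatrix, parts: list) -> np.ndarray:
    """Per-spot summed relative abundance of the selected parts."""
    idx = [c.part_ids.index(p) for p in parts]
    return c.values[:, idx].sum(axis=1)


def subset_spots(
    ws: Workspace,
    cluster_ids: list | None = None,
    density_selection: tuple[str, list, float] | None = None,
    spot_ids: list | None = None,
) -> Workspace:
    """Restrict a workspace to a spot selection.

    Exactly one criterion: ``cluster_ids`` (labels from the stored
    clustering), ``density_selection`` = (composition name, parts, threshold)
    on the per-spot summed abundance, or explicit ``spot_ids``.  Decomposition
    weight rows and compositions are row-subset; gene loadings are unchanged.
    The criterion is recorded in the provenance log.
    """
    given = [cluster_ids is not None, density_selection is not None, spot_ids is not None]
    if sum(given) != 1:
        raise ValueError("give exactly one of cluster_ids, density_selection, spot_ids")
    if ws.spots is None:
        raise ValueError("workspace has no spots")
    all_ids = ws.spots.spot_ids
    if cluster_ids is not None:
        if ws.cluster_labels is None:
            raise ValueError("no clustering stored in the workspace")
        mask = np.isin(ws.cluster_labels, cluster_ids)
        criterion = f"clusters {sorted(cluster_ids)}"
    elif density_selection is not None:
        name, parts, threshold = density_selection
        if name not in ws.compositions:
            raise KeyError(f"no composition named {name!r}")
        mask = spot_density(ws.compositions[name], parts) >= threshold
        criterion = f"density of {parts} in {name!r} >= {threshold}"
    else:
        wanted = set(spot_ids)
        mask = np.array([s in wanted for s in all_ids])
        criterion = f"{len(wanted)} explicit spot ids"
    index = np.where(mask)[0]
    if len(index) == 0:
        raise ValueError(f"empty spot selection ({criterion})")

    out = Workspace(config=dict(ws.config), provenance=list(ws.provenance))
    out.provenance.append({"subset": criterion, "n_spots": int(len(index))})
    out.spots = ws.spots.subset_spots(index)
    if ws.normalized is not None:
        nm = ws.normalized
        from .preprocess import NormalizedMatrix

        out.normalized = NormalizedMatrix(
            residuals=nm.residuals[index],
            gene_ids=nm.gene_ids,
            spot_ids=nm.spot_ids[index] if nm.spot_ids is not None else None,
            model_params=nm.model_params,
            clip_bound=nm.clip_bound,
        )
    if ws.decomposition is not None:
        import copy

        d = copy.deepcopy(ws.decomposition)
        d.weights = d.weights[index]
        d.spot_ids = d.spot_ids[index]
        if d.spot_mean is not None:
            d.spot_mean = d.spot_mean[index]
        out.decomposition = d
    for name, cm in ws.compositions.items():
        out.compositions[name] = CompositionMatrix(
            values=cm.values[index],
            part_ids=list(cm.part_ids),
            spot_ids=cm.spot_ids[index] if cm.spot_ids is not None else None,
            high_pass=cm.high_pass,
        )
    if ws.cluster_labels is not None:
        out.cluster_labels = np.asarray(ws.cluster_labels)[index]
    if ws.embedding is not None:
        out.embedding = np.asarray(ws.embedding)[index]
    return out
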