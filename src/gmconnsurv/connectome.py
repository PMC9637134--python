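"""Single-subject gray-matter covariance networks and the 93 predictors.

A subject's connectome is built from their segmented gray-matter map
alone: the volume is tiled into 3×3×3-voxel cubes (network nodes), the
Pearson correlation between every pair of cube intensity vectors forms a
similarity matrix, and edges are the correlations exceeding a
permutation-estimated false-discovery-rate threshold. Local efficiency is
computed per node and averaged within each of the atlas regions; together
with total brain volume, network size (node count) and mean degree this
yields ``n_regions + 3`` predictors — 93 for a standard 90-region
cortical/subcortical parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import GrayMatterVolume

__all__ = [
    "CubeNodeSet",
    "BinaryConnectome",
    "ConnectomeFeatureVector",
    "extract_cube_nodes",
    "similarity_matrix",
    "estimate_fdr_threshold",
    "binarize_and_connect",
    "local_efficiency",
    "all_local_efficiencies",
    "degree_and_size",
    "aggregate_regional_efficiency",
    "total_gray_matter_volume",
    "regional_gray_matter_volumes",
    "assemble_connectome_features",
    "connectome_feature_names",
    "subject_connectome_features",
]


@dataclass
class CubeNodeSet:
    """Cube nodes: value vectors, lattice positions and region labels."""

    node_values: np.ndarray  # n_nodes × cube_edge³
    node_centers: np.ndarray  # n_nodes × 3, cube corner voxel index
    cube_edge: int
    node_region: np.ndarray  # n_nodes, labels 1..n_regions

    @property
    def n_nodes(self) -> int:
        return self.node_values.shape[0]


@dataclass
class BinaryConnectome:
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    threshold_used: float
    node_region: np.ndarray

    def __post_init__(self) -> None:
        A = self.adjacency
        if A.dtype != bool or not np.array_equal(A, A.T) or A.diagonal().any():
            raise ValueError("adjacency must be boolean, symmetric, hollow")


@dataclass
class ConnectomeFeatureVector:
    regional_efficiency: np.ndarray  # n_regions values in [0, 1]
    total_brain_volume_ml: float
    network_size: int
    mean_degree: float
    names: list[str]

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [
                self.regional_efficiency,
                [self.total_brain_volume_ml, self.network_size, self.mean_degree],
            ]
        )


def extract_cube_nodes(
    volume: GrayMatterVolume,
    atlas: np.ndarray,
    cube_edge: int = 3,
    min_mask_fraction: float = 0.5,
) -> CubeNodeSet:
    """Tile the volume into non-overlapping cubes and keep in-mask ones.

    A cube becomes a node iff at least ``min_mask_fraction`` of its voxels
    are in the gray-matter mask; out-of-mask voxels contribute value 0.
    The node's region is the atlas label of the cube's majority in-mask
    voxel (ties broken by lowest label).
    """
    if cube_edge < 2:
        raise ValueError("cube_edge must be >= 2")
    if volume.values.shape != atlas.shape:
        raise ValueError("volume and atlas must share a shape")
    vals = np.where(volume.effective_mask, volume.values, 0.0)
    mask = volume.effective_mask
    sx, sy, sz = vals.shape
    nx, ny, nz = sx // cube_edge, sy // cube_edge, sz // cube_edge
    e = cube_edge
    vpc = e**3

    # reshape into (nx, ny, nz, e, e, e) blocks
    def blocks(arr: np.ndarray) -> np.ndarray:
        return (
            arr[: nx * e, : ny * e, : nz * e]
            .reshape(nx, e, ny, e, nz, e)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(nx * ny * nz, vpc)
        )

    v_blocks = blocks(vals)
    m_blocks = blocks(mask.astype(np.int8)).astype(bool)
    a_blocks = blocks(atlas.astype(np.int64))
    frac = m_blocks.mean(axis=1)
    keep = frac >= max(min_mask_fraction, np.finfo(float).tiny)

    idx = np.argwhere(keep).ravel()
    if idx.size < 2:
        raise ValueError("fewer than 2 cubes qualify as nodes")
    regions = np.empty(idx.size, dtype=np.int64)
    for out_i, bi in enumerate(idx):
        labels = a_blocks[bi][m_blocks[bi]]
        uniq, counts = np.unique(labels, return_counts=True)
        # majority in-mask label, ties to the lowest label
        regions[out_i] = uniq[np.argmax(counts)]
    centers = np.stack(np.unravel_index(idx, (nx, ny, nz)), axis=1) * e
    return CubeNodeSet(
        node_values=v_blocks[idx].astype(float),
        node_centers=centers,
        cube_edge=e,
        node_region=regions,
    )


def _rotation_orders(edge: int) -> np.ndarray:
    """Index orderings for the 48 axis-aligned rotations/reflections."""
    import itertools

    base = np.arange(edge**3).reshape(edge, edge, edge)
    seen = {}
    for perm in itertools.permutations(range(3)):
        for flips in itertools.product([False, True], repeat=3):
            arr = np.transpose(base, perm)
            for ax, f in enumerate(flips):
                if f:
                    arr = np.flip(arr, axis=ax)
            seen[arr.tobytes()] = arr.ravel().copy()
    return np.stack(list(seen.values()))


def similarity_matrix(
    nodes: CubeNodeSet,
    maximize_over_rotations: bool = False,
    drop_constant: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations between all cube pairs.

    Returns ``(r, kept)`` where ``kept`` indexes the nodes retained (a
    constant-valued cube has no defined correlation; with
    ``drop_constant`` such nodes are removed, otherwise a ValueError
    names the first offender). With ``maximize_over_rotations`` each
    entry is the maximum correlation over the 48 axis-aligned
    rotations/reflections of the second cube's value ordering.
    """
    X = nodes.node_values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        if not drop_constant:
            raise ValueError(
                f"node {int(np.flatnonzero(const)[0])} has zero variance"
            )
        kept = np.flatnonzero(~const)
    else:
        kept = np.arange(X.shape[0])
    if kept.size < 2:
        raise ValueError("fewer than 2 non-constant nodes")
    Xk = X[kept]
    Z = Xk - Xk.mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    if not maximize_over_rotations:
        r = Z @ Z.T
    else:
        orders = _rotation_orders(nodes.cube_edge)
        r = np.full((kept.size, kept.size), -np.inf)
        for order in orders:
            np.maximum(r, Z @ Z[:, order].T, out=r)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r, kept


def _null_exceedance(
    X: np.ndarray, grid: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean count of null off-diagonal correlations above each grid value.

    The null destroys inter-node covariance while preserving each node's
    marginal distribution: every node's value vector is independently
    permuted before correlations are recomputed.
    """
    n, m = X.shape
    iu = np.triu_indices(n, k=1)
    counts = np.zeros(grid.size)
    for _ in range(n_permutations):
        perm = np.argsort(rng.random((n, m)), axis=1)
        Xp = np.take_along_axis(X, perm, axis=1)
        Z = Xp - Xp.mean(axis=1, keepdims=True)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        vals = np.sort((Z @ Z.T)[iu])
        counts += vals.size - np.searchsorted(vals, grid, side="right")
    return counts / n_permutations


def estimate_fdr_threshold(
    nodes: CubeNodeSet,
    alpha: float = 0.05,
    n_permutations: int = 20,
    seed: int = 0,
    grid_size: int = 400,
) -> float:
    """Correlation threshold controlling the false discovery rate.

    Null correlations come from a random network: correlations recomputed
    after independently permuting each node's value vector. The returned
    threshold is the smallest t on a fine grid such that
    (expected null correlations > t) / (observed correlations > t) ≤ alpha.
    Deterministic for a fixed seed.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    r, kept = similarity_matrix(nodes)
    obs = np.sort(r[np.triu_indices(r.shape[0], k=1)])
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_size, endpoint=False)
    obs_counts = obs.size - np.searchsorted(obs, grid, side="right")
    null_counts = _null_exceedance(
        nodes.node_values[kept], grid, n_permutations, rng
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_counts > 0, null_counts / obs_counts, np.inf)
    ok = np.flatnonzero(fdr <= alpha)
    if ok.size == 0:
        raise ValueError(
            "no threshold achieves the requested FDR; consider a larger alpha"
        )
    return float(grid[ok[0]])


def binarize_and_connect(
    similarity: np.ndarray,
    threshold: float,
    reconnect_policy: str = "relax",
    decrement: float = 0.01,
) -> BinaryConnectome:
    """Threshold the similarity matrix, guaranteeing no isolated nodes.

    ``adjacency[i, j] = similarity[i, j] > threshold`` (hollow,
    symmetric). If isolated nodes remain: policy ``"error"`` raises;
    policy ``"relax"`` lowers the threshold in fixed decrements until
    every node has at least one edge, recording ``threshold_used``.
    """
    if not (-1.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (-1, 1)")
    if reconnect_policy not in ("error", "relax"):
        raise ValueError(f"unknown reconnect_policy {reconnect_policy!r}")
    r = np.asarray(similarity, dtype=float)
    t = threshold
    while True:
        A = r > t
        np.fill_diagonal(A, False)
        A &= A.T  # defensive; r should already be symmetric
        isolated = ~A.any(axis=1)
        if not isolated.any():
            return BinaryConnectome(
                adjacency=A,
                threshold_used=t,
                node_region=np.zeros(r.shape[0], dtype=np.int64),
            )
        if reconnect_policy == "error":
            raise ValueError(
                f"{int(isolated.sum())} isolated node(s) at threshold {t:.3f}"
            )
        t -= decrement
        if t <= 0.0:
            raise ValueError(
                "threshold relaxed to 0 without achieving connectivity"
            )


def local_efficiency(adjacency: np.ndarray, node_index: int) -> float:
    """Local efficiency of one node of a binary undirected graph.

    For node i with neighbor set N (k = |N|): 0 if k < 2, else the mean
    of 1/d(j, h) over ordered neighbor pairs, with d the shortest-path
    length *within the subgraph induced by N* (1/∞ = 0).
    """
    A = np.asarray(adjacency, dtype=bool)
    n = A.shape[0]
    if not (0 <= node_index < n):
        raise IndexError(f"node index {node_index} out of range for {n} nodes")
    nbrs = np.flatnonzero(A[node_index])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = A[np.ix_(nbrs, nbrs)]
    inv = _inverse_distance_sum(sub)
    return float(inv / (k * (k - 1)))


def _inverse_distance_sum(sub: np.ndarray) -> float:
    """Σ over ordered pairs of 1/d within a (small) induced subgraph.

    Exact: distance-d pair counts are peeled off by iterated boolean
    reachability (one matrix product per additional hop), which equals
    breadth-first search on every pair; pairs never reached contribute 0.
    """
    k = sub.shape[0]
    sub_f = sub.astype(np.float32)
    d1 = int(sub.sum())  # ordered adjacent pairs
    reach = sub | np.eye(k, dtype=bool)
    inv = float(d1)
    counted = d1 + k  # ordered pairs with known distance, incl. diagonal
    d = 1
    while counted < k * k:
        new_reach = (reach.astype(np.float32) @ sub_f) > 0
        new_reach |= reach
        newly = int(new_reach.sum()) - int(reach.sum())
        if newly == 0:
            break  # remaining pairs are disconnected: 1/inf = 0
        d += 1
        inv += newly / d
        counted += newly
        reach = new_reach
    return inv


def all_local_efficiencies(adjacency: np.ndarray) -> np.ndarray:
    """Local efficiency for every node."""
    A = np.asarray(adjacency, dtype=bool)
    return np.array([local_efficiency(A, i) for i in range(A.shape[0])])


def degree_and_size(adjacency: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Per-node degrees, network size (node count), and mean degree."""
    A = np.asarray(adjacency, dtype=bool)
    deg = A.sum(axis=1).astype(int)
    return deg, A.shape[0], float(deg.mean())


def aggregate_regional_efficiency(
    nodal_efficiencies: np.ndarray, node_region: np.ndarray, n_regions: int
) -> np.ndarray:
    """Mean nodal local efficiency per atlas region (labels 1..n_regions).

    Connectome size naturally varies across subjects, so nodal values are
    collapsed to a fixed-length regional vector to make subjects
    comparable. Raises if any region has no node.
    """
    eff = np.asarray(nodal_efficiencies, dtype=float)
    reg = np.asarray(node_region, dtype=np.int64)
    if eff.shape != reg.shape:
        raise ValueError("nodal_efficiencies and node_region must align")
    counts = np.bincount(reg, minlength=n_regions + 1)[1 : n_regions + 1]
    if (counts == 0).any():
        missing = (np.flatnonzero(counts == 0) + 1).tolist()
        raise ValueError(f"regions with no node: {missing}")
    sums = np.bincount(reg, weights=eff, minlength=n_regions + 1)[1 : n_regions + 1]
    return sums / counts


def total_gray_matter_volume(volume: GrayMatterVolume) -> float:
    """Total gray-matter volume in milliliters: Σ density × voxel volume."""
    voxel_mm3 = float(np.prod(volume.voxel_size_mm))
    return float(volume.values[volume.effective_mask].sum() * voxel_mm3 / 1000.0)


def regional_gray_matter_volumes(
    volume: GrayMatterVolume, atlas: np.ndarray
) -> np.ndarray:
    """Per-region gray-matter volume (ml), labels 1..max in ascending order."""
    if volume.values.shape != atlas.shape:
        raise ValueError("volume and atlas must share a shape")
    n_regions = int(atlas.max())
    labels = atlas.ravel()
    counts = np.bincount(labels, minlength=n_regions + 1)[1:]
    if (counts == 0).any():
        missing = (np.flatnonzero(counts == 0) + 1).tolist()
        raise ValueError(f"empty regions: {missing}")
    voxel_mm3 = float(np.prod(volume.voxel_size_mm))
    vals = np.where(volume.effective_mask, volume.values, 0.0).ravel()
    sums = np.bincount(labels, weights=vals, minlength=n_regions + 1)[1:]
    return sums * voxel_mm3 / 1000.0


def connectome_feature_names(n_regions: int) -> list[str]:
    return [f"eff_r{r:03d}" for r in range(1, n_regions + 1)] + [
        "brain_volume_ml",
        "network_size",
        "mean_degree",
    ]


def assemble_connectome_features(
    regional_efficiency: np.ndarray,
    total_volume: float,
    size: int,
    mean_degree: float,
) -> ConnectomeFeatureVector:
    """The flattened predictor vector: n_regions efficiencies + 3 globals."""
    eff = np.asarray(regional_efficiency, dtype=float)
    if eff.ndim != 1:
        raise ValueError("regional_efficiency must be a vector")
    return ConnectomeFeatureVector(
        regional_efficiency=eff,
        total_brain_volume_ml=float(total_volume),
        network_size=int(size),
        mean_degree=float(mean_degree),
        names=connectome_feature_names(eff.size),
    )


def subject_connectome_features(
    volume: GrayMatterVolume,
    atlas: np.ndarray,
    *,
    cube_edge: int = 3,
    min_mask_fraction: float = 0.5,
    fdr_alpha: float = 0.05,
    n_permutations: int = 20,
    reconnect_policy: str = "relax",
    seed: int = 0,
    maximize_over_rotations: bool = False,
) -> ConnectomeFeatureVector:
    """Full single-subject pipeline: volume → connectome → feature vector."""
    n_regions = int(atlas.max())
    nodes = extract_cube_nodes(volume, atlas, cube_edge, min_mask_fraction)
    r, kept = similarity_matrix(nodes, maximize_over_rotations)
    threshold = estimate_fdr_threshold(
        nodes, alpha=fdr_alpha, n_permutations=n_permutations, seed=seed
    )
    conn = binarize_and_connect(r, threshold, reconnect_policy)
    conn.node_region = nodes.node_region[kept]
    eff = all_local_efficiencies(conn.adjacency)
    regional = aggregate_regional_efficiency(eff, conn.node_region, n_regions)
    _, size, mean_deg = degree_and_size(conn.adjacency)
    total = total_gray_matter_volume(volume)
    return assemble_connectome_features(regional, total, size, mean_deg)
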