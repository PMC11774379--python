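"""Extended isolation forest over a sliding buffer of coefficient vectors.

Anomalous scaleogram columns (artefacts) are rare and geometrically far
from the bulk of recent activity, so random oblique partitions isolate
them in few splits.  Each tree partitions a sub-sample with hyperplane
cuts: a slope drawn from a standard normal (with dimensions zeroed
according to the extension level) and an intercept drawn uniformly inside
the node's bounding box; a point goes left when ``(x - intercept) . slope
<= 0``.  Scores follow the usual normalization by the average unsuccessful
binary-search-tree path length, so 0.5 marks unremarkable points and
values near 1 mark anomalies.

Trees are stored as flat arrays over an implicit complete binary tree
(children of slot ``i`` at ``2i+1`` / ``2i+2``); growth and scoring are
vectorized level-by-level, which keeps per-window retraining well inside
a real-time budget without compiled extensions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import PipelineConfig
from .scaleogram import CoefficientVector, Scaleogram

__all__ = [
    "IsolationTree",
    "IsolationForest",
    "SlidingBuffer",
    "AnomalyReport",
    "avg_path_normalizer",
    "build_forest",
    "path_length",
    "anomaly_score",
    "detect",
    "update_buffer",
]

_EULER_GAMMA = 0.5772156649


def avg_path_normalizer(size):
    """Average unsuccessful-BST-search path length ``c(n)``.

    Returns 0 for ``n <= 1``, 1 for ``n == 2`` and
    ``2 H(n-1) - 2 (n-1)/n`` otherwise, with ``H(i) = ln(i) + gamma``.
    Accepts scalars or arrays.
    """
    arr = np.asarray(size, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("size must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        general = 2.0 * (np.log(arr - 1.0) + _EULER_GAMMA) - 2.0 * (
            arr - 1.0
        ) / np.maximum(arr, 1.0)
    out = np.where(arr <= 1.0, 0.0, np.where(arr == 2.0, 1.0, general))
    if np.isscalar(size) or np.ndim(size) == 0:
        return float(out)
    return out


@dataclass
class IsolationTree:
    """One extended isolation tree over an implicit complete binary tree.

    ``slopes``/``intercepts`` are defined on internal slots; ``is_leaf``
    marks terminal slots and ``leaf_size`` the number of training vectors
    that terminated there.
    """

    slopes: np.ndarray  # (slots, dim)
    intercepts: np.ndarray  # (slots, dim)
    is_leaf: np.ndarray  # (slots,) bool
    leaf_size: np.ndarray  # (slots,) int
    depth_limit: int

    @property
    def dimension(self) -> int:
        return self.slopes.shape[1]

    @property
    def training_size(self) -> int:
        return int(self.leaf_size[self.is_leaf].sum())

    def path_lengths(self, vectors: np.ndarray) -> np.ndarray:
        """Edges traversed root-to-leaf plus the depth-limit correction
        ``c(leaf size)``, for a batch of vectors (rows)."""
        Y = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        if Y.shape[1] != self.dimension:
            raise ValueError(
                f"vector dimension {Y.shape[1]} != tree dimension "
                f"{self.dimension}"
            )
        node = np.zeros(len(Y), dtype=np.int64)
        edges = np.zeros(len(Y), dtype=np.float64)
        for _ in range(self.depth_limit):
            act = ~self.is_leaf[node]
            if not act.any():
                break
            nd = node[act]
            proj = np.einsum(
                "ij,ij->i", Y[act] - self.intercepts[nd], self.slopes[nd]
            )
            node[act] = 2 * nd + 1 + (proj > 0)
            edges[act] += 1.0
        return edges + avg_path_normalizer(self.leaf_size[node])


def _grow_tree(
    X: np.ndarray, depth_limit: int, el: int, rng: np.random.Generator
) -> IsolationTree:
    n, d = X.shape
    slots = 2 ** (depth_limit + 1) - 1
    slopes = np.zeros((slots, d))
    intercepts = np.zeros((slots, d))
    is_leaf = np.zeros(slots, dtype=bool)
    leaf_size = np.zeros(slots, dtype=np.int64)

    node = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for depth in range(depth_limit + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        order = np.argsort(node[idx], kind="stable")
        idx = idx[order]
        nodes_sorted = node[idx]
        starts = np.flatnonzero(np.r_[True, np.diff(nodes_sorted) > 0])
        seg_nodes = nodes_sorted[starts]
        seg_sizes = np.diff(np.r_[starts, idx.size])
        Xs = X[idx]
        boxmin = np.minimum.reduceat(Xs, starts, axis=0)
        boxmax = np.maximum.reduceat(Xs, starts, axis=0)
        degenerate = (boxmax - boxmin).max(axis=1) <= 0.0

        terminal = (seg_sizes <= 1) | degenerate | (depth == depth_limit)
        leaves = seg_nodes[terminal]
        is_leaf[leaves] = True
        leaf_size[leaves] = seg_sizes[terminal]

        internal = ~terminal
        k = int(internal.sum())
        if k:
            sl = rng.standard_normal((k, d))
            if el < d - 1:
                # zero out d-1-el uniformly chosen dimensions per split
                ranks = rng.random((k, d)).argsort(axis=1)
                sl[ranks < (d - 1 - el)] = 0.0
            u = rng.random((k, d))
            bmin = boxmin[internal]
            p = bmin + u * (boxmax[internal] - bmin)
            slopes[seg_nodes[internal]] = sl
            intercepts[seg_nodes[internal]] = p

        # route points of internal segments to their children
        seg_of_point = np.repeat(np.arange(seg_nodes.size), seg_sizes)
        in_internal = internal[seg_of_point]
        if in_internal.any():
            pts = idx[in_internal]
            nd = node[pts]
            proj = np.einsum(
                "ij,ij->i", X[pts] - intercepts[nd], slopes[nd]
            )
            node[pts] = 2 * nd + 1 + (proj > 0)
        active[idx[~in_internal]] = False

    return IsolationTree(
        slopes=slopes,
        intercepts=intercepts,
        is_leaf=is_leaf,
        leaf_size=leaf_size,
        depth_limit=depth_limit,
    )


@dataclass
class IsolationForest:
    """Ensemble of extended isolation trees with a shared sub-sample size."""

    trees: list[IsolationTree]
    subsample_size: int
    extension_level: int
    seed: int

    @property
    def dimension(self) -> int:
        return self.trees[0].dimension

    def score(self, vectors: np.ndarray) -> np.ndarray:
        """Anomaly score ``2**(-E[h(x)] / c(subsample_size))`` per row."""
        if not self.trees:
            raise ValueError("forest has no trees")
        Y = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
        mean_path = np.zeros(len(Y))
        for tree in self.trees:
            mean_path += tree.path_lengths(Y)
        mean_path /= len(self.trees)
        return 2.0 ** (-mean_path / avg_path_normalizer(self.subsample_size))


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, Scaleogram):
        return vectors.matrix.T
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(vectors)
    return np.stack([np.asarray(v.values, dtype=np.float64) for v in vectors])


def build_forest(
    vectors, config: PipelineConfig, seed: int | None = None
) -> IsolationForest:
    """Grow ``if_trees`` trees, each on a fresh uniform sub-sample.

    ``vectors`` may be an ``(N, dim)`` array, a list of
    :class:`CoefficientVector` or a :class:`Scaleogram`.  Fully
    reproducible from ``seed`` (defaulting to ``config.seed``).
    """
    X = _as_matrix(vectors)
    N, d = X.shape
    if N < config.if_subsample:
        raise ValueError(
            f"need at least if_subsample={config.if_subsample} vectors, "
            f"got {N}"
        )
    el = config.extension_level if config.extension_level is not None else d - 1
    if not 0 <= el <= d - 1:
        raise ValueError(f"extension_level must lie in [0, {d - 1}]")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    depth_limit = int(np.ceil(np.log2(config.if_subsample)))
    trees = [
        _grow_tree(
            X[rng.choice(N, size=config.if_subsample, replace=False)],
            depth_limit,
            el,
            rng,
        )
        for _ in range(config.if_trees)
    ]
    return IsolationForest(
        trees=trees,
        subsample_size=config.if_subsample,
        extension_level=el,
        seed=seed,
    )


def path_length(tree: IsolationTree, vector) -> float:
    """Root-to-leaf edge count for one vector, with leaf-size correction."""
    values = vector.values if isinstance(vector, CoefficientVector) else vector
    return float(tree.path_lengths(np.asarray(values))[0])


def anomaly_score(forest: IsolationForest, vector) -> float:
    """Score a single coefficient vector in (0, 1)."""
    values = vector.values if isinstance(vector, CoefficientVector) else vector
    return float(forest.score(np.asarray(values))[0])


@dataclass
class AnomalyReport:
    """Per-window anomaly scores and flagged coefficient-time columns."""

    window_index: int
    scores: np.ndarray
    AT: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    AT_exp: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64)
    )

    @property
    def n_anomalies(self) -> int:
        return len(self.AT)


def detect(forest: IsolationForest, current, t_a: float) -> AnomalyReport:
    """Score the current window's columns and flag those above ``t_a``.

    ``current`` is the normalized scaleogram of the window (or its column
    vectors).  Flagging is strict (> ``t_a``), ascending column order.
    """
    window_index = current.window_index if isinstance(current, Scaleogram) else 0
    X = _as_matrix(current)
    scores = forest.score(X)
    AT = np.flatnonzero(scores > t_a).astype(np.int64)
    return AnomalyReport(window_index=window_index, scores=scores, AT=AT)


class SlidingBuffer:
    """FIFO buffer of the last ``capacity`` windows' coefficient vectors.

    Stores, per window, both the raw scaleogram columns (for the medoid
    and mitigation distances) and the normalized ones (for forest
    training).  Inserting into a full buffer evicts the oldest window.
    Only pre-denoising vectors are stored, so mitigated windows never
    feed back into training.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._raw: deque[np.ndarray] = deque()
        self._norm: deque[np.ndarray] = deque()
        self._indices: deque[int] = deque()
        # running per-vector sums of Euclidean distances to every other
        # buffered vector, maintained incrementally so the medoid is O(1)
        # to look up after each append
        self._dist_sums: deque[np.ndarray] = deque()
        self._medoid_cache = None
        self.revision = 0

    def __len__(self) -> int:
        return len(self._raw)

    @property
    def is_full(self) -> bool:
        return len(self._raw) == self.capacity

    @property
    def n_vectors(self) -> int:
        return sum(m.shape[1] for m in self._raw)

    @property
    def window_indices(self) -> list[int]:
        return list(self._indices)

    def append(self, raw: Scaleogram, normalized: Scaleogram) -> None:
        if raw.normalized or not normalized.normalized:
            raise ValueError(
                "append expects (raw, normalized) scaleograms in that order"
            )
        if raw.matrix.shape != normalized.matrix.shape:
            raise ValueError("raw/normalized column sets are inconsistent")
        if self._raw and raw.matrix.shape != self._raw[0].shape:
            raise ValueError("window column set incomplete or inconsistent")
        if len(self._raw) == self.capacity:
            evicted = self._raw.popleft()
            self._norm.popleft()
            self._indices.popleft()
            self._dist_sums.popleft()
            for block, sums in zip(self._raw, self._dist_sums):
                sums -= cdist(block.T, evicted.T).sum(axis=1)

        new_block = raw.matrix.T  # (columns, dim)
        new_sums = cdist(new_block, new_block).sum(axis=1)
        for block, sums in zip(self._raw, self._dist_sums):
            D = cdist(new_block, block.T)
            sums += D.sum(axis=0)
            new_sums += D.sum(axis=1)

        self._raw.append(raw.matrix.copy())
        self._norm.append(normalized.matrix.copy())
        self._indices.append(raw.window_index)
        self._dist_sums.append(new_sums)
        self._medoid_cache = None
        self.revision += 1

    def normalized_matrix(self) -> np.ndarray:
        """All buffered normalized vectors as an (N, dim) array, FIFO order."""
        if not self._norm:
            raise ValueError("buffer is empty (cold start)")
        return np.concatenate([m.T for m in self._norm], axis=0)

    def raw_matrix(self) -> np.ndarray:
        """All buffered raw vectors as an (N, dim) array, FIFO order."""
        if not self._raw:
            raise ValueError("buffer is empty (cold start)")
        return np.concatenate([m.T for m in self._raw], axis=0)

    def distance_sums(self) -> np.ndarray:
        """Per-vector sum of Euclidean distances to all other buffered
        vectors (FIFO order), maintained incrementally."""
        if not self._dist_sums:
            raise ValueError("buffer is empty (cold start)")
        return np.concatenate(list(self._dist_sums))

    def vector_ids(self) -> list[tuple[int, int]]:
        """(window_index, column_index) for every buffered vector, FIFO."""
        out = []
        for w, m in zip(self._indices, self._raw):
            out.extend((w, j) for j in range(m.shape[1]))
        return out


def update_buffer(
    buffer: SlidingBuffer, raw: Scaleogram, normalized: Scaleogram
) -> SlidingBuffer:
    """Append one window's original (pre-denoising) column vectors."""
    buffer.append(raw, normalized)
    return buffer
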