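"""Spatial segmentation by bisecting k-means (Euclidean metric).

The divisive procedure starts from one cluster holding every pixel and
repeatedly splits the leaf with the largest within-cluster sum of squares
(WCSS) into two by 2-means (k-means++ initialisation, several restarts,
lowest-WCSS solution kept) until the requested number of leaves is reached.
The result is a binary :class:`SegmentationTree` whose leaves at a chosen
depth give the per-pixel segmentation maps; splitting deeper reveals finer
molecular sub-regions, exactly like choosing a deeper dendrogram cut.

Ties and degeneracy: leaves whose rows are all identical cannot be split and
are marked terminal; equal WCSS between candidate leaves is broken by node
creation index. An optional 3x3 median filter on the feature images is
available for noisy data but is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import InputError
from .peakpick import FeatureMatrix

__all__ = ["SegmentationNode", "SegmentationTree", "bisecting_kmeans", "cut_tree",
           "hierarchical_overview", "median_filter_features"]


@dataclass
class SegmentationNode:
    node_id: int
    pixel_indices: np.ndarray
    wcss: float
    depth: int
    children: tuple | None = None  # (SegmentationNode, SegmentationNode) or None
    terminal: bool = False  # unsplittable (identical rows)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SegmentationTree:
    root: SegmentationNode
    n_pixels: int
    feature_centers: np.ndarray = field(default=None)

    def leaves(self) -> list[SegmentationNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return sorted(out, key=lambda n: n.node_id)

    def height(self) -> int:
        return max(n.depth for n in self.leaves())

    def leaf_labels(self) -> np.ndarray:
        """Per-pixel integer label = index of the leaf holding the pixel."""
        labels = np.full(self.n_pixels, -1, dtype=int)
        for i, leaf in enumerate(self.leaves()):
            labels[leaf.pixel_indices] = i
        return labels

    def to_json(self) -> str:
        def encode(node):
            d = {
                "node_id": node.node_id,
                "n_pixels": int(node.pixel_indices.size),
                "wcss": float(node.wcss),
                "depth": node.depth,
                "terminal": node.terminal,
            }
            if node.children is not None:
                d["children"] = [encode(c) for c in node.children]
            return d

        return json.dumps(encode(self.root), indent=1, sort_keys=True)


def _wcss(x: np.ndarray) -> float:
    if x.shape[0] == 0:
        return 0.0
    return float(((x - x.mean(axis=0)) ** 2).sum())


def _features_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        x = features.values
    else:
        x = np.asarray(features, float)
    if x.ndim != 2:
        raise InputError("features must be a 2-D pixels x intervals array")
    if not np.all(np.isfinite(x)):
        raise InputError("features must be finite")
    return x


def _best_bisection(x: np.ndarray, restarts: int, rng: np.random.Generator):
    """Lowest-WCSS 2-means split of x, or None if x is unsplittable."""
    if x.shape[0] < 2 or np.all(x == x[0]):
        return None
    km = KMeans(
        n_clusters=2,
        init="k-means++",
        n_init=restarts,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(x)
    labels = km.labels_
    if len(np.unique(labels)) < 2:
        return None
    return labels


def bisecting_kmeans(
    features,
    n_leaves: int,
    seed: int = 0,
    restarts: int = 10,
) -> SegmentationTree:
    """Divisive segmentation of a feature matrix into ``n_leaves`` clusters."""
    x = _features_array(features)
    n = x.shape[0]
    if n_leaves < 2:
        raise InputError("n_leaves must be >= 2")
    if n_leaves > n:
        raise InputError(f"n_leaves={n_leaves} exceeds number of pixels ({n})")

    rng = np.random.default_rng(seed)
    next_id = 0
    root = SegmentationNode(next_id, np.arange(n), _wcss(x), depth=0)
    next_id += 1
    leaves = [root]

    while sum(1 for l in leaves if not l.terminal) and len(leaves) < n_leaves:
        # largest-WCSS splittable leaf; ties -> lower node id
        candidates = [l for l in leaves if not l.terminal]
        if not candidates:
            break
        target = max(candidates, key=lambda l: (l.wcss, -l.node_id))
        sub = x[target.pixel_indices]
        split = _best_bisection(sub, restarts, rng)
        if split is None:
            target.terminal = True
            continue
        kids = []
        for side in (0, 1):
            idx = target.pixel_indices[split == side]
            kids.append(
                SegmentationNode(next_id, idx, _wcss(x[idx]), depth=target.depth + 1)
            )
            next_id += 1
        target.children = (kids[0], kids[1])
        leaves.remove(target)
        leaves.extend(kids)

    return SegmentationTree(root=root, n_pixels=n,
                            feature_centers=getattr(features, "centers", None))


def cut_tree(tree: SegmentationTree, depth: int) -> np.ndarray:
    """Per-pixel labels using the tree cut at ``depth``.

    Nodes at exactly ``depth`` act as leaves (their subtrees are merged);
    shallower leaves keep their own label.
    """
    if depth < 0:
        raise InputError("depth must be >= 0")
    cut_nodes, stack = [], [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf or node.depth >= depth:
            cut_nodes.append(node)
        else:
            stack.extend(node.children)
    cut_nodes.sort(key=lambda n: n.node_id)
    labels = np.full(tree.n_pixels, -1, dtype=int)
    for i, node in enumerate(cut_nodes):
        labels[node.pixel_indices] = i
    return labels


def label_maps(features: FeatureMatrix, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Render per-pixel labels as one image per section (-1 off tissue)."""
    maps = {}
    for key, (sl, grid_shape) in features.section_slices.items():
        img = np.full(grid_shape, -1, dtype=int)
        sub = features.keys.iloc[sl]
        img[sub["y"].to_numpy(), sub["x"].to_numpy()] = labels[sl]
        maps[key] = img
    return maps


def hierarchical_overview(features, n_leaves: int, seed: int = 0, restarts: int = 10) -> SegmentationTree:
    """Study-wide overview segmentation: the same divisive algorithm run on
    the concatenated multi-segment feature matrix (gray/white matter emerge as
    the first split when their molecular contrast dominates)."""
    return bisecting_kmeans(features, n_leaves, seed=seed, restarts=restarts)


def median_filter_features(features: FeatureMatrix) -> FeatureMatrix:
    """Optional 3x3 spatial median filter of each interval image (denoising
    before clustering; default pipeline leaves this off)."""
    from scipy.ndimage import median_filter

    values = features.values.copy()
    for key, (sl, grid_shape) in features.section_slices.items():
        sub = features.keys.iloc[sl]
        ys, xs = sub["y"].to_numpy(), sub["x"].to_numpy()
        for j in range(values.shape[1]):
            img = np.zeros(grid_shape)
            img[ys, xs] = values[sl, j]
            filt = median_filter(img, size=3)
            values[sl, j] = filt[ys, xs]
    return FeatureMatrix(
        values=values,
        centers=features.centers,
        sigmas=features.sigmas,
        keys=features.keys,
        section_slices=features.section_slices,
    )
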