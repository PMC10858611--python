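"""Q trees: recursive collider-robust partitioning driven by Cochran's Q.

A Q tree recursively splits a sample into two strata.  At each node, every
candidate covariate is combined with each candidate splitting proportion
(3:7, 5:5, 7:3 by default); the two strata are formed with a collider-robust
stratifier (doubly-ranked by default) and scored by the two-stratum Cochran Q
statistic of their instrumental-variable estimates.  The covariate/proportion
pair with the greatest Q wins.  Splitting stops when the greatest Q falls
below a chi-squared(1) critical value (3.84 at the 95% level), when a child
would drop below the minimum node size, or when the maximum depth is reached.
Terminal nodes carry the ratio-method MR estimate of their members.

Unlike CART, child membership at fit time is the stratum assignment itself
(rank-based, not a covariate threshold); a threshold would re-introduce
collider bias.  The boundary value

    (n1 * mean1 + n2 * mean2) / (n1 + n2)

of the splitting covariate is recorded per node purely to route *new*
individuals at prediction time: an individual goes to the lower child iff
its covariate value is <= the boundary.  For the same reason the tree does
not use "honest" estimation with a separate estimation subsample: leaf
estimates come from the collider-robust strata themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .datasets import Dataset
from .stratify import largest_remainder_quotas

__all__ = [
    "QTreeHyperparameters",
    "TreeNode",
    "QTree",
    "boundary_value",
    "best_split",
    "grow_qtree",
    "predict_qtree",
]

#: 95th percentile of the chi-squared distribution with 1 df.
DEFAULT_Q_THRESHOLD = 3.84


@dataclass(frozen=True)
class QTreeHyperparameters:
    """Growth and stopping parameters for a Q tree.

    Defaults target biobank-scale data; for simulation-scale samples the
    minimum node size is typically scaled down (e.g. to 200).
    """

    q_threshold: float = DEFAULT_Q_THRESHOLD
    min_node_size: int = 1000
    max_depth: int = 5
    proportions: tuple[tuple[float, float], ...] = (
        (0.3, 0.7),
        (0.5, 0.5),
        (0.7, 0.3),
    )
    stratifier: str = "doubly_ranked"
    prestratum_size: int = 10
    mtry_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.stratifier not in ("naive", "residual", "doubly_ranked"):
            raise ValueError(f"unknown stratifier {self.stratifier!r}")
        if not 0 < self.mtry_fraction <= 1:
            raise ValueError("mtry_fraction must be in (0, 1]")

    def replace(self, **kwargs) -> "QTreeHyperparameters":
        return _dc_replace(self, **kwargs)


@dataclass
class TreeNode:
    """One node of a fitted Q tree (leaf when ``children`` is None)."""

    index: int
    depth: int
    n: int
    theta: float
    theta_se: float
    beta_X: float
    sigma_X: float
    beta_Y: float
    sigma_Y: float
    covariate: str | None = None
    proportion: tuple[float, float] | None = None
    boundary: float | None = None
    q_value: float | None = None
    child_means: tuple[float, float] | None = None
    children: tuple[int, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class QTree:
    """A fitted Q tree: a flat node list with root at index 0."""

    nodes: list[TreeNode]
    hyper: QTreeHyperparameters
    covariate_names: tuple[str, ...]
    n_fit: int = 0

    @property
    def depth(self) -> int:
        return max(node.depth for node in self.nodes)

    def leaves(self) -> list[TreeNode]:
        return [node for node in self.nodes if node.is_leaf]

    def to_json(self) -> str:
        def encode(node: TreeNode) -> dict:
            d = dict(node.__dict__)
            for key in ("proportion", "child_means", "children"):
                if d[key] is not None:
                    d[key] = list(d[key])
            return d

        return json.dumps(
            {
                "hyper": self.hyper.__dict__
                | {"proportions": [list(p) for p in self.hyper.proportions]},
                "covariate_names": list(self.covariate_names),
                "n_fit": self.n_fit,
                "nodes": [encode(n) for n in self.nodes],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QTree":
        payload = json.loads(text)
        hyper_d = payload["hyper"]
        hyper_d["proportions"] = tuple(tuple(p) for p in hyper_d["proportions"])
        nodes = []
        for d in payload["nodes"]:
            for key in ("proportion", "child_means", "children"):
                if d[key] is not None:
                    d[key] = tuple(d[key])
            nodes.append(TreeNode(**d))
        return cls(
            nodes=nodes,
            hyper=QTreeHyperparameters(**hyper_d),
            covariate_names=tuple(payload["covariate_names"]),
            n_fit=payload["n_fit"],
        )


def boundary_value(n1: int, n2: int, mean1: float, mean2: float) -> float:
    """Routing boundary for a split: the size-weighted mean of the two child
    means of the splitting covariate."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("child sizes must be positive")
    return (n1 * mean1 + n2 * mean2) / (n1 + n2)


def _ols_pair(z: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """OLS slope and classical SE of w on z with intercept (NaN if degenerate)."""
    n = z.size
    if n < 3:
        return np.nan, np.nan
    zc = z - z.mean()
    czz = zc @ zc
    if czz <= 0:
        return np.nan, np.nan
    beta = (zc @ w) / czz
    resid = w - w.mean() - beta * zc
    se = np.sqrt(max(resid @ resid, 0.0) / (n - 2) / czz)
    return float(beta), float(se)


def _two_stratum_q(bx, sx, by, sy):
    """Cochran Q and IVW theta for exactly two strata (scalars in arrays)."""
    if not (np.all(np.isfinite(bx)) and np.all(np.isfinite(by))):
        return None
    sy = np.maximum(sy, 1e-300)
    w = bx * bx / (sy * sy)
    theta = float(np.sum(w * (by / bx)) / np.sum(w))
    den = sy * sy + theta * theta * sx * sx
    q = float(np.sum((by - theta * bx) ** 2 / den))
    return q, theta


@dataclass(frozen=True)
class SplitRule:
    """A selected split: covariate, proportion, routing boundary and the
    heterogeneity (Q) of the two child MR estimates."""

    covariate_name: str
    proportion: tuple[float, float]
    boundary: float
    q_value: float
    child_means: tuple[float, float]
    lower_mask: np.ndarray = field(repr=False, compare=False, default=None)


def _node_split_search(
    Z: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    M: np.ndarray,
    cand_idx: np.ndarray,
    names: tuple[str, ...],
    hyper: QTreeHyperparameters,
    rng: np.random.Generator,
) -> SplitRule | None:
    """Exhaustive candidate-covariate x proportion search at one node.

    Works entirely with grouped sums so each candidate evaluation costs a few
    passes over the node; the instrument ranking into pre-strata is shared
    across candidates.
    """
    m = Z.size
    props = hyper.proportions

    if hyper.stratifier == "doubly_ranked":
        z_rank = np.empty(m, dtype=np.int64)
        z_rank[np.lexsort((rng.random(m), Z))] = np.arange(m)
        prestratum = z_rank // hyper.prestratum_size
        sizes = np.bincount(prestratum)
    else:
        prestratum = np.zeros(m, dtype=np.int64)
        sizes = np.array([m])
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))

    # lower-child quota per pre-stratum size, per proportion
    max_size = int(sizes.max())
    cuts = np.zeros((len(props), max_size + 1), dtype=np.int64)
    for pi, pr in enumerate(props):
        for s in np.unique(sizes):
            cuts[pi, s] = largest_remainder_quotas(np.asarray(pr), int(s))[0]

    if hyper.stratifier == "residual":
        zc = Z - Z.mean()
        czz = zc @ zc
        if czz <= 0:
            return None

    best: tuple[float, int, int] | None = None  # (q, cand position, prop index)
    best_state = None
    for pos, c in enumerate(cand_idx):
        Mc = M[:, c]
        if hyper.stratifier == "residual":
            key_vals = Mc - ((zc @ Mc) / czz) * zc
        else:
            key_vals = Mc
        order = np.lexsort((rng.random(m), key_vals, prestratum))
        within_rank = np.arange(m) - starts[prestratum[order]]
        size_sorted = sizes[prestratum[order]]
        z_s, x_s, y_s, m_s = Z[order], X[order], Y[order], Mc[order]
        V = np.vstack(
            [
                np.ones(m),
                z_s,
                z_s * z_s,
                x_s,
                z_s * x_s,
                x_s * x_s,
                y_s,
                z_s * y_s,
                y_s * y_s,
                m_s,
            ]
        )
        tot = V.sum(axis=1)
        for pi in range(len(props)):
            lower = within_rank < cuts[pi, size_sorted]
            low = V @ lower.astype(float)
            upp = tot - low
            n1, n2 = low[0], upp[0]
            if min(n1, n2) < max(hyper.min_node_size, 3):
                continue
            stats2 = _pair_assoc(low, upp)
            if stats2 is None:
                continue
            bx, sx, by, sy = stats2
            res = _two_stratum_q(bx, sx, by, sy)
            if res is None:
                continue
            q, _ = res
            if best is None or q > best[0]:
                best = (q, pos, pi)
                mean1 = low[9] / n1
                mean2 = upp[9] / n2
                best_state = (lower, order, (mean1, mean2), (int(n1), int(n2)))

    if best is None:
        return None
    q, pos, pi = best
    lower_sorted, order, (mean1, mean2), (n1, n2) = best_state
    lower_mask = np.zeros(m, dtype=bool)
    lower_mask[order[lower_sorted]] = True
    return SplitRule(
        covariate_name=names[cand_idx[pos]],
        proportion=props[pi],
        boundary=boundary_value(n1, n2, mean1, mean2),
        q_value=q,
        child_means=(float(mean1), float(mean2)),
        lower_mask=lower_mask,
    )


def _pair_assoc(low: np.ndarray, upp: np.ndarray):
    """Slope/SE of X~Z and Y~Z in the lower and upper stratum from sums."""
    bx = np.empty(2)
    sx = np.empty(2)
    by = np.empty(2)
    sy = np.empty(2)
    for i, s in enumerate((low, upp)):
        n, sz, szz, sxv, szx, sxx, syv, szy, syy = s[:9]
        czz = szz - sz * sz / n
        if czz <= 0 or n < 3:
            return None
        czx = szx - sz * sxv / n
        cxx = sxx - sxv * sxv / n
        czy = szy - sz * syv / n
        cyy = syy - syv * syv / n
        bx[i] = czx / czz
        by[i] = czy / czz
        sx[i] = np.sqrt(max(cxx - czx * czx / czz, 0.0) / (n - 2) / czz)
        sy[i] = np.sqrt(max(cyy - czy * czy / czz, 0.0) / (n - 2) / czz)
    return bx, sx, by, sy


def best_split(
    node_data: Dataset,
    candidates: list[str],
    hyper: QTreeHyperparameters,
    rng: np.random.Generator | int = 0,
) -> SplitRule | None:
    """Search for the best (covariate, proportion) split of a node.

    Returns None when no candidate split keeps both children at or above the
    minimum node size, or when the greatest Q is below the threshold.
    """
    if node_data.n == 0 or not candidates:
        raise ValueError("node data and candidates must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cand_idx = np.array([node_data.covariate_names.index(c) for c in candidates])
    rule = _node_split_search(
        node_data.Z,
        node_data.X,
        node_data.Y,
        node_data.M,
        cand_idx,
        node_data.covariate_names,
        hyper,
        rng,
    )
    if rule is None or rule.q_value < hyper.q_threshold:
        return None
    return rule


def grow_qtree(
    train: Dataset,
    hyper: QTreeHyperparameters | None = None,
    seed: int | np.random.Generator = 0,
) -> QTree:
    """Grow a Q tree on the training sample by recursive best_split.

    Child membership comes from the collider-robust stratum assignment found
    during the split search.  Node MR estimates (ratio method) are recorded
    at every node; a node whose estimate is degenerate inherits its parent's.
    """
    hyper = hyper or QTreeHyperparameters()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Z, X, Y, M = train.Z, train.X, train.Y, train.M
    names = train.covariate_names
    p = len(names)
    # e.g. 40% of 28 covariates -> a random subset of 11 per node
    k_cand = max(1, int(round(hyper.mtry_fraction * p)))

    nodes: list[TreeNode] = []

    def make_node(idx: np.ndarray, depth: int, parent: TreeNode | None) -> TreeNode:
        bX, sX = _ols_pair(Z[idx], X[idx])
        bY, sY = _ols_pair(Z[idx], Y[idx])
        if np.isfinite(bX) and bX != 0 and np.isfinite(bY):
            theta = bY / bX
            theta_se = sY / abs(bX)
        elif parent is not None:
            theta, theta_se = parent.theta, parent.theta_se
            bX, sX, bY, sY = parent.beta_X, parent.sigma_X, parent.beta_Y, parent.sigma_Y
        else:
            theta, theta_se = np.nan, np.nan
        node = TreeNode(
            index=len(nodes),
            depth=depth,
            n=int(idx.size),
            theta=float(theta),
            theta_se=float(theta_se),
            beta_X=float(bX),
            sigma_X=float(sX),
            beta_Y=float(bY),
            sigma_Y=float(sY),
        )
        nodes.append(node)
        return node

    def build(idx: np.ndarray, depth: int, parent: TreeNode | None) -> int:
        node = make_node(idx, depth, parent)
        if depth >= hyper.max_depth or idx.size < 2 * hyper.min_node_size:
            return node.index
        cand_idx = (
            rng.permutation(p)[:k_cand] if k_cand < p else np.arange(p)
        )
        rule = _node_split_search(
            Z[idx], X[idx], Y[idx], M[idx], cand_idx, names, hyper, rng
        )
        if rule is None or rule.q_value < hyper.q_threshold:
            return node.index
        node.covariate = rule.covariate_name
        node.proportion = rule.proportion
        node.boundary = float(rule.boundary)
        node.q_value = float(rule.q_value)
        node.child_means = rule.child_means
        lower_idx = idx[rule.lower_mask]
        upper_idx = idx[~rule.lower_mask]
        left = build(lower_idx, depth + 1, node)
        right = build(upper_idx, depth + 1, node)
        node.children = (left, right)
        return node.index

    build(np.arange(train.n), 0, None)
    return QTree(nodes=nodes, hyper=hyper, covariate_names=names, n_fit=train.n)


def predict_qtree(
    tree: QTree, M: np.ndarray, covariate_names: tuple[str, ...] | None = None
) -> np.ndarray:
    """Route individuals through the tree and return their leaf MR estimates.

    At each internal node an individual goes to the lower child iff its value
    of the splitting covariate is <= the node's boundary (ties route lower).
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    names = tuple(covariate_names) if covariate_names is not None else tree.covariate_names
    col = {name: j for j, name in enumerate(names)}
    used = {node.covariate for node in tree.nodes if node.covariate is not None}
    missing = used - set(col)
    if missing:
        raise KeyError(f"missing covariate columns: {sorted(missing)}")

    n = M.shape[0]
    assign = np.zeros(n, dtype=np.int64)
    out = np.empty(n, dtype=float)
    for node in tree.nodes:  # parents precede children in creation order
        rows = np.nonzero(assign == node.index)[0]
        if rows.size == 0:
            continue
        if node.is_leaf:
            out[rows] = node.theta
        else:
            vals = M[rows, col[node.covariate]]
            lower = vals <= node.boundary
            assign[rows[lower]] = node.children[0]
            assign[rows[~lower]] = node.children[1]
    return out
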