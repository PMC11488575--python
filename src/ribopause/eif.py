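"""Extended Isolation Forest for 2-D anomaly scoring.

Isolation forests detect anomalies by how quickly a point can be isolated
under recursive random partitioning: anomalies sit in sparse regions and are
separated after few cuts, so their expected path length from the root is
short.  The *extended* variant replaces axis-parallel cuts with random
hyperplanes — each internal node draws a normal vector uniformly on the unit
sphere and an intercept point uniformly inside the node's bounding box, and
splits its points by the sign of ``(x - p) . n``.

The anomaly score of a query point is::

    s = 2 ** (-E[path] / c(psi))

where ``psi`` is the per-tree subsample size and ``c(n)`` is the average
path length of an unsuccessful search in a binary search tree built on ``n``
points, used both to normalize scores and to credit unresolved leaves with
the expected depth of a subtree over their remaining points.  Scores lie in
``(0, 1]``; values near 1 indicate anomalies, values well below 0.5 indicate
ordinary points.

Trees are stored as flat arrays so that scoring is vectorized level-by-level
over the whole query set.  Randomness flows from a single seed expanded into
per-tree ``SeedSequence`` children, making fits bit-reproducible regardless
of evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

EULER_GAMMA = float(np.euler_gamma)


def harmonic_c(n: int) -> float:
    """Average unsuccessful-search path length of a BST on ``n`` points.

    The standard isolation-forest normalizer ``c(n) = 2 H(n-1) - 2(n-1)/n``
    with the harmonic number approximated as ``H(i) = ln(i) + gamma``.
    ``c(1) = c(0) = 0``: a single point cannot be split further.
    """
    if n < 1:
        raise ValueError(f"harmonic_c requires n >= 1, got {n}")
    if n <= 1:
        return 0.0
    h = np.log(n - 1.0) + EULER_GAMMA
    return float(2.0 * h - 2.0 * (n - 1.0) / n)


@dataclass
class _Tree:
    """One isolation tree in flat-array form.

    ``left``/``right`` are child node indices, ``-1`` marking a leaf.  For
    leaves, ``adjust`` holds ``harmonic_c(leaf size)`` — the expected extra
    depth had the leaf's points been split to completion.
    """

    normals: np.ndarray   # (k, d)
    intercepts: np.ndarray  # (k, d)
    left: np.ndarray      # (k,) int
    right: np.ndarray     # (k,) int
    adjust: np.ndarray    # (k,) float
    n_points: np.ndarray  # (k,) int


@dataclass
class EifModel:
    """A fitted extended-isolation-forest ensemble."""

    n_trees: int
    psi: int
    max_depth: int
    dim: int
    seed: int
    trees: list[_Tree] = field(default_factory=list)

    @property
    def c_psi(self) -> float:
        return harmonic_c(self.psi)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "ribopause-eif",
            "version": 1,
            "n_trees": self.n_trees,
            "psi": self.psi,
            "max_depth": self.max_depth,
            "dim": self.dim,
            "seed": self.seed,
            "trees": [
                {
                    "normals": t.normals.tolist(),
                    "intercepts": t.intercepts.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "adjust": t.adjust.tolist(),
                    "n_points": t.n_points.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EifModel":
        d = json.loads(text)
        if d.get("format") != "ribopause-eif" or d.get("version") != 1:
            raise ValueError("unrecognized EIF model dump")
        model = cls(
            n_trees=d["n_trees"], psi=d["psi"], max_depth=d["max_depth"],
            dim=d["dim"], seed=d["seed"],
        )
        for td in d["trees"]:
            model.trees.append(
                _Tree(
                    normals=np.array(td["normals"], dtype=float),
                    intercepts=np.array(td["intercepts"], dtype=float),
                    left=np.array(td["left"], dtype=np.int64),
                    right=np.array(td["right"], dtype=np.int64),
                    adjust=np.array(td["adjust"], dtype=float),
                    n_points=np.array(td["n_points"], dtype=np.int64),
                )
            )
        return model


def _build_tree(X: np.ndarray, rng: np.random.Generator, max_depth: int) -> _Tree:
    d = X.shape[1]
    normals: list[np.ndarray] = []
    intercepts: list[np.ndarray] = []
    left: list[int] = []
    right: list[int] = []
    adjust: list[float] = []
    n_points: list[int] = []

    def new_node() -> int:
        normals.append(np.zeros(d))
        intercepts.append(np.zeros(d))
        left.append(-1)
        right.append(-1)
        adjust.append(0.0)
        n_points.append(0)
        return len(left) - 1

    # explicit stack; processing order is fixed so the draw sequence is
    # reproducible for a given generator state
    root = new_node()
    stack: list[tuple[int, np.ndarray, int]] = [(root, X, 0)]
    while stack:
        node, pts, depth = stack.pop()
        n = pts.shape[0]
        n_points[node] = n
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        if depth >= max_depth or n <= 1 or np.all(lo == hi):
            adjust[node] = harmonic_c(max(n, 1))
            continue
        # random hyperplane: normal uniform on the unit sphere, intercept
        # uniform in the node's bounding box; degenerate draws (all points
        # on one side) still terminate because equal-coordinate boxes are
        # caught above and splits shrink the box
        while True:
            nv = rng.normal(size=d)
            norm = np.linalg.norm(nv)
            if norm > 0:
                nv /= norm
                break
        p = rng.uniform(lo, hi)
        side = (pts - p) @ nv <= 0.0
        if side.all() or not side.any():
            # plane missed the point set (possible with ties on the box
            # boundary): treat as an unresolved leaf
            adjust[node] = harmonic_c(n)
            continue
        normals[node] = nv
        intercepts[node] = p
        l_id = new_node()
        r_id = new_node()
        left[node] = l_id
        right[node] = r_id
        stack.append((r_id, pts[~side], depth + 1))
        stack.append((l_id, pts[side], depth + 1))

    return _Tree(
        normals=np.array(normals),
        intercepts=np.array(intercepts),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        adjust=np.array(adjust),
        n_points=np.array(n_points, dtype=np.int64),
    )


def fit_eif(
    points: np.ndarray,
    n_trees: int = 200,
    psi: int | None = None,
    seed: int = 0,
) -> EifModel:
    """Fit an extended isolation forest on ``points`` (n x d, d >= 2).

    Each tree is grown on a uniform subsample of size ``psi`` drawn without
    replacement, to depth at most ``ceil(log2(psi))``.  ``psi`` defaults to
    min(256, n) and is clamped to ``n`` when larger.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("points must be an n x d array with d >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if psi is None:
        psi = min(256, n)
    if psi > n:
        import warnings

        warnings.warn(f"psi={psi} > n={n}; clamping to n")
        psi = n
    if psi < 2:
        raise ValueError("psi must be >= 2")
    max_depth = int(np.ceil(np.log2(psi)))
    model = EifModel(
        n_trees=n_trees, psi=psi, max_depth=max_depth, dim=X.shape[1], seed=seed
    )
    children = np.random.SeedSequence(seed).spawn(n_trees)
    for t in range(n_trees):
        rng = np.random.default_rng(children[t])
        idx = rng.choice(n, size=psi, replace=False)
        model.trees.append(_build_tree(X[idx], rng, max_depth))
    return model


def _flatten_forest(model: "EifModel"):
    """Concatenate all trees into flat arrays with global node indices."""
    normals, intercepts, left, right, adjust, roots = [], [], [], [], [], []
    offset = 0
    for t in model.trees:
        k = len(t.left)
        roots.append(offset)
        normals.append(t.normals)
        intercepts.append(t.intercepts)
        shift = np.where(t.left >= 0, t.left + offset, -1)
        left.append(shift)
        right.append(np.where(t.right >= 0, t.right + offset, -1))
        adjust.append(t.adjust)
        offset += k
    return (
        np.concatenate(normals),
        np.concatenate(intercepts),
        np.concatenate(left),
        np.concatenate(right),
        np.concatenate(adjust),
        np.array(roots, dtype=np.int64),
    )


try:  # compiled hot loop; the numpy path below stays as reference/fallback
    from numba import njit

    @njit(cache=False)
    def _paths_kernel(X, normals, intercepts, left, right, adjust, roots):
        m, d = X.shape
        n_trees = roots.shape[0]
        out = np.empty(m)
        for i in range(m):
            total = 0.0
            for t in range(n_trees):
                node = roots[t]
                depth = 0.0
                while left[node] >= 0:
                    proj = 0.0
                    for k in range(d):
                        proj += (X[i, k] - intercepts[node, k]) * normals[node, k]
                    node = left[node] if proj <= 0.0 else right[node]
                    depth += 1.0
                total += depth + adjust[node]
            out[i] = total / n_trees
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    _HAVE_NUMBA = False


def _tree_paths(tree: _Tree, X: np.ndarray) -> np.ndarray:
    """Vectorized path length of every row of X through one tree."""
    m = X.shape[0]
    node = np.zeros(m, dtype=np.int64)
    depth = np.zeros(m, dtype=float)
    active = tree.left[node] >= 0
    while active.any():
        idx = np.nonzero(active)[0]
        cur = node[idx]
        proj = np.einsum(
            "ij,ij->i", X[idx] - tree.intercepts[cur], tree.normals[cur]
        )
        nxt = np.where(proj <= 0.0, tree.left[cur], tree.right[cur])
        node[idx] = nxt
        depth[idx] += 1.0
        active[idx] = tree.left[nxt] >= 0
    return depth + tree.adjust[node]


def mean_path_length(
    model: EifModel, points: np.ndarray, compiled: bool = True
) -> np.ndarray:
    """Mean per-tree isolation path length of each query point.

    ``compiled=False`` forces the vectorized numpy traversal; both paths
    implement the identical tree walk.
    """
    X = np.atleast_2d(np.ascontiguousarray(points, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(f"expected dimension {model.dim}, got {X.shape[1]}")
    if compiled and _HAVE_NUMBA:
        return _paths_kernel(X, *_flatten_forest(model))
    total = np.zeros(X.shape[0])
    for tree in model.trees:
        total += _tree_paths(tree, X)
    return total / model.n_trees


def anomaly_score(model: EifModel, points: np.ndarray) -> np.ndarray:
    """Anomaly score ``2**(-mean_path / c(psi))`` for one or many points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    mp = mean_path_length(model, pts)
    c = model.c_psi
    if c <= 0:  # psi == 1 cannot happen (psi >= 2), but guard anyway
        s = np.ones_like(mp)
    else:
        s = np.power(2.0, -mp / c)
    return float(s[0]) if single else s
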