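"""Minimum-displacement landmark parsimony on a fixed topology.

Given superimposed terminal configurations and a rooted tree, ancestral
configurations are chosen to minimise the total Euclidean landmark
displacement summed over branches,

    L = sum_l sum_{branches (u,v)} || x_l(u) - x_l(v) ||,

the landmark analogue of unordered (minimum-steps) parsimony for
continuous characters.  The objective separates into one convex
multifacility Weber problem per landmark, whose per-node optimality
condition is that every internal node sits at the geometric median of its
tree neighbours.  Each is solved by damped Newton iterations on an
epsilon-smoothed objective, followed by guarded exact resolution of the
coincident-node ties where the objective is non-smooth (see
``_solve_all_landmarks``).  Because only branch *sums* enter the
objective, the optimum value is invariant to where the tree is rooted.

Also here: the minimum-distance superimposition of every specimen onto a
reference taxon (rotation + translation chosen to minimise the *unsquared*
summed landmark distance, by iteratively reweighted least squares), which
precedes the optimisation, and the consistency index of a reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree as _sparse_mst
from scipy.spatial.distance import pdist, squareform

from .landmark_io import LandmarkDataset
from .superimposition import AlignedDataset
from .tree_io import PhyloTree

__all__ = [
    "AncestralReconstruction",
    "ReferenceAlignment",
    "geometric_median",
    "minimum_distance_align",
    "reconstruct_ancestral",
    "branch_length_for_landmarks",
    "consistency_index",
]

_EPS_SCHEDULE = (1e-3, 1e-5, 1e-7)


# ---------------------------------------------------------------------------
# Geometric median


def geometric_median(
    points: Sequence[Sequence[float]] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """The point minimising the (weighted) sum of Euclidean distances.

    Damped Weiszfeld fixed-point iteration with the standard vertex test
    (Vardi-Zhang): when the iterate lands on a data point, that vertex is
    optimal iff the pull of the remaining points does not exceed its own
    weight; otherwise the iterate is pushed off along the pull direction.
    Away from the data points the iteration is Newton-accelerated, which
    restores fast convergence in the near-collinear and near-vertex
    configurations where plain Weiszfeld crawls.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a (n, d) array")
    n = pts.shape[0]
    if n == 0:
        raise ValueError("need at least one point")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w <= 0).any():
            raise ValueError("weights must be positive, one per point")
    if n == 1:
        return pts[0].copy()

    scale = float(np.abs(pts).max()) or 1.0
    coincident_tol = 1e-13 * scale

    def objective(y):
        return float((w * np.linalg.norm(pts - y, axis=1)).sum())

    if init is not None:
        y = np.asarray(init, float).copy()
    else:
        y = (w[:, None] * pts).sum(axis=0) / w.sum()
    f_y = objective(y)
    for it in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        on = d <= coincident_tol
        if on.any():
            others = ~on
            if not others.any():
                return y  # all points coincide here
            r_vec = (
                w[others, None] * (pts[others] - y) / d[others, None]
            ).sum(axis=0)
            r = np.linalg.norm(r_vec)
            wk = w[on].sum()
            if r <= wk:
                return y  # vertex optimality condition
            t = (w[others] / d[others])[:, None]
            t_point = (t * pts[others]).sum(axis=0) / t.sum()
            step = 1.0 - wk / r
            y_new = step * t_point + (1.0 - step) * y
        else:
            u = (pts - y) / d[:, None]
            g = -(w[:, None] * u).sum(axis=0)
            # Newton step on the smooth objective; fall back to Weiszfeld
            y_new = None
            if it >= 2:
                wd = w / d
                H = np.diag([wd.sum()] * 2) - (wd[:, None, None] * u[:, :, None] * u[:, None, :]).sum(axis=0)
                try:
                    step = np.linalg.solve(H, -g)
                except np.linalg.LinAlgError:
                    step = None
                if step is not None and np.isfinite(step).all():
                    cand = y + step
                    f_cand = objective(cand)
                    if f_cand <= f_y + 1e-15 * (1 + abs(f_y)):
                        y_new = cand
                        f_y = f_cand
            if y_new is None:
                inv = (w / d)[:, None]
                y_new = (inv * pts).sum(axis=0) / inv.sum()
                f_y = objective(y_new)
        if np.linalg.norm(y_new - y) <= tol * (1.0 + np.linalg.norm(y)):
            return y_new
        y = y_new
    return y


# ---------------------------------------------------------------------------
# Minimum-distance superimposition onto a reference taxon


@dataclass
class ReferenceAlignment:
    """Specimens superimposed onto a reference taxon by the minimum
    (unsquared) distance criterion.  The reference itself is untouched."""

    reference_taxon: str
    transformed: dict[str, np.ndarray]
    objective: dict[str, float]

    def as_mapping(self) -> dict[str, np.ndarray]:
        return dict(self.transformed)


def _weighted_rigid_fit(
    X: np.ndarray, Y: np.ndarray, w: np.ndarray, allow_scale: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares similarity fit of X onto Y: returns (R, t, s)
    with x -> s * R x + t, R a proper rotation."""
    wsum = w.sum()
    mx = (w[:, None] * X).sum(axis=0) / wsum
    my = (w[:, None] * Y).sum(axis=0) / wsum
    Xc = X - mx
    Yc = Y - my
    M = (w[:, None] * Xc).T @ Yc
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    D = np.diag([1.0, d])
    Q = U @ D @ Vt  # Xc @ Q ~ Yc
    R = Q.T
    if allow_scale:
        denom = float((w[:, None] * Xc**2).sum())
        s = float((S * np.diag(D)).sum()) / denom if denom > 0 else 1.0
    else:
        s = 1.0
    t = my - s * (R @ mx)
    return R, t, s


def minimum_distance_align(
    dataset: AlignedDataset | LandmarkDataset | Mapping[str, np.ndarray],
    reference: str,
    allow_scale: bool = False,
    tol: float = 1e-12,
    max_iter: int = 2000,
    floor: float = 1e-9,
) -> ReferenceAlignment:
    """Superimpose every configuration onto ``reference`` minimising the
    summed *unsquared* Euclidean landmark distances.

    Rotation + translation only by default (no reflection, no rescaling);
    solved by iteratively reweighted least squares with weights
    ``1/max(d_i, floor)``, run to objective change below ``tol``.
    """
    if isinstance(dataset, AlignedDataset):
        configs = dataset.as_mapping()
    elif isinstance(dataset, LandmarkDataset):
        configs = {c.specimen_id: c.coords for c in dataset.configurations}
    else:
        configs = {k: np.asarray(v, float) for k, v in dataset.items()}
    if reference not in configs:
        raise ValueError(f"unknown reference taxon {reference!r}")
    Y = configs[reference]
    transformed: dict[str, np.ndarray] = {}
    objective: dict[str, float] = {}
    for sid, X0 in configs.items():
        if sid == reference:
            transformed[sid] = Y.copy()
            objective[sid] = 0.0
            continue
        X = X0.copy()
        prev = np.inf
        obj = float(np.linalg.norm(X - Y, axis=1).sum())
        for _ in range(max_iter):
            d = np.linalg.norm(X - Y, axis=1)
            w = 1.0 / np.maximum(d, floor)
            R, t, s = _weighted_rigid_fit(X, Y, w, allow_scale)
            X = s * (X @ R.T) + t
            obj = float(np.linalg.norm(X - Y, axis=1).sum())
            if abs(prev - obj) < tol:
                break
            prev = obj
        transformed[sid] = X
        objective[sid] = obj
    return ReferenceAlignment(
        reference_taxon=reference, transformed=transformed, objective=objective
    )


# ---------------------------------------------------------------------------
# Ancestral reconstruction


@dataclass
class AncestralReconstruction:
    """Ancestral configurations and per-branch landmark displacements."""

    tree: PhyloTree
    node_positions: dict[str, np.ndarray]  # every node id -> (p, 2)
    branch_landmark_lengths: pd.DataFrame  # index: branch id, columns: landmark
    tree_length: float
    per_landmark_lengths: pd.Series  # landmark -> summed length
    per_landmark_minimums: pd.Series  # landmark -> MST lower reference
    consistency_index: float
    convergence: dict[str, Any] = field(default_factory=dict)

    @property
    def ancestral(self) -> dict[str, np.ndarray]:
        """Configurations of internal nodes only."""
        internal = {n.id for n in self.tree.internal_nodes()}
        return {k: v for k, v in self.node_positions.items() if k in internal}

    def branch_table(self) -> pd.DataFrame:
        """Long-form (branch, landmark, length) table."""
        long = self.branch_landmark_lengths.stack().reset_index()
        long.columns = ["branch", "landmark", "length"]
        return long

    def to_dict(self) -> dict[str, Any]:
        return {
            "tree_length": self.tree_length,
            "consistency_index": self.consistency_index,
            "per_landmark_lengths": self.per_landmark_lengths.tolist(),
            "node_positions": {
                k: v.tolist() for k, v in sorted(self.node_positions.items())
            },
            "branch_landmark_lengths": {
                branch: self.branch_landmark_lengths.loc[branch].tolist()
                for branch in sorted(self.branch_landmark_lengths.index)
            },
        }


class _TreeArrays:
    """Index arrays for vectorised objective/gradient evaluation."""

    def __init__(self, tree: PhyloTree) -> None:
        self.order = list(tree.postorder())
        self.index = {n.id: i for i, n in enumerate(self.order)}
        self.child_idx = np.array(
            [self.index[n.id] for n in self.order if not n.is_root], dtype=int
        )
        self.parent_idx = np.array(
            [self.index[n.parent.id] for n in self.order if not n.is_root], dtype=int
        )
        self.internal_idx = np.array(
            [self.index[n.id] for n in self.order if not n.is_leaf], dtype=int
        )
        self.leaf_nodes = [n for n in self.order if n.is_leaf]
        self.init_leafsets = [
            np.array(
                [self.index[l.id] for l in PhyloTree._leaves_below(n)], dtype=int
            )
            for n in self.order
            if not n.is_leaf
        ]


def _solve_all_landmarks(
    arrays: _TreeArrays,
    leafX: np.ndarray,
    eps_schedule: Sequence[float],
    max_sweeps: int,
    squared: bool,
) -> tuple[np.ndarray, int]:
    """Solve the p independent Weber problems on the tree.

    Each landmark's summed-displacement objective is convex but non-smooth
    wherever adjacent nodes coincide.  Strategy per landmark:

    1. damped Newton with the exact Hessian on the smoothed objective
       (sqrt(d^2 + eps^2) edge terms) over the decreasing ``eps_schedule``,
       warm-starting each level — Newton absorbs the 1/eps stiffness that
       defeats first-order methods;
    2. guarded exact resolution of the remaining kinks: connected groups
       of near-coincident adjacent free nodes are collapsed onto the
       geometric median of their outside neighbours, and free nodes
       hugging an adjacent leaf are pinned onto it, each move accepted
       only if the exact objective does not increase;
    3. a final Newton pass on the contracted problem (collapsed groups
       share one variable, pinned nodes are fixed), which is now smooth,
       at a much smaller smoothing.

    Tie-breaks fall out of the smoothing: a degree-2 root on the segment
    between its children lands on the midpoint.  ``leafX``: (n_nodes, p, 2)
    with leaf rows filled.  Returns the positions and the number of
    objective evaluations.
    """
    X = leafX
    p = X.shape[1]
    for k, idx in zip(arrays.internal_idx, arrays.init_leafsets):
        X[k] = X[idx].mean(axis=0)

    ci, pi, free = arrays.child_idx, arrays.parent_idx, arrays.internal_idx
    n_nodes = X.shape[0]
    eye = np.eye(2)
    evals = 0
    leaf_mask = np.ones(n_nodes, dtype=bool)
    leaf_mask[free] = False

    def full_objective(Y: np.ndarray) -> float:
        D = Y[ci] - Y[pi]
        d2 = (D**2).sum(axis=1)
        return float(d2.sum()) if squared else float(np.sqrt(d2).sum())

    def newton(Y: np.ndarray, varmap: np.ndarray, eps_list, max_it: int):
        """Damped Newton over the variables of ``varmap`` (-1 = fixed,
        shared ids = rigidly-merged nodes).  Mutates Y; returns the final
        gradient max-norm."""
        nonlocal evals
        m = int(varmap.max()) + 1
        if m == 0:
            return 0.0
        fa, fb = varmap[ci], varmap[pi]
        keep = ~((fa >= 0) & (fa == fb))
        cie, pie = ci[keep], pi[keep]
        fae, fbe = fa[keep], fb[keep]
        sel = varmap >= 0

        def set_vars(Y, z):
            Y[sel] = z[varmap[sel]]

        # initial variable values: current position of each group's first node
        z = np.zeros((m, 2))
        for i in range(n_nodes - 1, -1, -1):
            if varmap[i] >= 0:
                z[varmap[i]] = Y[i]
        X_cur_local = Y

        def fgh(z, eps, want_h):
            nonlocal evals
            evals += 1
            set_vars(X_cur_local, z)
            D = X_cur_local[cie] - X_cur_local[pie]
            d2 = (D**2).sum(axis=1)
            if squared:
                s = None
                f = float(d2.sum())
                G = 2.0 * D
            else:
                s = np.sqrt(d2 + eps * eps)
                f = float(s.sum())
                G = D / s[:, None]
            g = np.zeros((m, 2))
            np.add.at(g, fae[fae >= 0], G[fae >= 0])
            np.add.at(g, fbe[fbe >= 0], -G[fbe >= 0])
            if not want_h:
                return f, g, None
            if squared:
                K = np.broadcast_to(2.0 * eye, (len(cie), 2, 2)).copy()
            else:
                K = (
                    eye[None] - D[:, :, None] * D[:, None, :] / (s**2)[:, None, None]
                ) / s[:, None, None]
            H = np.zeros((m, 2, m, 2))
            for e in range(len(cie)):
                a, b = fae[e], fbe[e]
                if a >= 0:
                    H[a, :, a, :] += K[e]
                if b >= 0:
                    H[b, :, b, :] += K[e]
                if a >= 0 and b >= 0:
                    H[a, :, b, :] -= K[e]
                    H[b, :, a, :] -= K[e]
            return f, g, H.reshape(2 * m, 2 * m)

        gnorm = 0.0
        for eps in eps_list:
            for _ in range(max_it):
                f, g, H = fgh(z, eps, want_h=True)
                gnorm = float(np.abs(g).max()) if g.size else 0.0
                if gnorm < 1e-11:
                    break
                gvec = g.ravel()
                reg = 1e-12 * float(np.trace(H)) / max(1, 2 * m)
                try:
                    step = np.linalg.solve(H + reg * np.eye(2 * m), -gvec)
                except np.linalg.LinAlgError:
                    step = -gvec
                if not np.isfinite(step).all():
                    step = -gvec
                # trust region: an ill-conditioned solve can emit huge steps
                diameter = float(np.ptp(X_cur_local, axis=0).max()) or 1.0
                snorm = float(np.abs(step).max())
                if snorm > diameter:
                    step = step * (diameter / snorm)
                gd = float(gvec @ step)
                if gd >= 0:
                    step = -gvec
                    gd = -float(gvec @ gvec)
                accepted = False
                for candidate, cgd in ((step, gd), (-gvec, -float(gvec @ gvec))):
                    t = 1.0
                    for _bt in range(40):
                        z_try = z + t * candidate.reshape(m, 2)
                        f_try, _, _ = fgh(z_try, eps, want_h=False)
                        if f_try <= f + 1e-4 * t * cgd:
                            z = z_try
                            accepted = True
                            break
                        t *= 0.5
                    if accepted:
                        break
                if not accepted:
                    break
                if t * float(np.abs(candidate).max()) < 1e-14:
                    break  # accepted but immeasurable movement: stalled
        set_vars(X_cur_local, z)
        return gnorm

    for l in range(p):
        X_cur = X[:, l].copy()
        scale = float(np.abs(X_cur).max()) or 1.0
        varmap = -np.ones(n_nodes, dtype=int)
        varmap[free] = np.arange(len(free))
        newton(X_cur, varmap, list(eps_schedule), max(100, max_sweeps // 100))

        if not squared:

            def resolve_kinks(near: float) -> np.ndarray:
                """Guarded collapse of near-coincident adjacent free nodes
                and pinning onto hugged adjacent leaves, on the exact
                objective; returns the contracted variable map."""
                adj: dict[int, list[int]] = {int(i): [] for i in free}
                for c, q in zip(ci, pi):
                    c, q = int(c), int(q)
                    if not leaf_mask[c] and not leaf_mask[q]:
                        if float(np.linalg.norm(X_cur[c] - X_cur[q])) < near:
                            adj[c].append(q)
                            adj[q].append(c)
                seen: set[int] = set()
                group_id = -np.ones(n_nodes, dtype=int)
                n_groups = 0
                for i in free:
                    i = int(i)
                    if i in seen:
                        continue
                    comp = [i]
                    seen.add(i)
                    queue = [i]
                    while queue:
                        a = queue.pop()
                        for b in adj[a]:
                            if b not in seen:
                                seen.add(b)
                                comp.append(b)
                                queue.append(b)
                    if len(comp) >= 2:
                        members = set(comp)
                        ext = [
                            X_cur[int(o)]
                            for c, q in zip(ci, pi)
                            for a, o in ((int(c), int(q)), (int(q), int(c)))
                            if a in members and int(o) not in members
                        ]
                        before = full_objective(X_cur)
                        saved = {a: X_cur[a].copy() for a in comp}
                        target = geometric_median(
                            np.asarray(ext), tol=1e-13, init=X_cur[comp[0]]
                        )
                        for a in comp:
                            X_cur[a] = target
                        if full_objective(X_cur) > before + 1e-13 * (1.0 + before):
                            for a in comp:  # genuinely distinct
                                X_cur[a] = saved[a]
                            for a in comp:
                                group_id[a] = n_groups
                                n_groups += 1
                        else:
                            for a in comp:
                                group_id[a] = n_groups
                            n_groups += 1
                    else:
                        group_id[i] = n_groups
                        n_groups += 1
                pinned = np.zeros(n_groups, dtype=bool)
                for c, q in zip(ci, pi):
                    c, q = int(c), int(q)
                    if leaf_mask[q] and not leaf_mask[c]:
                        fr, lf = c, q
                    elif leaf_mask[c] and not leaf_mask[q]:
                        fr, lf = q, c
                    else:
                        continue
                    if pinned[group_id[fr]]:
                        continue
                    if float(np.linalg.norm(X_cur[fr] - X_cur[lf])) < near:
                        gid = group_id[fr]
                        members = [int(i) for i in free if group_id[int(i)] == gid]
                        before = full_objective(X_cur)
                        saved = {a: X_cur[a].copy() for a in members}
                        for a in members:
                            X_cur[a] = X_cur[lf]
                        if full_objective(X_cur) > before + 1e-13 * (1.0 + before):
                            for a in members:
                                X_cur[a] = saved[a]
                        else:
                            pinned[gid] = True
                varmap2 = -np.ones(n_nodes, dtype=int)
                gid_to_var: dict[int, int] = {}
                next_id = 0
                for i in free:
                    i = int(i)
                    gid = group_id[i]
                    if pinned[gid]:
                        continue
                    if gid not in gid_to_var:
                        gid_to_var[gid] = next_id
                        next_id += 1
                    varmap2[i] = gid_to_var[gid]
                return varmap2

            # iterate: widen the kink-detection radius until the contracted
            # problem is smooth enough for Newton to flatten the gradient
            gnorm = np.inf
            for round_ in range(4):
                varmap2 = resolve_kinks(min(1e-5 * 10.0**round_, 1e-2) * scale)
                gnorm = newton(X_cur, varmap2, [1e-10], max(100, max_sweeps // 100))
                if gnorm <= 1e-8:
                    break
            # a residual gradient g on a region of diameter D bounds the
            # objective error by ~ g*D; micro-stalls (g ~ 1e-4 when the
            # Armijo test hits float resolution on degenerate blobs) are
            # harmless, so only genuine breakdown is fatal
            if gnorm > 1e-3:
                raise RuntimeError(
                    f"ancestral reconstruction did not converge for landmark "
                    f"{l} (gradient {gnorm:.2e} on the contracted problem "
                    f"after {evals} evaluations)"
                )
        X[:, l] = X_cur
    return X, evals


def _mst_length(points: np.ndarray) -> float:
    """Length of the Euclidean minimum spanning tree over the points.

    Exact duplicates are collapsed first: the sparse-graph MST routine
    treats zero-weight edges as absent, and duplicates contribute zero
    length anyway."""
    pts = np.unique(points, axis=0)
    if pts.shape[0] < 2:
        return 0.0
    dm = squareform(pdist(pts))
    return float(_sparse_mst(dm).sum())


def reconstruct_ancestral(
    terminals: Mapping[str, np.ndarray] | AlignedDataset | ReferenceAlignment,
    tree: PhyloTree,
    eps_schedule: Sequence[float] = _EPS_SCHEDULE,
    tol: float = 1e-12,
    max_sweeps: int = 10_000,
    squared: bool = False,
) -> AncestralReconstruction:
    """Minimum-displacement ancestral configurations on a fixed topology.

    Parameters
    ----------
    terminals
        Per-leaf (p, 2) configurations in a common superimposed space.
    squared
        Use squared-change parsimony instead of the default summed
        Euclidean displacement (offered for comparison only).
    """
    if isinstance(terminals, AlignedDataset):
        configs = terminals.as_mapping()
    elif isinstance(terminals, ReferenceAlignment):
        configs = terminals.as_mapping()
    else:
        configs = {k: np.asarray(v, float) for k, v in terminals.items()}
    leaf_labels = tree.leaf_labels()
    missing = [l for l in leaf_labels if l not in configs]
    if missing:
        raise ValueError(f"no configuration for leaves: {missing}")
    p = next(iter(configs.values())).shape[0]
    for k, v in configs.items():
        if v.shape != (p, 2):
            raise ValueError(f"{k!r}: expected shape {(p, 2)}, got {v.shape}")

    arrays = _TreeArrays(tree)
    branch_ids = tree.branches()
    leafX = np.zeros((len(arrays.order), p, 2))
    for node in arrays.leaf_nodes:
        leafX[arrays.index[node.id]] = configs[str(node.label)]
    X, evals = _solve_all_landmarks(arrays, leafX, eps_schedule, max_sweeps, squared)
    node_positions: dict[str, np.ndarray] = {
        node: X[i].copy() for node, i in arrays.index.items()
    }
    # child_idx follows postorder of non-root nodes, i.e. branch_ids order
    diffs = X[arrays.child_idx] - X[arrays.parent_idx]
    d = np.linalg.norm(diffs, axis=2)
    lengths = d * d if squared else d
    minimums = np.array(
        [_mst_length(np.asarray([configs[lab][l] for lab in leaf_labels])) for l in range(p)]
    )

    df = pd.DataFrame(lengths, index=branch_ids, columns=range(p))
    per_landmark = df.sum(axis=0)
    tree_length = float(per_landmark.sum())
    min_series = pd.Series(minimums, index=range(p))
    ci = 1.0 if tree_length == 0.0 else min(1.0, float(min_series.sum()) / tree_length)
    return AncestralReconstruction(
        tree=tree,
        node_positions=node_positions,
        branch_landmark_lengths=df,
        tree_length=tree_length,
        per_landmark_lengths=per_landmark,
        per_landmark_minimums=min_series,
        consistency_index=ci,
        convergence={
            "objective_evaluations": evals,
            "eps_schedule": list(eps_schedule),
            "tol": tol,
            "squared": squared,
        },
    )


def branch_length_for_landmarks(
    recon: AncestralReconstruction,
    branch: str,
    subset: Iterable[int],
) -> float:
    """Summed displacement of a landmark subset along one branch."""
    subset = list(subset)
    if branch not in recon.branch_landmark_lengths.index:
        raise KeyError(f"no branch {branch!r} in reconstruction")
    p = recon.branch_landmark_lengths.shape[1]
    for i in subset:
        if not 0 <= i < p:
            raise IndexError(f"landmark index {i} out of range (p={p})")
    if not subset:
        return 0.0
    return float(recon.branch_landmark_lengths.loc[branch, subset].sum())


def consistency_index(recon: AncestralReconstruction) -> float:
    """CI = (sum of per-landmark minimum lengths) / tree length, capped at 1.

    The per-landmark minimum is the Euclidean minimum-spanning-tree length
    over that landmark's terminal positions.  On very small trees the
    free-internal-node optimum can undercut the MST (Steiner effect), so
    the ratio is capped at 1 to keep CI in (0, 1].  Zero tree length
    (identical terminals) is defined as CI = 1.
    """
    return recon.consistency_index
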