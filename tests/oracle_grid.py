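"""Independent oracle for the single-landmark tree-length optimum.

Block-coordinate *exhaustive grid search*: each internal node in turn is
placed on the best point of a full 1e-3 grid over [0, 1]^2 given its tree
neighbours, and — because single-node moves can jam on the nonsmooth
ridges where internal nodes coincide — every connected subset of internal
nodes is additionally offered a rigid translation over the same grid.
Sweeps repeat until nothing improves, then a local 1e-4 grid polish runs.
The per-landmark objective is convex in all internal positions jointly, so
no restart scheme is needed; the subset moves cover every nonsmooth escape
direction.  Shares nothing with the package's smoothed L-BFGS solver.
"""

from itertools import combinations

import numpy as np


def _grid(lo=0.0, hi=1.0, step=1e-3):
    ax = np.arange(lo, hi + step / 2, step)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def grid_search_tree_length(tree, leaf_xy, coarse=1e-3, fine=1e-4, max_sweeps=500):
    """Minimum summed branch length for one landmark, by grid search.

    ``leaf_xy``: leaf label -> (2,) position, all inside [0, 1]^2.
    """
    pos = {n.id: np.asarray(leaf_xy[str(n.label)], float) for n in tree.leaves()}
    internal = tree.internal_nodes()
    all_leaves = [np.asarray(v, float) for v in leaf_xy.values()]
    for n in internal:
        pos[n.id] = np.mean(all_leaves, axis=0)

    def total_length():
        t = 0.0
        for n in tree.postorder():
            if not n.is_root:
                t += float(np.linalg.norm(pos[n.id] - pos[n.parent.id]))
        return t

    def adjacent(a, b):
        return b is a.parent or a is b.parent

    groups = [[n] for n in internal]
    for size in range(2, len(internal) + 1):
        for combo in combinations(internal, size):
            # connected in the tree?
            reached = {combo[0].id}
            frontier = [combo[0]]
            members = {n.id: n for n in combo}
            while frontier:
                n = frontier.pop()
                for m in combo:
                    if m.id not in reached and adjacent(n, m):
                        reached.add(m.id)
                        frontier.append(m)
            if len(reached) == size:
                groups.append(list(combo))

    def group_objective_on(points, group):
        """Objective contribution of the group's external edges when the
        group is rigidly translated so its first member sits at ``points``."""
        members = {n.id for n in group}
        total = np.zeros(points.shape[0])
        for n in group:
            off = pos[n.id] - pos[group[0].id]
            ext = [c for c in n.children if c.id not in members]
            if n.parent is not None and n.parent.id not in members:
                ext.append(n.parent)
            for e in ext:
                q = pos[e.id] - off
                total += np.hypot(points[:, 0] - q[0], points[:, 1] - q[1])
        return total

    def sweep(pointset_for):
        improved = False
        for group in groups:
            anchor = pos[group[0].id]
            points = pointset_for(anchor)
            vals = group_objective_on(points, group)
            current = float(group_objective_on(anchor[None], group)[0])
            j = int(np.argmin(vals))
            if vals[j] < current - 1e-12:
                shift = points[j] - anchor
                for n in group:
                    pos[n.id] = pos[n.id] + shift
                improved = True
        return improved

    grid = _grid(step=coarse)
    for _ in range(max_sweeps):
        if not sweep(lambda _p: grid):
            break

    def local(p):
        ax = np.arange(p[0] - 2 * coarse, p[0] + 2 * coarse + fine / 2, fine)
        ay = np.arange(p[1] - 2 * coarse, p[1] + 2 * coarse + fine / 2, fine)
        gx, gy = np.meshgrid(ax, ay, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    for _ in range(max_sweeps):
        if not sweep(local):
            break

    return total_length()
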