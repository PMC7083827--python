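"""Minimal diagnostic plots: a PC1-PC2 morphospace scatter and the
focal-branch displacement vectors over the ancestral configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hypothesis_test import displacement_vectors
from .landmark_parsimony import AncestralReconstruction
from .superimposition import MorphospaceSummary


def plot_morphospace(summary: MorphospaceSummary, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.scores[:, 0], summary.scores[:, 1], s=18, c="tab:blue")
    for sid, (x, y) in zip(summary.specimen_ids, summary.scores[:, :2]):
        ax.annotate(sid, (x, y), fontsize=6, alpha=0.7)
    tot = summary.eigenvalues.sum() or 1.0
    ax.set_xlabel(f"PC1 ({100 * summary.eigenvalues[0] / tot:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * summary.eigenvalues[1] / tot:.1f}%)")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_displacements(
    recon: AncestralReconstruction, branch: str, path: str | Path
) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    child = recon.tree.node(branch)
    parent_cfg = recon.node_positions[child.parent.id]
    vecs = displacement_vectors(recon, branch)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(parent_cfg[:, 0], parent_cfg[:, 1], c="0.5", s=20, label="ancestor")
    ax.quiver(
        parent_cfg[:, 0],
        parent_cfg[:, 1],
        vecs[:, 0],
        vecs[:, 1],
        angles="xy",
        scale_units="xy",
        scale=1,
        color="tab:blue",
        width=0.004,
    )
    ax.set_aspect("equal")
    ax.set_title(f"landmark displacement on branch {branch}")
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
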