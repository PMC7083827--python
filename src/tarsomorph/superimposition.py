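"""Generalized Procrustes analysis with sliding semilandmarks, and the
morphospace summaries (PCA, Sum of Variances) computed from the aligned
coordinates.

The alignment loop is the classical iterative scheme: centre every
configuration, scale it (to unit centroid size, or not at all in mm mode),
rotate it onto the current consensus with the SVD (Kabsch) solution, slide
the semilandmarks along their chord tangents toward the consensus under the
Procrustes-distance criterion, and update the consensus until it stops
moving.  The converged alignment is finally rotated into a canonical frame
(principal axes of the consensus, deterministic sign rule, proper rotation
only) so that the output is invariant to arbitrary rigid transforms — and,
in unit mode, rescalings — of the inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset, LandmarkScheme

__all__ = [
    "AlignedDataset",
    "MorphospaceSummary",
    "centroid_size",
    "optimal_rotation",
    "gpa_align",
    "slide_semilandmarks",
    "pca",
    "sum_of_variances",
]

logger = logging.getLogger(__name__)

SCALE_MODES = ("unit", "mm")


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 3:
        raise ValueError("centroid size requires at least 3 points")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincident")
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimising ||A @ R.T - B|| for centred A, B.

    Points transform as x -> R x.  Reflections are excluded: the returned
    matrix always has determinant +1 even when B is a reflected copy of A.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    M = A.T @ B  # cross-covariance
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, d])
    Q = U @ D @ Vt  # A @ Q ~ B
    return Q.T


@dataclass
class AlignedDataset:
    """Superimposed coordinates plus alignment provenance."""

    scheme: LandmarkScheme
    specimen_ids: list[str]
    aligned: np.ndarray  # (n, p, 2)
    consensus: np.ndarray  # (p, 2), coordinate-wise mean of `aligned`
    centroid_sizes: np.ndarray  # (n,), original sizes in input units
    scale_mode: str = "unit"
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def coords_of(self, specimen_id: str) -> np.ndarray:
        return self.aligned[self.specimen_ids.index(specimen_id)]

    def as_mapping(self) -> dict[str, np.ndarray]:
        return {sid: self.aligned[i] for i, sid in enumerate(self.specimen_ids)}

    def to_dataframe(self):
        """Specimen x coordinate table (x1, y1, x2, y2, ...)."""
        import pandas as pd

        p = self.aligned.shape[1]
        cols = [f"{ax}{i + 1}" for i in range(p) for ax in ("x", "y")]
        return pd.DataFrame(
            self.aligned.reshape(self.n_specimens, -1),
            index=self.specimen_ids,
            columns=cols,
        )


def _centre_scale(coords: np.ndarray, unit: bool) -> np.ndarray:
    out = coords - coords.mean(axis=0)
    if unit:
        out = out / np.sqrt((out**2).sum())
    return out


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus onto its principal axes.

    Deterministic sign rule: after rotation, the consensus point with the
    largest |x| has positive x.  The candidate frames differ by a half-turn,
    so the rule picks exactly one proper rotation.
    """
    X = consensus - consensus.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    R = Vt.copy()
    if np.linalg.det(R) < 0:
        R[1] = -R[1]
    Y = X @ R.T
    j = int(np.argmax(np.abs(Y[:, 0])))
    if Y[j, 0] < 0:
        R = -R  # half-turn; determinant unchanged
    return R


def _slide_pass(
    coords: np.ndarray, consensus: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Slide one specimen's semilandmarks toward the consensus.

    Each semilandmark moves along the line through its current position in
    the direction of the chord between its two neighbours, to the foot of
    the perpendicular from the corresponding consensus point — the
    Procrustes-distance sliding criterion.  Fixed landmarks never move.
    """
    out = coords.copy()
    for k, (a, b) in enumerate(scheme.semilandmark_neighbours):
        sl = scheme.n_landmarks + k
        tangent = coords[b] - coords[a]
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            warnings.warn(
                f"semilandmark {k}: coincident neighbours, left unmoved",
                stacklevel=3,
            )
            continue
        u = tangent / norm
        out[sl] = coords[sl] + np.dot(consensus[sl] - coords[sl], u) * u
    return out


def slide_semilandmarks(aligned: AlignedDataset) -> AlignedDataset:
    """Slide every specimen's semilandmarks against the current consensus."""
    if aligned.scheme.n_semilandmarks < 1:
        raise ValueError("scheme declares no semilandmarks")
    new = np.stack(
        [_slide_pass(x, aligned.consensus, aligned.scheme) for x in aligned.aligned]
    )
    prov = dict(aligned.provenance)
    prov["slid"] = True
    return AlignedDataset(
        scheme=aligned.scheme,
        specimen_ids=list(aligned.specimen_ids),
        aligned=new,
        consensus=new.mean(axis=0),
        centroid_sizes=aligned.centroid_sizes.copy(),
        scale_mode=aligned.scale_mode,
        provenance=prov,
    )


def gpa_align(
    dataset: LandmarkDataset,
    slide: bool = True,
    scale_mode: str = "unit",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes alignment of a landmark dataset.

    Parameters
    ----------
    slide
        Slide semilandmarks (if the scheme declares any) along their chord
        tangents under the Procrustes-distance criterion at each iteration.
    scale_mode
        ``"unit"`` scales every configuration to centroid size 1 (shape
        analysis); ``"mm"`` keeps the millimetre scale and only centres and
        rotates.
    tol
        Convergence: root-mean-square change of the consensus per point
        coordinate below this stops the loop.
    """
    if scale_mode not in SCALE_MODES:
        raise ValueError(f"scale_mode must be one of {SCALE_MODES}")
    if dataset.n_specimens < 2:
        raise ValueError("GPA requires at least 2 configurations")
    scheme = dataset.scheme
    unit = scale_mode == "unit"
    do_slide = slide and scheme.n_semilandmarks > 0

    raw = dataset.coords_array()
    sizes = np.array([centroid_size(x) for x in raw])
    coords = np.stack([_centre_scale(x, unit) for x in raw])

    # order-invariant, rotation-invariant initial consensus: average the
    # individually canonicalised shapes (a symmetric function of the set)
    canon = np.stack([x @ _canonical_rotation(x).T for x in coords])
    consensus = _centre_scale(canon.mean(axis=0), unit)
    objective_trajectory: list[float] = []
    converged = False
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # rotate everything onto the current consensus
        coords = np.stack([x @ optimal_rotation(x, consensus).T for x in coords])
        if do_slide:
            coords = np.stack([_slide_pass(x, consensus, scheme) for x in coords])
            # sliding perturbs location/size; restore the Procrustes frame
            coords = np.stack([_centre_scale(x, unit) for x in coords])
            coords = np.stack([x @ optimal_rotation(x, consensus).T for x in coords])
        objective_trajectory.append(float(((coords - consensus) ** 2).sum()))
        new_consensus = coords.mean(axis=0)
        new_consensus = _centre_scale(new_consensus, unit)
        # remove rotational drift of the frame before measuring change
        new_consensus = new_consensus @ optimal_rotation(new_consensus, consensus).T
        change = float(
            np.sqrt(((new_consensus - consensus) ** 2).mean())
        )
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        # typical with sliding, whose crawl along the chords has no strict
        # fixed point at this tolerance; recorded in provenance, not fatal
        logger.info(
            "GPA did not converge in %d iterations (last change %.3e)",
            max_iter,
            change,
        )
    # final strict pass so the stated frame invariants hold exactly
    coords = np.stack([_centre_scale(x, unit) for x in coords])
    coords = np.stack([x @ optimal_rotation(x, consensus).T for x in coords])
    # canonical orientation: output independent of input orientation
    R = _canonical_rotation(consensus)
    coords = coords @ R.T
    consensus_final = coords.mean(axis=0)

    return AlignedDataset(
        scheme=scheme,
        specimen_ids=dataset.specimen_ids,
        aligned=coords,
        consensus=consensus_final,
        centroid_sizes=sizes,
        scale_mode=scale_mode,
        provenance={
            "slid": do_slide,
            "scale_mode": scale_mode,
            "iterations": iterations,
            "final_change": change,
            "converged": converged,
            "objective_trajectory": objective_trajectory,
        },
    )


# ---------------------------------------------------------------------------
# Morphospace


@dataclass
class MorphospaceSummary:
    """Principal components of the aligned coordinates plus total variance."""

    specimen_ids: list[str]
    scores: np.ndarray  # (n, k), centred projections
    eigenvalues: np.ndarray  # (k,), descending variances
    sum_of_variances: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "specimen_ids": list(self.specimen_ids),
            "scores": self.scores.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "sum_of_variances": self.sum_of_variances,
        }


def sum_of_variances(aligned: AlignedDataset | np.ndarray, ddof: int = 1) -> float:
    """Disparity as the summed per-coordinate variance across specimens.

    The divisor convention is configurable (``ddof=1`` for the unbiased
    n-1 divisor, ``ddof=0`` for n).
    """
    X = aligned.aligned if isinstance(aligned, AlignedDataset) else np.asarray(aligned, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("sum of variances requires at least 2 specimens")
    flat = X.reshape(n, -1)
    return float(np.var(flat, axis=0, ddof=ddof).sum())


def pca(aligned: AlignedDataset, ddof: int = 1) -> MorphospaceSummary:
    """PCA of the flattened aligned coordinates (specimens x 2p).

    The eigenvalue sum equals the total coordinate variance (same divisor),
    so ``sum(eigenvalues) == sum_of_variances`` by the trace identity.
    """
    n = aligned.n_specimens
    if n < 3:
        raise ValueError("PCA requires at least 3 specimens")
    flat = aligned.aligned.reshape(n, -1)
    centred = flat - flat.mean(axis=0)
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - ddof)
    scores = centred @ Vt.T
    return MorphospaceSummary(
        specimen_ids=list(aligned.specimen_ids),
        scores=scores,
        eigenvalues=eigenvalues,
        sum_of_variances=sum_of_variances(aligned, ddof=ddof),
    )
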