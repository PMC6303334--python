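"""Landmark geometry: configurations, centroid size, partial GPA, tangent space.

The shape of a configuration of k landmarks in d dimensions is what remains
after translation, scale and rotation are removed.  Partial generalized
Procrustes analysis (GPA) centres each configuration, scales it to unit
centroid size and rotates it to minimise the summed squared distance to an
iteratively re-estimated consensus.  Aligned pre-shapes are then orthogonally
projected onto the linear tangent space at the consensus; all statistics
downstream operate on tangent coordinates.

Reflections are never part of the alignment: asymmetry is signal here, and
mirror images enter only through the explicit transform-and-relabel machinery
of :mod:`morphosym.symmetry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "AlignedSet",
    "centroid_size",
    "partial_gpa",
    "tangent_project",
    "procrustes_distance",
]


class GPAConvergenceError(RuntimeError):
    """Raised when the GPA consensus fails to stabilise within ``max_iter``."""

    def __init__(self, n_iter: int, change: float):
        self.n_iter = n_iter
        self.change = change
        super().__init__(
            f"GPA did not converge after {n_iter} iterations "
            f"(last consensus change {change:.3e})"
        )


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One unit's k x d matrix of landmark coordinates.

    Parameters
    ----------
    coords
        ``(k, d)`` array of Cartesian landmark positions, arbitrary units.
    labels
        Ordered landmark identifiers; defaults to ``1..k`` (landmark numbering
        is 1-based throughout, following morphometric convention).
    """

    coords: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (landmarks x dimensions)")
        k, d = coords.shape
        if k < 3:
            raise ValueError(f"need at least 3 landmarks, got {k}")
        if d not in (2, 3):
            raise ValueError(f"only 2-D or 3-D landmarks supported, got d={d}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite landmark coordinates")
        object.__setattr__(self, "coords", coords)
        labels = self.labels
        if labels is None:
            labels = tuple(range(1, k + 1))
        else:
            labels = tuple(labels)
            if len(labels) != k:
                raise ValueError("labels length must match number of landmarks")
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class AlignedSet:
    """Result of partial GPA followed (optionally) by tangent projection.

    Attributes
    ----------
    aligned
        ``(N, k, d)`` unit-size, centred, rotated pre-shapes.
    consensus
        ``(k, d)`` mean shape, unit centroid size.
    tangent_coords
        ``(N, k*d)`` row-vectorised tangent-space coordinates (``None`` until
        :func:`tangent_project` is applied).
    procrustes_ss
        Summed squared distances of aligned pre-shapes to the consensus.
    centroid_sizes
        ``(N,)`` original centroid sizes (recorded before scaling).
    n_iter
        GPA iterations used.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    procrustes_ss: float
    n_iter: int
    tangent_coords: np.ndarray | None = None
    ss_history: list | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def d(self) -> int:
        return self.aligned.shape[2]


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: root summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under coordinate
    scaling.  Raises on a degenerate configuration with all landmarks
    coincident (zero size).
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide (zero centroid size)")
    return size


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    size = np.sqrt(np.sum(centred**2))
    if size == 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centred / size, float(size)


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimising ||x @ R - target||_F."""
    d = x.shape[1]
    if d == 2:
        # closed form: angle from the cross/dot aggregates
        a = float(np.sum(x[:, 0] * target[:, 0] + x[:, 1] * target[:, 1]))
        b = float(np.sum(x[:, 0] * target[:, 1] - x[:, 1] * target[:, 0]))
        theta = np.arctan2(b, a)
        c, s = np.cos(theta), np.sin(theta)
        return np.array([[c, s], [-s, c]])
    # general d: SVD with determinant correction to exclude reflections
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _rotate_all_to(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate every pre-shape in ``(N,k,2)`` ``stack`` onto ``target`` (vectorised, 2-D)."""
    if stack.shape[2] != 2:
        return np.stack([x @ _optimal_rotation(x, target) for x in stack])
    a = np.einsum("nki,ki->n", stack, target)
    b = stack[:, :, 0] @ target[:, 1] - stack[:, :, 1] @ target[:, 0]
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(stack)
    out[:, :, 0] = c[:, None] * stack[:, :, 0] - s[:, None] * stack[:, :, 1]
    out[:, :, 1] = s[:, None] * stack[:, :, 0] + c[:, None] * stack[:, :, 1]
    return out


def partial_gpa(
    configs,
    tol: float = 1e-10,
    max_iter: int = 100,
    symmetrize_consensus=None,
) -> AlignedSet:
    """Partial generalized Procrustes analysis.

    Each configuration is centred, scaled to unit centroid size and rotated
    (rotation only, never reflection) to the consensus, which is re-estimated
    and re-normalised to unit size each iteration until its displacement
    falls below ``tol``.  The consensus is initialised from the first
    configuration, making runs deterministic.

    Parameters
    ----------
    configs
        Sequence of :class:`LandmarkConfiguration` (or ``(k, d)`` arrays) with
        identical ``k`` and ``d``; at least two.
    symmetrize_consensus
        Optional callable mapping a ``(k, d)`` consensus to a symmetrised
        copy, applied each iteration.  Used by the object-symmetry analyses to
        force a consensus that is exactly symmetric under the declared group.
    """
    mats = [c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, float) for c in configs]
    if len(mats) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"non-conformant configurations: shapes {sorted(shapes)}")

    sizes = np.empty(len(mats))
    stack = np.empty((len(mats),) + mats[0].shape)
    for i, m in enumerate(mats):
        stack[i], sizes[i] = _center_and_scale(m)

    consensus = stack[0].copy()
    if symmetrize_consensus is not None:
        consensus, _ = _center_and_scale(symmetrize_consensus(consensus))
    change = np.inf
    ss_history = []
    for it in range(1, max_iter + 1):
        stack = _rotate_all_to(stack, consensus)
        ss_history.append(float(np.sum((stack - consensus) ** 2)))
        new = stack.mean(axis=0)
        if symmetrize_consensus is not None:
            new = symmetrize_consensus(new)
        new, _ = _center_and_scale(new)
        change = float(np.sqrt(np.sum((new - consensus) ** 2)))
        consensus = new
        if change < tol:
            break
    else:
        raise GPAConvergenceError(max_iter, change)

    stack = _rotate_all_to(stack, consensus)
    ss = float(np.sum((stack - consensus) ** 2))
    return AlignedSet(
        aligned=stack,
        consensus=consensus,
        centroid_sizes=sizes,
        procrustes_ss=ss,
        n_iter=it,
        ss_history=ss_history,
    )


def tangent_project(aligned: AlignedSet) -> AlignedSet:
    """Orthogonally project aligned pre-shapes onto the tangent plane at the consensus.

    The tangent coordinate of pre-shape ``x`` is ``x - (x . c) c`` with ``c``
    the vectorised unit consensus: the component along the consensus direction
    is removed, so the consensus itself maps to the zero vector and the
    projection is idempotent.  Fills ``tangent_coords`` in place and returns
    the set.
    """
    if aligned.consensus is None:
        raise ValueError("aligned set has no consensus")
    n, k, d = aligned.aligned.shape
    c = aligned.consensus.reshape(-1)
    x = aligned.aligned.reshape(n, k * d)
    aligned.tangent_coords = x - np.outer(x @ c, c)
    return aligned


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Square root of the minimal summed squared difference between the unit-size
    centred pre-shapes over rotations (no reflection).
    """
    xa, _ = _center_and_scale(np.asarray(a, float))
    xb, _ = _center_and_scale(np.asarray(b, float))
    xa = xa @ _optimal_rotation(xa, xb)
    return float(np.sqrt(np.sum((xa - xb) ** 2)))
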