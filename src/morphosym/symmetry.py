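"""Symmetry-group machinery for matching, object, and nested symmetry.

Matching symmetry: physically separate repeated parts (e.g. the five pyramids
of a sea-urchin lantern), each digitised as its own configuration; symmetric
variation is carried by per-individual part averages, asymmetry by deviations
from them.

Object symmetry: the symmetry axis passes through a single structure.  Each
configuration is duplicated, the copy reflected and its paired landmarks
relabelled; a joint GPA of originals and copies yields a perfectly symmetric
consensus, and symmetric/asymmetric variation occupy orthogonal complementary
subspaces of the tangent space.

Nested (C_nv) symmetry composes the two: bilateral object symmetry of each
part inside rotational matching symmetry of the whole.  Only the reflection
generates transform-and-relabel copies; the rotational level is pure part
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LandmarkConfiguration, partial_gpa, _center_and_scale

__all__ = [
    "SymmetryScheme",
    "SubspaceProjectors",
    "lantern_scheme",
    "reflect_and_relabel",
    "reflection_operator",
    "symmetrize",
    "subspace_projectors",
]


@dataclass(frozen=True)
class SymmetryScheme:
    """Declaration of the symmetry structure of a dataset.

    Parameters
    ----------
    mode
        ``"matching"`` (repeated parts only), ``"object"`` (bilateral object
        symmetry only) or ``"nested"`` (bilateral object symmetry of each part
        nested in rotational matching symmetry of the whole, group C_nv).
    n_landmarks
        Number of landmarks k per configuration.
    pairing
        1-based landmark index pairs swapped by the reflection.
    unpaired
        1-based indices of landmarks lying on the symmetry axis.
    n_parts
        Number of repeated parts at the matching level (1 for pure object
        symmetry; 5 for the lantern).
    """

    mode: str
    n_landmarks: int
    pairing: tuple = ()
    unpaired: tuple = ()
    n_parts: int = 1

    def __post_init__(self):
        if self.mode not in ("matching", "object", "nested"):
            raise ValueError(f"unknown symmetry mode {self.mode!r}")
        pairing = tuple(tuple(int(i) for i in p) for p in self.pairing)
        unpaired = tuple(int(i) for i in self.unpaired)
        object.__setattr__(self, "pairing", pairing)
        object.__setattr__(self, "unpaired", unpaired)
        if self.mode in ("object", "nested"):
            for a, b in pairing:
                if a == b:
                    raise ValueError(f"landmark {a} paired with itself")
            covered = sorted([i for p in pairing for i in p] + list(unpaired))
            if covered != list(range(1, self.n_landmarks + 1)):
                raise ValueError(
                    "pairing plus unpaired must partition landmarks 1..k exactly; "
                    f"got {covered} for k={self.n_landmarks}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    @property
    def has_reflection(self) -> bool:
        return self.mode in ("object", "nested")

    def permutation(self) -> np.ndarray:
        """0-based landmark permutation induced by the reflection (an involution)."""
        perm = np.arange(self.n_landmarks)
        for a, b in self.pairing:
            perm[a - 1], perm[b - 1] = b - 1, a - 1
        return perm


def lantern_scheme(mode: str = "nested") -> SymmetryScheme:
    """The 12-landmark sea-urchin lantern scheme (C_5v).

    Four landmarks {1, 4, 10, 12} sit on the interradial suture (the bilateral
    symmetry axis of each pyramid); the mirror pairs are {2,3}, {5,8}, {6,7},
    {9,11}.  Five pyramids repeat rotationally.
    """
    return SymmetryScheme(
        mode=mode,
        n_landmarks=12,
        pairing=((2, 3), (5, 8), (6, 7), (9, 11)),
        unpaired=(1, 4, 10, 12),
        n_parts=5,
    )


def reflect_and_relabel(
    config: LandmarkConfiguration | np.ndarray, scheme: SymmetryScheme
) -> LandmarkConfiguration | np.ndarray:
    """Reflect a configuration and swap the labels of mirror-paired landmarks.

    The x coordinate (first axis) is negated and each paired landmark row is
    exchanged with its partner; on-axis landmarks stay in place.  Applying the
    operation twice returns the input exactly.  Accepts and returns either a
    :class:`LandmarkConfiguration` or a bare ``(k, d)`` array.
    """
    if not scheme.has_reflection:
        raise ValueError("scheme has no bilateral pairing (matching mode)")
    is_cfg = isinstance(config, LandmarkConfiguration)
    coords = config.coords if is_cfg else np.asarray(config, float)
    if coords.shape[0] != scheme.n_landmarks:
        raise ValueError(
            f"configuration has {coords.shape[0]} landmarks, scheme declares {scheme.n_landmarks}"
        )
    out = coords[scheme.permutation()].copy()
    out[:, 0] = -out[:, 0]
    if is_cfg:
        return LandmarkConfiguration(out, labels=config.labels)
    return out


def reflection_operator(scheme: SymmetryScheme, d: int = 2) -> np.ndarray:
    """The (k*d) x (k*d) orthogonal matrix acting on vectorised configurations
    as :func:`reflect_and_relabel` (row-major landmark-by-coordinate order)."""
    k = scheme.n_landmarks
    perm = scheme.permutation()
    op = np.zeros((k * d, k * d))
    for l in range(k):
        for c in range(d):
            sign = -1.0 if c == 0 else 1.0
            op[perm[l] * d + c, l * d + c] = sign
    return op


def symmetrize(
    config: LandmarkConfiguration | np.ndarray, scheme: SymmetryScheme
) -> LandmarkConfiguration | np.ndarray:
    """Bilaterally symmetric average of a configuration.

    Procrustes consensus of the configuration and its reflected-relabelled
    copy (a two-configuration partial GPA), followed by an exact averaging
    step with its own mirror image so the output is symmetric to machine
    precision.  Returned in the canonical frame in which the symmetry axis
    coincides with the reflection convention (shape-wise idempotent; a
    symmetric input maps to a configuration of the same shape), scaled back
    to the input's centroid size.
    """
    is_cfg = isinstance(config, LandmarkConfiguration)
    coords = config.coords if is_cfg else np.asarray(config, float)
    mirror = reflect_and_relabel(coords, scheme)
    aligned = partial_gpa(
        [coords, mirror],
        symmetrize_consensus=lambda m: 0.5 * (m + reflect_and_relabel(m, scheme)),
    )
    cons = aligned.consensus
    cons = 0.5 * (cons + reflect_and_relabel(cons, scheme))  # exact symmetry
    _, size = _center_and_scale(coords)
    if is_cfg:
        return LandmarkConfiguration(cons * size, labels=config.labels)
    return cons * size


@dataclass(frozen=True)
class SubspaceProjectors:
    """Orthogonal complementary projectors onto the symmetric and asymmetric
    subspaces of the shape tangent space at a symmetric consensus."""

    symmetric: np.ndarray
    asymmetric: np.ndarray
    dim_sym: int
    dim_asym: int
    consensus: np.ndarray = field(repr=False, default=None)


def _similarity_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions (2 translations,
    rotation, scale) at a unit-size centred 2-D consensus, as columns."""
    k, d = consensus.shape
    if d != 2:
        raise NotImplementedError("subspace dimension accounting implemented for d=2")
    c = consensus.reshape(-1)
    tx = np.zeros(k * d)
    tx[0::2] = 1.0
    ty = np.zeros(k * d)
    ty[1::2] = 1.0
    rot = np.empty(k * d)  # 90-degree rotation of each landmark of the consensus
    rot[0::2] = -consensus[:, 1]
    rot[1::2] = consensus[:, 0]
    basis = np.column_stack([tx, ty, c, rot])
    q, _ = np.linalg.qr(basis)
    return q


def subspace_projectors(
    scheme: SymmetryScheme, consensus: np.ndarray, d: int = 2
) -> SubspaceProjectors:
    """Build the symmetric/asymmetric tangent-subspace projectors.

    At a consensus that is itself symmetric under the reflection operator A,
    the tangent space (the orthogonal complement of the four similarity
    directions) splits into the +1 and -1 eigenspaces of A.  For d = 2, p
    mirror pairs and u on-axis landmarks each subspace has dimension
    ``2p + u - 2``, which is asserted against the numerical rank.

    Raises if ``d != 2`` or if the consensus is not symmetric under the scheme.
    """
    if d != 2:
        raise NotImplementedError("subspace projectors are validated for d=2 only")
    if not scheme.has_reflection:
        raise ValueError("scheme has no reflection; no object-symmetry subspaces")
    cons = np.asarray(consensus, float)
    sym_err = float(np.abs(reflect_and_relabel(cons, scheme) - cons).max())
    if sym_err > 1e-6:
        raise ValueError(
            f"consensus is not symmetric under the scheme (max deviation {sym_err:.2e}); "
            "build it from an expanded (original + reflected) GPA"
        )
    kd = scheme.n_landmarks * d
    a_op = reflection_operator(scheme, d)
    q = _similarity_basis(cons)
    p_tan = np.eye(kd) - q @ q.T
    p_sym = p_tan @ (0.5 * (np.eye(kd) + a_op)) @ p_tan
    p_asym = p_tan @ (0.5 * (np.eye(kd) - a_op)) @ p_tan
    # symmetrise against round-off
    p_sym = 0.5 * (p_sym + p_sym.T)
    p_asym = 0.5 * (p_asym + p_asym.T)

    expected = 2 * scheme.n_pairs + len(scheme.unpaired) - 2
    dim_sym = int(round(np.trace(p_sym)))
    dim_asym = int(round(np.trace(p_asym)))
    if (dim_sym, dim_asym) != (expected, expected):
        raise AssertionError(
            f"projector ranks ({dim_sym}, {dim_asym}) disagree with the closed form "
            f"2p+u-2 = {expected}; scheme/consensus mismatch?"
        )
    return SubspaceProjectors(p_sym, p_asym, dim_sym, dim_asym, consensus=cons)
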