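"""Synthetic lantern-structured datasets with known variance components.

The generator reads the nested mixed model generatively: for individual i,
part j, replicate r it composes a tangent-space deviation

    t_ijr = a_i + beta_j + gamma_j + (a beta)_ij + (a gamma)_ij + E_ijr

where ``a_i`` (individual), ``(a beta)_ij`` (rotational FA) are isotropic
Gaussians on the symmetric subspace, ``(a gamma)_ij`` (bilateral FA) on the
asymmetric subspace, ``E_ijr`` (measurement error) on the full tangent
space, ``beta_j`` are fixed symmetric-subspace rotational-DA displacements
and ``gamma_j`` fixed asymmetric-subspace bilateral-DA displacements.  The
configuration is the symmetric template plus the reshaped deviation, then
hit with a random similarity transform (rotation, translation, scale) so the
GPA has real work to do.  Centroid sizes carry their own log-normal
individual/FA/error components.

Default parameters are the lantern study conditions: 10 individuals x 5
parts x 2 replicates, 12 landmarks (4 mirror pairs, 4 on-axis), sigma values
back-solved from the published mean squares of the case study, bilateral DA
of magnitude 0.01 shape units and no rotational DA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anova import ShapeDataset
from .geometry import LandmarkConfiguration, _center_and_scale
from .symmetry import SymmetryScheme, lantern_scheme, reflect_and_relabel, subspace_projectors

__all__ = [
    "VarianceComponents",
    "lantern_template",
    "simulate_lanterns",
]

_TEMPLATE_XY = np.array(
    [
        [0.00, -1.00],  # 1  oral tip (on axis)
        [-0.16, -0.62],  # 2  retractor tip, left
        [0.16, -0.62],  # 3  retractor tip, right
        [0.00, -0.18],  # 4  foramen magnum base (on axis)
        [-0.52, 0.34],  # 5  hemipyramid/epiphysis junction, left
        [-0.60, 0.56],  # 6
        [0.60, 0.56],  # 7
        [0.52, 0.34],  # 8
        [0.42, 0.80],  # 9
        [0.00, 0.66],  # 10 (on axis)
        [-0.42, 0.80],  # 11
        [0.00, 0.95],  # 12 (on axis)
    ]
)


def lantern_template(scheme: SymmetryScheme | None = None) -> np.ndarray:
    """Stylized 12-landmark pyramid template, centred, unit centroid size,
    exactly symmetric under the lantern scheme."""
    if scheme is None:
        scheme = lantern_scheme()
    t, _ = _center_and_scale(_TEMPLATE_XY)
    t = 0.5 * (t + reflect_and_relabel(t, scheme))
    t, _ = _center_and_scale(t)
    return 0.5 * (t + reflect_and_relabel(t, scheme))


@dataclass
class VarianceComponents:
    """Simulation ground truth: template, sigmas, DA vectors, grid, seed.

    Sigmas are isotropic per-tangent-coordinate standard deviations in shape
    (Procrustes) units.  ``da_rotational`` / ``da_bilateral`` may be scalars
    (magnitude of deterministic canonical displacement patterns, per-part
    sum-to-zero for the rotational level) or explicit ``(n_parts, k*d)`` /
    ``(k*d,)`` arrays lying in the symmetric / asymmetric subspace.
    ``size_*`` are log-scale standard deviations of the centroid-size
    components.
    """

    sigma_individual: float = 0.0111  # sigma1: among-individual, symmetric subspace
    sigma_rot_fa: float = 0.0019  # sigma2: rotational FA, symmetric subspace
    sigma_bil_fa: float = 0.0027  # sigma3: bilateral FA, asymmetric subspace
    sigma_error: float = 0.0017  # sigma4: measurement error, full tangent space
    da_rotational: float | np.ndarray = 0.0
    da_bilateral: float | np.ndarray = 0.01
    n_individuals: int = 10
    n_parts: int = 5
    n_replicates: int = 2
    seed: int = 0
    base_size: float = 1.0
    size_sigma_individual: float = 0.05
    size_sigma_fa: float = 0.01
    size_sigma_error: float = 0.002
    consensus: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("sigma_individual", "sigma_rot_fa", "sigma_bil_fa", "sigma_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _canonical_vector(proj: np.ndarray, phase: float) -> np.ndarray:
    """Deterministic unit vector in the range of a projector."""
    n = proj.shape[0]
    raw = np.sin(phase + 1.7 * np.arange(1, n + 1))
    v = proj @ raw
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("degenerate canonical direction")
    return v / nrm


def _da_vectors(param, proj, n_parts, kd, label, center_parts):
    """Resolve a DA parameter into per-part (or single) subspace vectors."""
    if np.isscalar(param):
        mag = float(param)
        if mag == 0.0:
            return np.zeros((n_parts, kd))
        if center_parts:
            # rotational DA: distinct per-part displacements, sum-to-zero
            vecs = np.stack(
                [mag * _canonical_vector(proj, 0.9 * (j + 1)) for j in range(n_parts)]
            )
            return vecs - vecs.mean(axis=0)
        # bilateral DA: one common displacement shared by all parts
        return np.broadcast_to(mag * _canonical_vector(proj, 0.9), (n_parts, kd)).copy()
    arr = np.asarray(param, float)
    if arr.ndim == 1:
        arr = np.broadcast_to(arr, (n_parts, kd)).copy()
    if arr.shape != (n_parts, kd):
        raise ValueError(f"{label} must be scalar, (k*d,), or (n_parts, k*d)")
    resid = arr - arr @ proj
    if np.abs(resid).max() > 1e-8 * max(1.0, np.abs(arr).max()):
        raise ValueError(f"{label} displacement lies outside its declared subspace")
    return arr


def simulate_lanterns(
    params: VarianceComponents | None = None,
    scheme: SymmetryScheme | None = None,
    rng: np.random.Generator | None = None,
    apply_similarity: bool = True,
):
    """Draw a lantern-structured dataset; returns ``(ShapeDataset, truth)``.

    ``truth`` maps effect names to the exact tangent-space draws (plus the
    parameters), enabling parameter-recovery checks.  All randomness flows
    from ``params.seed`` unless an explicit generator is supplied.
    """
    if params is None:
        params = VarianceComponents()
    if scheme is None:
        scheme = lantern_scheme()
        scheme = SymmetryScheme(
            mode=scheme.mode,
            n_landmarks=scheme.n_landmarks,
            pairing=scheme.pairing,
            unpaired=scheme.unpaired,
            n_parts=params.n_parts,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    template = (
        lantern_template(scheme) if params.consensus is None else np.asarray(params.consensus, float)
    )
    k, d = template.shape
    kd = k * d
    proj = subspace_projectors(scheme, template)
    ps, pa = proj.symmetric, proj.asymmetric
    ptan = ps + pa
    I, J, R = params.n_individuals, params.n_parts, params.n_replicates

    beta = _da_vectors(params.da_rotational, ps, J, kd, "da_rotational", center_parts=True)
    gamma = _da_vectors(params.da_bilateral, pa, J, kd, "da_bilateral", center_parts=False)

    a_i = rng.standard_normal((I, kd)) @ ps * params.sigma_individual
    ab_ij = rng.standard_normal((I, J, kd)) @ ps * params.sigma_rot_fa
    ag_ij = rng.standard_normal((I, J, kd)) @ pa * params.sigma_bil_fa
    e_ijr = rng.standard_normal((I, J, R, kd)) @ ptan * params.sigma_error

    t = (
        a_i[:, None, None, :]
        + beta[None, :, None, :]
        + gamma[None, :, None, :]
        + ab_ij[:, :, None, :]
        + ag_ij[:, :, None, :]
        + e_ijr
    )

    log_size = (
        rng.standard_normal((I, 1, 1)) * params.size_sigma_individual
        + rng.standard_normal((I, J, 1)) * params.size_sigma_fa
        + rng.standard_normal((I, J, R)) * params.size_sigma_error
    )
    sizes = params.base_size * np.exp(log_size)

    configs, ind, part, rep = [], [], [], []
    for i in range(I):
        for j in range(J):
            for r in range(R):
                coords = template + t[i, j, r].reshape(k, d)
                coords = coords * sizes[i, j, r]
                if apply_similarity:
                    theta = rng.uniform(0, 2 * np.pi)
                    c, s_ = np.cos(theta), np.sin(theta)
                    coords = coords @ np.array([[c, s_], [-s_, c]])
                    coords = coords + rng.uniform(-2, 2, size=2)
                configs.append(LandmarkConfiguration(coords))
                ind.append(i + 1)
                part.append(j + 1)
                rep.append(r + 1)

    dataset = ShapeDataset(configs, ind, part, rep, scheme)
    truth = {
        "params": params,
        "template": template,
        "individual": a_i,
        "rotational_fa": ab_ij,
        "bilateral_fa": ag_ij,
        "error": e_ijr,
        "da_rotational": beta,
        "da_bilateral": gamma,
        "log_sizes": log_size,
        "projectors": proj,
    }
    return dataset, truth
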