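"""Per-effect covariance matrices, their PCA, and shape-change export.

The SSCP matrix of each ANOVA effect, divided by its degrees of freedom,
estimates a mean-square matrix whose expectation is a design-implied mixture
of variance components.  Subtracting the mean-square matrix of the EMS
partner and dividing by the number of records per effect-level combination
recovers the covariance matrix attached to each effect (individual
variation, rotational FA, bilateral FA, measurement error).  PCA of those
matrices yields the dominant patterns of shape change, exported as
per-landmark displacement vectors anchored at the consensus ("lollipops").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import DesignComponents, design_dfs, effect_arrays

__all__ = [
    "EffectCovariance",
    "effect_covariances",
    "pca_effect",
    "variance_components",
    "directional_asymmetry",
    "lollipop_frame",
]

# partner whose mean-square matrix enters each effect's expected mean square
# one multiplier level down (NOT always the F-test denominator: e.g. the
# rotational-FA term of the nested design subtracts the symmetric error, while
# its F test uses the bilateral-FA term)
EMS_PARTNER = {
    "A1": {
        "individual": "individual_x_part",
        "part": "individual_x_part",
        "individual_x_part": "error",
        "error": None,
    },
    "A2": {
        "part": "symmetric_error",
        "reflection": "asymmetric_error",
        "part_x_reflection": "asymmetric_error",
        "symmetric_error": None,
        "asymmetric_error": None,
    },
    "A3": {
        "individual": "individual_x_part",
        "part": "individual_x_part",
        "reflection_in_part": "individual_x_reflection_in_part",
        "individual_x_part": "symmetric_error",
        "individual_x_reflection_in_part": "asymmetric_error",
        "symmetric_error": None,
        "asymmetric_error": None,
    },
}


def _multipliers(design: str, grid) -> dict:
    """Records per level combination of each effect (the EMS coefficient of
    its own variance component)."""
    i, j, r = grid
    if design == "A1":
        return {
            "individual": j * r,
            "part": i * r,
            "individual_x_part": r,
            "error": 1,
        }
    if design == "A2":
        return {
            "part": i * r,
            "reflection": i * j * r,
            "part_x_reflection": i * r,
            "symmetric_error": 1,
            "asymmetric_error": 1,
        }
    if design == "A3":
        return {
            "individual": j * r,
            "part": i * r,
            "reflection_in_part": i * r,
            "individual_x_part": r,
            "individual_x_reflection_in_part": r,
            "symmetric_error": 1,
            "asymmetric_error": 1,
        }
    raise ValueError(f"unknown design {design!r}")


def _estimation_dfs(design: str, grid, dims) -> dict:
    """Conventional df used for mean-square matrices in EMS estimation.

    Identical to the table df except for the error terms of the
    object-symmetry designs, where the unbiased replicate-contrast count
    ``IJ(R-1)`` is used instead of the part-centred table value (see
    docs/methods.md)."""
    i, j, r = grid
    out = {k: v[0] for k, v in design_dfs(design, grid, dims).items()}
    if design in ("A2", "A3"):
        out["symmetric_error"] = i * j * (r - 1)
        out["asymmetric_error"] = i * j * (r - 1)
    return out


@dataclass
class EffectCovariance:
    """Covariance matrix attached to one ANOVA effect."""

    effect: str
    covariance: np.ndarray
    consensus: np.ndarray
    indefinite: bool = False

    def __post_init__(self):
        c = np.asarray(self.covariance, float)
        if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise ValueError("covariance matrix must be symmetric")
        self.covariance = 0.5 * (c + c.T)

    @property
    def trace(self) -> float:
        return float(np.trace(self.covariance))


def effect_covariances(
    design: str,
    comp: DesignComponents,
    mode: str = "ems",
    clip: bool = False,
    effects=None,
) -> dict:
    """Recover per-effect covariance matrices from the fitted design.

    mode="ems"
        ``(MS-matrix of effect - MS-matrix of its EMS partner) / multiplier``;
        error terms are their MS matrix directly.  Subtraction can produce
        indefinite matrices on real data; these are reported as-is with a
        warning (``clip=True`` truncates negative eigenvalues at zero).
    mode="ms"
        plain mean-square matrices, ``SSCP / conventional df``.
    """
    arrs = effect_arrays(design, comp)
    dfs = _estimation_dfs(design, comp.grid, comp.dims)
    mult = _multipliers(design, comp.grid)
    ms = {k: (x.T @ x) / dfs[k] for k, x in arrs.items()}
    out = {}
    for eff in effects if effects is not None else arrs:
        partner = EMS_PARTNER[design][eff]
        if mode == "ms" or partner is None:
            cov = ms[eff]
        elif mode == "ems":
            cov = (ms[eff] - ms[partner]) / mult[eff]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
        tol = 1e-10 * max(1.0, float(np.abs(w).max()))
        indefinite = bool(w.min() < -tol)
        if indefinite and not clip:
            warnings.warn(
                f"EMS subtraction left covariance of {eff!r} indefinite "
                f"(min eigenvalue {w.min():.3e}); reported as-is",
                stacklevel=2,
            )
        if clip:
            wv, vv = np.linalg.eigh(0.5 * (cov + cov.T))
            cov = (vv * np.clip(wv, 0.0, None)) @ vv.T
            indefinite = False
        out[eff] = EffectCovariance(eff, cov, comp.consensus, indefinite=indefinite)
    return out


@dataclass
class EffectPCA:
    """Eigen-decomposition of an effect covariance as shape changes."""

    effect: str
    eigenvalues: np.ndarray  # nonincreasing
    eigenvectors: np.ndarray  # orthonormal columns
    displacements: np.ndarray  # (n_pc, k, d) landmark displacement per PC
    consensus: np.ndarray


def pca_effect(cov: EffectCovariance, n_pc: int | None = None) -> EffectPCA:
    """Principal components of an effect covariance matrix.

    Eigenpairs ordered by decreasing eigenvalue; each retained PC is reshaped
    into k x d per-landmark displacement vectors anchored at the consensus.
    """
    c = cov.covariance
    w, v = np.linalg.eigh(c)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if n_pc is not None:
        w, v = w[:n_pc], v[:, :n_pc]
    k, d = cov.consensus.shape
    disp = v.T.reshape(-1, k, d)
    return EffectPCA(cov.effect, w, v, disp, cov.consensus)


def variance_components(design: str, comp: DesignComponents) -> dict:
    """Isotropic variance-component estimates (per tangent coordinate).

    Traces of the EMS-recovered covariance matrices divided by the dimension
    of the subspace each effect occupies.  For the nested design this returns
    the sigma^2 of the individual, rotational-FA, bilateral-FA and error
    terms of the model equation.
    """
    from .anova import SUBSPACE

    ms_dim, ma_dim = comp.dims
    covs = effect_covariances(design, comp, mode="ems")
    dim_of = {"sym": ms_dim, "asym": ma_dim, "both": ms_dim + ma_dim}
    out = {}
    for eff, cov in covs.items():
        sub = SUBSPACE[design][eff]
        out[eff] = cov.trace / dim_of[sub]
    if design == "A1":
        out["error_total"] = out["error"]
    else:
        # isotropic error spans both subspaces; pool the two restrictions
        tr = covs["symmetric_error"].trace + covs["asymmetric_error"].trace
        out["error_total"] = tr / (ms_dim + ma_dim)
    return out


def directional_asymmetry(comp: DesignComponents) -> np.ndarray:
    """Bilateral DA displacement: the mean asymmetric component, i.e. half
    the difference between the averages of original and reflected
    configurations, as a (k, d) per-landmark vector."""
    if comp.a is None:
        raise ValueError("bilateral DA requires object-symmetry components")
    k, d = comp.consensus.shape
    return comp.a.mean(axis=(0, 1, 2)).reshape(k, d)


def lollipop_frame(pcas, amplification: float = 10.0) -> pd.DataFrame:
    """Shape-change export: one row per (effect, PC, landmark).

    Columns: effect, pc, landmark, consensus x/y, displacement dx/dy
    (amplified).  This is the numeric content of a lollipop graph; rendering
    is left to :func:`plot_lollipops` or external tools.
    """
    rows = []
    for pca in pcas:
        k = pca.consensus.shape[0]
        for ipc in range(pca.displacements.shape[0]):
            for l in range(k):
                rows.append(
                    {
                        "effect": pca.effect,
                        "pc": ipc + 1,
                        "eigenvalue": pca.eigenvalues[ipc],
                        "landmark": l + 1,
                        "x": pca.consensus[l, 0],
                        "y": pca.consensus[l, 1],
                        "dx": amplification * pca.displacements[ipc, l, 0],
                        "dy": amplification * pca.displacements[ipc, l, 1],
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["amplification"] = amplification
    return df


def plot_lollipops(frame: pd.DataFrame, ax=None):
    """Render a lollipop frame (optional; requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for _, r in frame.iterrows():
        ax.plot([r.x, r.x + r.dx], [r.y, r.y + r.dy], "k-", lw=2)
        ax.plot(r.x, r.y, "o", mfc="none", mec="k")
    ax.set_aspect("equal")
    return ax
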