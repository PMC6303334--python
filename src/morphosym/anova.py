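"""Procrustes ANOVA designs for simple and nested symmetries.

Three statistical designs decompose tangent-space shape variation of a
structure with bilateral object symmetry nested in rotational matching
symmetry (the sea-urchin lantern being the canonical case: I individuals x
J parts x 2 replicates, each part bilaterally symmetric):

* **A1 (rotational matching symmetry, group C_n)** — each part is first
  replaced by its bilaterally symmetric average, then a two-way mixed model
  ``Y_ikr = mu + a_i + beta_k + (a beta)_ik + E_ikr`` partitions variation
  into individual (random), part = rotational directional asymmetry (fixed),
  individual x part = rotational fluctuating asymmetry (random) and
  measurement error.

* **A2 (bilateral object symmetry, group C_1v)** — originals plus
  reflected-relabelled copies are jointly aligned; after correcting for the
  individual effect and for individual deviations from rotational symmetry
  (differences in means at the individual and individual-x-part level), a
  two-way fixed-effects model tests part, reflection (bilateral DA) and
  part x reflection (bilateral FA) against the symmetric and asymmetric
  components of measurement error respectively.

* **A3 (nested symmetry, group C_nv)** — the full mixed model with nested and
  crossed factors ``Y_ijkr = mu + a_i + beta_j + gamma_k(j) + (a beta)_ij +
  (a gamma)_ik(j) + E_r(ijk)``: individual, part (rotational DA),
  reflection-within-part (bilateral DA), individual x part (rotational FA),
  individual x reflection-within-part (bilateral FA), and error split into
  its symmetric and asymmetric components.

Sums of squares are squared norms of the balanced-design marginal-mean
components, summed over the I x J x R original records (reflected copies fix
the consensus and the subspace split but are not double counted).  Shape
degrees of freedom are conventional degrees of freedom times the dimension
of the tangent subspace an effect lives in; mean squares for shape use shape
df, centroid-size ANOVA uses conventional df.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import LandmarkConfiguration, partial_gpa, tangent_project
from .symmetry import (
    SymmetryScheme,
    SubspaceProjectors,
    reflect_and_relabel,
    subspace_projectors,
    symmetrize,
)

__all__ = [
    "ShapeDataset",
    "DesignComponents",
    "EFFECT_TABLE_COLUMNS",
    "goodall_f",
    "prepare_matching",
    "prepare_object",
    "anova_rotational_matching",
    "anova_bilateral_object",
    "anova_nested",
    "anova_centroid_size",
    "design_dfs",
    "DENOMINATORS",
    "SUBSPACE",
    "RANDOM_EFFECTS",
]

EFFECT_TABLE_COLUMNS = [
    "effect",
    "conv_df",
    "shape_df",
    "SS",
    "MS",
    "F",
    "P_param",
    "P_perm",
    "pillai",
    "pillai_P_param",
    "pillai_P_perm",
]


class UnbalancedDesignError(ValueError):
    """The designs require a complete, balanced individual x part x replicate grid."""


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class ShapeDataset:
    """Landmark configurations indexed by (individual, part, replicate).

    ``configs[i][j][r]`` conventions are flattened: ``configs`` is a list in
    row-major (individual, part, replicate) order over the complete balanced
    grid, together with the three 1-based index arrays.
    """

    configs: list
    individual: np.ndarray
    part: np.ndarray
    replicate: np.ndarray
    scheme: SymmetryScheme
    centroid_sizes: np.ndarray = None

    def __post_init__(self):
        from .geometry import centroid_size

        self.individual = np.asarray(self.individual, int)
        self.part = np.asarray(self.part, int)
        self.replicate = np.asarray(self.replicate, int)
        n = len(self.configs)
        if not (len(self.individual) == len(self.part) == len(self.replicate) == n):
            raise ValueError("index arrays must match the number of configurations")
        if self.centroid_sizes is None:
            self.centroid_sizes = np.array([centroid_size(c) for c in self.configs])
        self._levels = tuple(
            np.unique(ix) for ix in (self.individual, self.part, self.replicate)
        )
        ni, nj, nr = (len(l) for l in self._levels)
        if ni * nj * nr != n:
            raise UnbalancedDesignError(
                f"incomplete grid: {n} records for {ni} individuals x {nj} parts x {nr} replicates"
            )
        key = set(zip(self.individual, self.part, self.replicate))
        if len(key) != n:
            raise UnbalancedDesignError("duplicated (individual, part, replicate) cells")

    @property
    def shape_grid(self) -> tuple[int, int, int]:
        return tuple(len(l) for l in self._levels)

    def sorted_order(self) -> np.ndarray:
        """Row-major (individual, part, replicate) order of the records."""
        return np.lexsort((self.replicate, self.part, self.individual))

    def sizes_array(self) -> np.ndarray:
        """Centroid sizes as an (I, J, R) array."""
        ni, nj, nr = self.shape_grid
        return np.asarray(self.centroid_sizes)[self.sorted_order()].reshape(ni, nj, nr)

    @classmethod
    def from_configs(
        cls,
        configs,
        ids,
        scheme: SymmetryScheme,
        id_pattern: str = r"(?P<individual>\d+)[_\-](?P<part>\d+)[_\-](?P<replicate>\d+)",
    ) -> "ShapeDataset":
        """Build a dataset from configurations and TPS-style ID strings.

        The default pattern reads IDs of the form ``<individual>_<part>_<replicate>``.
        """
        pat = re.compile(id_pattern)
        idx = {"individual": [], "part": [], "replicate": []}
        for s in ids:
            m = pat.search(str(s))
            if m is None:
                raise ValueError(f"ID {s!r} does not match pattern {id_pattern!r}")
            for k in idx:
                idx[k].append(int(m.group(k)))
        return cls(list(configs), idx["individual"], idx["part"], idx["replicate"], scheme)


# ---------------------------------------------------------------------------
# alignment / component extraction


@dataclass
class DesignComponents:
    """Tangent-space components of a dataset, ready for any design.

    ``y`` holds the tangent rows of the original records as an (I, J, R, D)
    array with D = k*d.  For object/nested schemes ``s`` and ``a`` are the
    projections of ``y`` onto the symmetric and asymmetric tangent subspaces
    (built from a joint GPA of originals and reflected-relabelled copies,
    whose consensus is exactly symmetric).  For pure matching symmetry (the
    A1 pipeline) the records are bilaterally symmetrized part shapes and only
    ``y`` is populated.
    """

    design_family: str  # "matching" or "object"
    y: np.ndarray
    consensus: np.ndarray
    scheme: SymmetryScheme
    dims: tuple[int, int]
    sizes: np.ndarray = None
    s: np.ndarray = None
    a: np.ndarray = None
    projectors: SubspaceProjectors = field(default=None, repr=False)
    procrustes_ss: float = None

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.y.shape[:3]


def prepare_matching(dataset: ShapeDataset, tol: float = 1e-10, max_iter: int = 100) -> DesignComponents:
    """Analysis-1 pipeline: symmetrize each part, joint GPA, tangent projection.

    Each configuration is replaced by the Procrustes consensus of itself and
    its reflected-relabelled copy, so every record is exactly bilaterally
    symmetric and variation is confined to the symmetric shape subspace
    (dimension 2p + u - 2).
    """
    scheme = dataset.scheme
    order = dataset.sorted_order()
    sym = [symmetrize(dataset.configs[i], scheme) for i in order]
    aligned = partial_gpa(sym, tol=tol, max_iter=max_iter)
    tangent_project(aligned)
    ni, nj, nr = dataset.shape_grid
    d = aligned.d
    y = aligned.tangent_coords.reshape(ni, nj, nr, aligned.k * d)
    m = 2 * scheme.n_pairs + len(scheme.unpaired) - 2
    return DesignComponents(
        design_family="matching",
        y=y,
        consensus=aligned.consensus,
        scheme=scheme,
        dims=(m, m),
        sizes=dataset.sizes_array(),
        procrustes_ss=aligned.procrustes_ss,
    )


def prepare_object(dataset: ShapeDataset, tol: float = 1e-10, max_iter: int = 100) -> DesignComponents:
    """Analysis-2/3 pipeline: expand with reflected copies, joint GPA, split.

    The dataset is doubled with reflected-relabelled copies; a joint partial
    GPA (its consensus symmetrized each iteration, hence exactly symmetric
    under the group) aligns all 2 x I x J x R configurations.  The tangent
    rows of the original records are then projected onto the symmetric and
    asymmetric subspaces at the consensus.
    """
    scheme = dataset.scheme
    if not scheme.has_reflection:
        raise ValueError("object-symmetry pipeline needs a scheme with bilateral pairing")
    order = dataset.sorted_order()
    originals = [dataset.configs[i] for i in order]
    expanded = list(originals) + [reflect_and_relabel(c, scheme) for c in originals]
    aligned = partial_gpa(
        expanded,
        tol=tol,
        max_iter=max_iter,
        symmetrize_consensus=lambda m: 0.5 * (m + reflect_and_relabel(m, scheme)),
    )
    cons = 0.5 * (aligned.consensus + reflect_and_relabel(aligned.consensus, scheme))
    aligned.consensus = cons
    tangent_project(aligned)
    n = len(originals)
    y = aligned.tangent_coords[:n]
    proj = subspace_projectors(scheme, cons)
    s = y @ proj.symmetric
    a = y @ proj.asymmetric
    ni, nj, nr = dataset.shape_grid
    dd = y.shape[1]
    return DesignComponents(
        design_family="object",
        y=y.reshape(ni, nj, nr, dd),
        consensus=cons,
        scheme=scheme,
        dims=(proj.dim_sym, proj.dim_asym),
        sizes=dataset.sizes_array(),
        s=s.reshape(ni, nj, nr, dd),
        a=a.reshape(ni, nj, nr, dd),
        projectors=proj,
        procrustes_ss=aligned.procrustes_ss,
    )


# ---------------------------------------------------------------------------
# effect decompositions (balanced marginal means)


def _sq(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def a1_effect_means(y: np.ndarray) -> dict:
    """Two-way mixed-model component means for an (I, J, R, D) array."""
    grand = y.mean(axis=(0, 1, 2))
    mi = y.mean(axis=(1, 2))
    mj = y.mean(axis=(0, 2))
    mij = y.mean(axis=2)
    return {"grand": grand, "mi": mi, "mj": mj, "mij": mij}


def a1_ss(y: np.ndarray) -> dict:
    c = a1_effect_means(y)
    i, j, r = y.shape[:3]
    return {
        "individual": j * r * _sq(c["mi"] - c["grand"]),
        "part": i * r * _sq(c["mj"] - c["grand"]),
        "individual_x_part": r
        * _sq(c["mij"] - c["mi"][:, None] - c["mj"][None, :] + c["grand"]),
        "error": _sq(y - c["mij"][:, :, None]),
    }


def a2_ss(s: np.ndarray, a: np.ndarray, correct_asymmetric: bool = True) -> dict:
    """Analysis-2 sums of squares after the mean correction.

    The correction removes per-individual and per-(individual, part) mean
    differences (which would otherwise inflate the error terms when parts
    from distinct individuals are pooled): the individual effect and
    rotational-FA deviations in the symmetric subspace and, by default, the
    (individual, part)-level deviations of the asymmetric component as well.
    """
    i, j, r = s.shape[:3]
    grand = s.mean(axis=(0, 1, 2))
    sj = s.mean(axis=(0, 2))
    sij = s.mean(axis=2)
    aij = a.mean(axis=2)
    aj = a.mean(axis=(0, 2))
    abar = a.mean(axis=(0, 1, 2))
    out = {
        "part": i * r * _sq(sj - grand),
        "reflection": i * j * r * _sq(abar),
        "part_x_reflection": i * r * _sq(aj - abar),
        "symmetric_error": _sq(s - sij[:, :, None]),
    }
    if correct_asymmetric:
        out["asymmetric_error"] = _sq(a - aij[:, :, None])
    else:
        out["asymmetric_error"] = _sq(a - aj[None, :, None])
    out["total_error"] = out["symmetric_error"] + out["asymmetric_error"]
    return out


def a3_ss(s: np.ndarray, a: np.ndarray) -> dict:
    i, j, r = s.shape[:3]
    grand = s.mean(axis=(0, 1, 2))
    si = s.mean(axis=(1, 2))
    sj = s.mean(axis=(0, 2))
    sij = s.mean(axis=2)
    aij = a.mean(axis=2)
    aj = a.mean(axis=(0, 2))
    out = {
        "individual": j * r * _sq(si - grand),
        "part": i * r * _sq(sj - grand),
        "reflection_in_part": i * r * _sq(aj),
        "individual_x_part": r * _sq(sij - si[:, None] - sj[None, :] + grand),
        "individual_x_reflection_in_part": r * _sq(aij - aj[None, :]),
        "symmetric_error": _sq(s - sij[:, :, None]),
        "asymmetric_error": _sq(a - aij[:, :, None]),
    }
    out["total_error"] = out["symmetric_error"] + out["asymmetric_error"]
    return out


def effect_arrays(design: str, comp: DesignComponents) -> dict:
    """Full (N, D) component row matrices per effect (for SSCPs and PCA)."""
    i, j, r, d = comp.y.shape
    full = lambda x: np.broadcast_to(x, (i, j, r, d)).reshape(i * j * r, d)
    if design == "A1":
        y = comp.y
        c = a1_effect_means(y)
        return {
            "individual": full((c["mi"] - c["grand"])[:, None, None]),
            "part": full((c["mj"] - c["grand"])[None, :, None]),
            "individual_x_part": full(
                (c["mij"] - c["mi"][:, None] - c["mj"][None, :] + c["grand"])[:, :, None]
            ),
            "error": (y - c["mij"][:, :, None]).reshape(i * j * r, d),
        }
    s, a = comp.s, comp.a
    grand = s.mean(axis=(0, 1, 2))
    si = s.mean(axis=(1, 2))
    sj = s.mean(axis=(0, 2))
    sij = s.mean(axis=2)
    aij = a.mean(axis=2)
    aj = a.mean(axis=(0, 2))
    abar = a.mean(axis=(0, 1, 2))
    common = {
        "symmetric_error": (s - sij[:, :, None]).reshape(i * j * r, d),
        "asymmetric_error": (a - aij[:, :, None]).reshape(i * j * r, d),
    }
    if design == "A2":
        return {
            "part": full((sj - grand)[None, :, None]),
            "reflection": full(abar),
            "part_x_reflection": full((aj - abar)[None, :, None]),
            **common,
        }
    if design == "A3":
        return {
            "individual": full((si - grand)[:, None, None]),
            "part": full((sj - grand)[None, :, None]),
            "reflection_in_part": full(aj[None, :, None]),
            "individual_x_part": full(
                (sij - si[:, None] - sj[None, :] + grand)[:, :, None]
            ),
            "individual_x_reflection_in_part": full((aij - aj[None, :])[:, :, None]),
            **common,
        }
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# df bookkeeping, denominator maps, fixed/random declarations

SUBSPACE = {
    "A1": {
        "individual": "sym",
        "part": "sym",
        "individual_x_part": "sym",
        "error": "sym",
    },
    "A2": {
        "part": "sym",
        "reflection": "asym",
        "part_x_reflection": "asym",
        "symmetric_error": "sym",
        "asymmetric_error": "asym",
        "total_error": "both",
    },
    "A3": {
        "individual": "sym",
        "part": "sym",
        "reflection_in_part": "asym",
        "individual_x_part": "sym",
        "individual_x_reflection_in_part": "asym",
        "symmetric_error": "sym",
        "asymmetric_error": "asym",
        "total_error": "both",
    },
}

DENOMINATORS = {
    "A1": {
        "individual": "individual_x_part",
        "part": "individual_x_part",
        "individual_x_part": "error",
    },
    "A2": {
        "part": "symmetric_error",
        "reflection": "asymmetric_error",
        "part_x_reflection": "asymmetric_error",
    },
    # reconstructed so that the published F ratios follow from the published
    # SS and df of the nested-design table
    "A3": {
        "individual": "individual_x_part",
        "part": "individual_x_part",
        "reflection_in_part": "individual_x_reflection_in_part",
        "individual_x_part": "individual_x_reflection_in_part",
        "individual_x_reflection_in_part": "asymmetric_error",
    },
    "size": {
        "individual": "individual_x_part",
        "part": "individual_x_part",
        "individual_x_part": "error",
    },
}

RANDOM_EFFECTS = {
    "A1": ("individual", "individual_x_part"),
    "A2": (),
    "A3": ("individual", "individual_x_part", "individual_x_reflection_in_part"),
    "size": ("individual", "individual_x_part"),
}


def design_dfs(design: str, grid: tuple[int, int, int], dims: tuple[int, int]) -> dict:
    """Conventional and shape df per effect for a balanced (I, J, R) grid.

    Shape df are conventional df times the dimension of the tangent subspace
    the effect occupies (``dims = (dim_sym, dim_asym)``).  The error terms of
    the object-symmetry designs carry ``J(I-1)(R-1)`` conventional df per
    subspace: the replicate contrasts are centred within part levels, a
    consequence of the mean corrections applied when parts are pooled across
    individuals.
    """
    i, j, r = grid
    ms, ma = dims
    if design == "A1":
        conv = {
            "individual": i - 1,
            "part": j - 1,
            "individual_x_part": (i - 1) * (j - 1),
            "error": i * j * (r - 1),
        }
        return {k: (v, v * ms) for k, v in conv.items()}
    if design == "size":
        conv = {
            "individual": i - 1,
            "part": j - 1,
            "individual_x_part": (i - 1) * (j - 1),
            "error": i * j * (r - 1),
        }
        return {k: (v, v) for k, v in conv.items()}
    err = j * (i - 1) * (r - 1)
    if design == "A2":
        conv = {
            "part": (j - 1, ms),
            "reflection": (1, ma),
            "part_x_reflection": (j - 1, ma),
            "symmetric_error": (err, ms),
            "asymmetric_error": (err, ma),
            "total_error": (err, ms + ma),
        }
    elif design == "A3":
        conv = {
            "individual": (i - 1, ms),
            "part": (j - 1, ms),
            "reflection_in_part": (j, ma),
            "individual_x_part": ((i - 1) * (j - 1), ms),
            "individual_x_reflection_in_part": ((i - 1) * j, ma),
            "symmetric_error": (err, ms),
            "asymmetric_error": (err, ma),
            "total_error": (err, ms + ma),
        }
    else:
        raise ValueError(f"unknown design {design!r}")
    return {k: (df, df * mult) for k, (df, mult) in conv.items()}


# ---------------------------------------------------------------------------
# Goodall's F and table assembly


def goodall_f(ss_num: float, df_num: float, ss_den: float, df_den: float):
    """Goodall's F-ratio and its parametric P value.

    ``F = (ss_num/df_num) / (ss_den/df_den)`` referred to an F distribution
    with ``(df_num, df_den)`` degrees of freedom; for shape effects the df
    passed in are the shape df (conventional df times subspace dimension).
    Returns ``(nan, nan)`` with a warning if the denominator SS is zero.
    """
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_num < 0 or ss_den < 0:
        raise ValueError("sums of squares must be nonnegative")
    if ss_den == 0:
        import warnings

        warnings.warn("zero denominator SS: F and P reported as NA", stacklevel=2)
        return float("nan"), float("nan")
    f = (ss_num / df_num) / (ss_den / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p


def _assemble_table(
    design: str,
    ss: dict,
    dfs: dict,
    order: list,
    use_shape_df: bool = True,
) -> pd.DataFrame:
    rows = []
    denom = DENOMINATORS[design]
    for eff in order:
        conv_df, shape_df = dfs[eff]
        test_df = shape_df if use_shape_df else conv_df
        ms = ss[eff] / test_df
        rec = {
            "effect": eff,
            "conv_df": conv_df,
            "shape_df": shape_df,
            "SS": ss[eff],
            "MS": ms,
            "F": np.nan,
            "P_param": np.nan,
            "P_perm": np.nan,
            "pillai": np.nan,
            "pillai_P_param": np.nan,
            "pillai_P_perm": np.nan,
        }
        if eff in denom:
            dn = denom[eff]
            dn_df = dfs[dn][1] if use_shape_df else dfs[dn][0]
            rec["F"], rec["P_param"] = goodall_f(ss[eff], test_df, ss[dn], dn_df)
        rows.append(rec)
    return pd.DataFrame(rows, columns=EFFECT_TABLE_COLUMNS)


def _maybe_inference(table, design, comp, n_permutations, seed, manova):
    from . import inference

    if manova:
        inference.add_pillai(table, design, comp)
    if n_permutations:
        if seed is None:
            raise ValueError("permutation tests require an explicit seed")
        inference.add_permutation_pvalues(
            table, design, comp, n_permutations=n_permutations, seed=seed, manova=manova
        )
    return table


def anova_rotational_matching(
    comp: DesignComponents, n_permutations: int = 0, seed=None, manova: bool = True
) -> pd.DataFrame:
    """Analysis 1: two-way mixed Procrustes ANOVA of symmetrized parts (C_n).

    Expects components from :func:`prepare_matching` (two replicates are
    required for the measurement-error row).  Both main effects are tested
    against the individual x part interaction (rotational FA), the
    interaction against measurement error.
    """
    if comp.design_family != "matching":
        raise ValueError("Analysis 1 runs on the matching-symmetry pipeline (prepare_matching)")
    if comp.grid[2] < 2:
        raise ValueError("measurement error is not estimable without replicate measurements")
    ss = a1_ss(comp.y)
    dfs = design_dfs("A1", comp.grid, comp.dims)
    table = _assemble_table("A1", ss, dfs, ["individual", "part", "individual_x_part", "error"])
    return _maybe_inference(table, "A1", comp, n_permutations, seed, manova)


def anova_bilateral_object(
    comp: DesignComponents,
    n_permutations: int = 0,
    seed=None,
    manova: bool = True,
    correct_asymmetric: bool = True,
) -> pd.DataFrame:
    """Analysis 2: two-way fixed-effects Procrustes ANOVA of bilateral object
    symmetry (C_1v), after the individual-level mean corrections.

    Part is tested against the symmetric component of measurement error;
    reflection (bilateral DA) and part x reflection (bilateral FA) against
    the asymmetric component.
    """
    if comp.design_family != "object" or comp.a is None:
        raise ValueError("Analysis 2 runs on the object-symmetry pipeline (prepare_object)")
    ss = a2_ss(comp.s, comp.a, correct_asymmetric=correct_asymmetric)
    dfs = design_dfs("A2", comp.grid, comp.dims)
    table = _assemble_table(
        "A2",
        ss,
        dfs,
        ["part", "reflection", "part_x_reflection", "symmetric_error", "asymmetric_error", "total_error"],
    )
    return _maybe_inference(table, "A2", comp, n_permutations, seed, manova)


def anova_nested(
    comp: DesignComponents, n_permutations: int = 0, seed=None, manova: bool = True
) -> pd.DataFrame:
    """Analysis 3: mixed-model Procrustes ANOVA with nested and crossed
    factors (C_nv): bilateral object symmetry nested in rotational matching
    symmetry."""
    if comp.design_family != "object" or comp.a is None:
        raise ValueError("Analysis 3 runs on the object-symmetry pipeline (prepare_object)")
    ss = a3_ss(comp.s, comp.a)
    dfs = design_dfs("A3", comp.grid, comp.dims)
    table = _assemble_table(
        "A3",
        ss,
        dfs,
        [
            "individual",
            "part",
            "reflection_in_part",
            "individual_x_part",
            "individual_x_reflection_in_part",
            "symmetric_error",
            "asymmetric_error",
            "total_error",
        ],
    )
    return _maybe_inference(table, "A3", comp, n_permutations, seed, manova)


def anova_centroid_size(
    sizes: np.ndarray, n_permutations: int = 0, seed=None
) -> pd.DataFrame:
    """Two-way mixed ANOVA of centroid size (matching symmetry only).

    Size asymmetry exists only at the matching level: with object symmetry
    there is a unique configuration for the whole structure and hence no
    asymmetry in size.  ``sizes`` is the (I, J, R) array of centroid sizes;
    conventional degrees of freedom are used throughout.
    """
    sizes = np.asarray(sizes, float)
    if sizes.ndim != 3:
        raise ValueError(
            "size ANOVA needs per-(individual, part, replicate) sizes; object-symmetry "
            "data have a single configuration for the whole structure and no size asymmetry"
        )
    y = sizes[..., None]
    ss = a1_ss(y)
    dfs = design_dfs("size", sizes.shape, (1, 1))
    table = _assemble_table(
        "size", ss, dfs, ["individual", "part", "individual_x_part", "error"], use_shape_df=False
    )
    if n_permutations:
        from . import inference

        if seed is None:
            raise ValueError("permutation tests require an explicit seed")
        comp = DesignComponents(
            design_family="matching",
            y=y,
            consensus=None,
            scheme=None,
            dims=(1, 1),
        )
        inference.add_permutation_pvalues(
            table, "size", comp, n_permutations=n_permutations, seed=seed, manova=False
        )
    return table
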