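"""MANOVA (Pillai's trace with generalized inverse) and permutation tests.

Shape subspaces are rank-deficient, so Pillai's trace is computed as
``trace(H @ ginv(H + E))`` with a Moore-Penrose generalized inverse and the
dimensionality of the parametric F approximation taken as the numerical rank
of ``H + E``.

Permutation tests use restricted schemes matched to each effect's role in
the design: random main effects shuffle individual cell means within part
strata; fixed part/reflection main effects shuffle part labels within
individuals or flip reflection signs per cell; interaction and nested-FA
terms permute cell residuals after subtracting the main effects.  When the
permutation group is smaller than the requested number of permutations the
null set is enumerated exhaustively (with a notice).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import factorial
from types import SimpleNamespace

import numpy as np
from scipy import stats

from .anova import (
    DENOMINATORS,
    SUBSPACE,
    a1_ss,
    a2_ss,
    a3_ss,
    design_dfs,
    effect_arrays,
)

__all__ = [
    "PermutationScheme",
    "pillai_trace",
    "pillai_pvalue",
    "permutation_test",
    "add_pillai",
    "add_permutation_pvalues",
]


@dataclass
class PermutationScheme:
    """Configuration of a permutation test for one effect."""

    effect: str
    n_permutations: int = 10000
    seed: int | None = None
    statistic: str = "goodall"  # or "pillai"


# ---------------------------------------------------------------------------
# Pillai's trace


def pillai_trace(H: np.ndarray, E: np.ndarray, rcond: float | None = None):
    """Pillai's trace ``trace(H @ ginv(H + E))`` and the rank of ``H + E``.

    ``H`` is the hypothesis SSCP matrix, ``E`` the error SSCP from the same
    tangent subspace.  Singular values of ``H + E`` below
    ``max_dim * eps * s_max`` (or ``rcond * s_max``) are treated as zero.
    Returns ``(statistic, rank)``; all-zero matrices give ``(nan, 0)`` with a
    warning.
    """
    H = np.asarray(H, float)
    E = np.asarray(E, float)
    if H.shape != E.shape or H.shape[0] != H.shape[1]:
        raise ValueError("H and E must be square matrices of the same size")
    T = H + E
    smax = float(np.abs(T).max()) if T.size else 0.0
    if smax == 0.0:
        warnings.warn("all-zero SSCP matrices: Pillai's trace undefined", stacklevel=2)
        return float("nan"), 0
    if rcond is None:
        rcond = T.shape[0] * np.finfo(float).eps
    w, v = np.linalg.eigh(0.5 * (T + T.T))
    keep = w > rcond * w.max()
    rank = int(keep.sum())
    ginv = (v[:, keep] / w[keep]) @ v[:, keep].T
    return float(np.trace(H @ ginv)), rank


def pillai_pvalue(V: float, p: int, vh: int, ve: int) -> float:
    """Parametric P for Pillai's trace via the standard F approximation.

    ``p`` is the dimensionality (numerical rank of H + E), ``vh``/``ve`` the
    conventional hypothesis and error degrees of freedom.
    """
    if not np.isfinite(V) or p <= 0:
        return float("nan")
    s = min(p, vh)
    m = (abs(p - vh) - 1) / 2.0
    n = (ve - p - 1) / 2.0
    df2 = s * (2 * n + s + 1)
    if df2 <= 0:
        return float("nan")
    ratio = V / s
    if ratio >= 1.0:
        return 0.0
    f = ((2 * n + s + 1) / (2 * m + s + 1)) * ratio / (1.0 - ratio)
    df1 = s * (2 * m + s + 1)
    return float(stats.f.sf(f, df1, df2))


def _pillai_for_effect(design: str, comp_like, effect: str):
    """Pillai statistic for one effect against its design denominator.

    Returns ``nan`` when the effect and its denominator occupy different
    tangent subspaces (e.g. a symmetric-subspace FA term tested against an
    asymmetric-subspace one), where the statistic is not meaningful.
    """
    den = DENOMINATORS[design].get(effect)
    if den is None:
        return float("nan"), 0
    sub = SUBSPACE[design]
    if sub[effect] != sub[den]:
        return float("nan"), 0
    arrs = effect_arrays(design, comp_like)
    Xh, Xe = arrs[effect], arrs[den]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pillai_trace(Xh.T @ Xh, Xe.T @ Xe)


def add_pillai(table, design: str, comp) -> None:
    """Fill the Pillai columns of an effect table in place."""
    dfs = design_dfs(design, comp.grid, comp.dims)
    for idx, row in table.iterrows():
        eff = row["effect"]
        den = DENOMINATORS[design].get(eff)
        if den is None:
            continue
        V, rank = _pillai_for_effect(design, comp, eff)
        table.at[idx, "pillai"] = V
        table.at[idx, "pillai_P_param"] = pillai_pvalue(
            V, rank, dfs[eff][0], dfs[den][0]
        )


# ---------------------------------------------------------------------------
# permutation machinery
#
# Each action is defined by a descriptor space: sampling draws a random
# descriptor, exhaustive mode enumerates all of them, and `apply` rebuilds a
# permuted component array from a descriptor.  Cell means (over replicates)
# are the exchangeable units for all between-cell schemes; within-cell
# replicate deviations ride along unchanged, so error terms estimated from
# replicate contrasts are invariant under the permutations that use them as
# denominators.


class _Action:
    source = "s"  # which component array is permuted

    def __init__(self, i, j, r):
        self.i, self.j, self.r = i, j, r

    def count(self):  # size of the permutation group (None = too large / unknown)
        return None

    def sample(self, rng):
        raise NotImplementedError

    def enumerate_all(self):
        raise NotImplementedError

    def apply(self, x, desc):
        raise NotImplementedError

    @staticmethod
    def _split(x):
        m = x.mean(axis=2)
        return m, x - m[:, :, None]


class _ShuffleCellsWithinPart(_Action):
    """Shuffle individual labels of cell means within each part stratum
    (restricted permutation for a random main effect)."""

    def count(self):
        return factorial(self.i) ** self.j

    def sample(self, rng):
        return [rng.permutation(self.i) for _ in range(self.j)]

    def enumerate_all(self):
        perms = list(itertools.permutations(range(self.i)))
        for combo in itertools.product(perms, repeat=self.j):
            yield [np.asarray(p) for p in combo]

    def apply(self, x, desc):
        m, dev = self._split(x)
        out = np.empty_like(m)
        for j, perm in enumerate(desc):
            out[:, j] = m[perm, j]
        return out[:, :, None] + dev


class _ShufflePartsWithinIndividual(_Action):
    """Shuffle part labels of cell means within each individual
    (restricted permutation for a fixed main effect)."""

    def count(self):
        return factorial(self.j) ** self.i

    def sample(self, rng):
        return [rng.permutation(self.j) for _ in range(self.i)]

    def enumerate_all(self):
        perms = list(itertools.permutations(range(self.j)))
        for combo in itertools.product(perms, repeat=self.i):
            yield [np.asarray(p) for p in combo]

    def apply(self, x, desc):
        m, dev = self._split(x)
        out = np.empty_like(m)
        for i, perm in enumerate(desc):
            out[i] = m[i, perm]
        return out[:, :, None] + dev


class _ShuffleRecordResiduals(_Action):
    """Permute replicate-level records freely after subtracting the fitted
    reduced model (permutation across main factors after subtraction of
    their effects).  Subclasses define the reduced model."""

    def _reduced(self, x):
        raise NotImplementedError

    def count(self):
        return factorial(self.i * self.j * self.r)

    def sample(self, rng):
        return rng.permutation(self.i * self.j * self.r)

    def enumerate_all(self):
        for p in itertools.permutations(range(self.i * self.j * self.r)):
            yield np.asarray(p)

    def apply(self, x, desc):
        fit = self._reduced(x)
        resid = x - fit
        d = x.shape[-1]
        resid = resid.reshape(-1, d)[desc].reshape(x.shape)
        return fit + resid


class _ShuffleInteractionResiduals(_ShuffleRecordResiduals):
    """Interaction test: residualize on both main effects, shuffle records."""

    def _reduced(self, x):
        mi = x.mean(axis=(1, 2), keepdims=True)
        mj = x.mean(axis=(0, 2), keepdims=True)
        grand = x.mean(axis=(0, 1, 2), keepdims=True)
        return mi + mj - grand


class _SignFlipCellMeans(_Action):
    """Flip the sign of the asymmetric cell mean per (individual, part) cell:
    swapping the two reflection labels within each part (restricted
    permutation for a nested reflection effect)."""

    source = "a"

    def count(self):
        return 2 ** (self.i * self.j)

    def sample(self, rng):
        return rng.integers(0, 2, size=(self.i, self.j)) * 2 - 1

    def enumerate_all(self):
        for combo in itertools.product((-1, 1), repeat=self.i * self.j):
            yield np.asarray(combo).reshape(self.i, self.j)

    def apply(self, x, desc):
        m, dev = self._split(x)
        return (desc[:, :, None] * m)[:, :, None] + dev


class _ShuffleAsymResiduals(_ShuffleRecordResiduals):
    """Bilateral-FA test: residualize the asymmetric records on the per-part
    reflection (nested DA) means, shuffle records."""

    source = "a"

    def _reduced(self, x):
        return x.mean(axis=(0, 2), keepdims=True)


class _ShuffleAsymCentered(_Action):
    """Part x reflection test: permute (individual, part) cell means freely
    after centring by the overall bilateral-DA mean.  Cells are the
    exchangeable units here: the two replicates of a cell share its FA
    deviation, so record-level shuffling would break that correlation."""

    source = "a"

    def count(self):
        return factorial(self.i * self.j)

    def sample(self, rng):
        return rng.permutation(self.i * self.j)

    def enumerate_all(self):
        for p in itertools.permutations(range(self.i * self.j)):
            yield np.asarray(p)

    def apply(self, x, desc):
        m, dev = self._split(x)
        grand = m.mean(axis=(0, 1), keepdims=True)
        resid = m - grand
        d = resid.shape[-1]
        resid = resid.reshape(-1, d)[desc].reshape(m.shape)
        return (grand + resid)[:, :, None] + dev


_ACTIONS = {
    ("A1", "individual"): _ShuffleCellsWithinPart,
    ("A1", "part"): _ShufflePartsWithinIndividual,
    ("A1", "individual_x_part"): _ShuffleInteractionResiduals,
    ("size", "individual"): _ShuffleCellsWithinPart,
    ("size", "part"): _ShufflePartsWithinIndividual,
    ("size", "individual_x_part"): _ShuffleInteractionResiduals,
    ("A2", "part"): _ShufflePartsWithinIndividual,
    ("A2", "reflection"): _SignFlipCellMeans,
    ("A2", "part_x_reflection"): _ShuffleAsymCentered,
    ("A3", "individual"): _ShuffleCellsWithinPart,
    ("A3", "part"): _ShufflePartsWithinIndividual,
    ("A3", "reflection_in_part"): _SignFlipCellMeans,
    ("A3", "individual_x_part"): _ShuffleInteractionResiduals,
    ("A3", "individual_x_reflection_in_part"): _ShuffleAsymResiduals,
}


def _design_ss(design, s, a):
    if design in ("A1", "size"):
        return a1_ss(s)
    if design == "A2":
        return a2_ss(s, a)
    if design == "A3":
        return a3_ss(s, a)
    raise ValueError(f"unknown design {design!r}")


def _goodall_stat(design, effect, dfs, s, a):
    ss = _design_ss(design, s, a)
    den = DENOMINATORS[design][effect]
    if ss[den] == 0:
        return float("nan")
    return (ss[effect] / dfs[effect][1]) / (ss[den] / dfs[den][1])


def _pillai_stat(design, effect, dfs, s, a):
    comp_like = SimpleNamespace(y=s, s=s, a=a)
    V, _ = _pillai_for_effect(design, comp_like, effect)
    return V


def permutation_test(
    comp,
    design: str,
    effect: str,
    n_permutations: int = 10000,
    seed: int | None = None,
    statistic: str = "goodall",
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation P value for one effect under its restricted scheme.

    The observed statistic is included in the null set (``P >= 1/(n+1)``);
    when the permutation group has fewer elements than ``n_permutations`` it
    is enumerated exhaustively instead and ``P = #{stat* >= stat}/count``.
    Reproducible for a given seed.
    """
    key = (design, effect)
    if key not in _ACTIONS:
        raise ValueError(f"no permutation scheme for effect {effect!r} in design {design}")
    s = comp.y if comp.a is None else comp.s
    a = comp.a
    i, j, r, _ = s.shape
    action = _ACTIONS[key](i, j, r)
    dfs = design_dfs(design, (i, j, r), comp.dims)
    stat_fn = {"goodall": _goodall_stat, "pillai": _pillai_stat}[statistic]
    obs = stat_fn(design, effect, dfs, s, a)
    if not np.isfinite(obs):
        return float("nan")
    tol = 1e-12 * max(1.0, abs(obs))

    def permuted(desc):
        if action.source == "a":
            return s, action.apply(a, desc)
        return action.apply(s, desc), a

    count = action.count()
    if count is not None and count <= n_permutations:
        warnings.warn(
            f"permutation group for {effect} has only {count} elements; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        hits = total = 0
        for desc in action.enumerate_all():
            total += 1
            if stat_fn(design, effect, dfs, *permuted(desc)) >= obs - tol:
                hits += 1
        return hits / total

    if rng is None:
        if seed is None:
            raise ValueError("permutation test requires a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if stat_fn(design, effect, dfs, *permuted(action.sample(rng))) >= obs - tol:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def add_permutation_pvalues(
    table, design: str, comp, n_permutations: int, seed: int, manova: bool = True
) -> None:
    """Fill the permutation P columns of an effect table in place.

    One seeded generator drives all effects in table order, so a given
    (table, seed, n_permutations) triple always reproduces identical P
    values.
    """
    rng = np.random.default_rng(seed)
    for idx, row in table.iterrows():
        eff = row["effect"]
        if (design, eff) not in _ACTIONS:
            continue
        table.at[idx, "P_perm"] = permutation_test(
            comp, design, eff, n_permutations, statistic="goodall", rng=rng
        )
        if manova and np.isfinite(row["pillai"]):
            table.at[idx, "pillai_P_perm"] = permutation_test(
                comp, design, eff, n_permutations, statistic="pillai", rng=rng
            )
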