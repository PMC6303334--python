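# Methods

This note records the statistical models, the numerical choices, and the
design decisions behind morphosym, in enough detail to audit or extend the
package.

## Geometry

**Partial GPA.** Configurations are centred, scaled to unit centroid size and
rotated (2-D closed-form rotation from the cross/dot aggregates; SVD with
determinant correction in 3-D) to minimise summed squared distance to a
consensus that is re-estimated and re-normalised each iteration.  Partial
(not full) Procrustes: no additional scale parameter is fitted after the
unit-size normalisation.  Reflections are excluded from the alignment;
mirror images enter only through the explicit transform-and-relabel copies
of the symmetry machinery, so asymmetry information is never silently
removed.  The consensus is initialised from the first configuration, making
runs deterministic.  Convergence: consensus displacement < 1e-10 (Frobenius),
cap 100 iterations, both configurable; the objective history is recorded and
is non-increasing.  These convergence constants are implementation choices —
the standard practice values — since nothing in the underlying theory pins
them.

**Tangent projection.** Orthogonal (not stereographic) projection onto the
tangent plane at the consensus: `t = x − (x·c)c` for vectorised unit
consensus `c`.  Idempotent; the consensus maps to zero; for small variation
tangent distances agree with Procrustes distances to first order (verified
at 1e-4 relative on low-variance simulations).

## Symmetry machinery

A `SymmetryScheme` declares the mode (matching / object / nested), the
mirror pairing (an involution on 1-based landmark indices) and the on-axis
landmarks.  `reflect_and_relabel` negates the first coordinate and swaps
paired rows — the axis convention is fixed so runs are reproducible; any
axis is equivalent after GPA.

For object and nested designs the dataset is expanded with
reflected-relabelled copies and jointly aligned; the consensus is averaged
with its own mirror image every GPA iteration (and once exactly at the end),
so it is symmetric to machine precision.  At a symmetric consensus the
reflection operator commutes with the similarity projector, and the tangent
space splits into orthogonal complementary eigenspaces: the symmetric and
asymmetric subspaces, each of dimension `2p + u − 2` for p pairs and u
on-axis landmarks in 2-D (10 and 10 for the 12-landmark lantern scheme).
Projector ranks are asserted against this closed form at construction.
3-D subspace accounting differs and is not implemented (the data model
accepts 3-D configurations, the designs are validated for 2-D).

Nested mode composes per-record reflection expansion (object level) with
part bookkeeping (matching level); no rotational copies are generated
because the rotational symmetry is matching, not object.  Parts are assumed
pre-oriented by the user (e.g. relative to a fixed anatomical marker);
orientation is a data-acquisition fact the software cannot infer.

`symmetrize` (the A1 pre-step) returns the Procrustes consensus of a
configuration and its mirror copy, in the canonical frame where the
symmetry axis matches the reflection convention — it is not rotated back
onto the input, which would destroy exact axis alignment; the subsequent
GPA re-aligns everything anyway.

## The three designs: SS, df, denominators

All designs require a complete balanced I × J × R grid (unbalanced data are
rejected, not approximated).  Sums of squares are squared norms of the
balanced-design marginal-mean components summed over the I × J × R original
records; reflected copies determine the consensus and the subspace split but
are not double counted.  The total SS conserved by the object designs is the
variation about the *perfectly symmetric* reference: `Σ‖s − s̄‖² + Σ‖a‖²`,
so the overall asymmetric mean (the bilateral DA) is an effect, not part of
the baseline.  Additivity holds to ~1e-15 relative (tested at 1e-10).

Shape df = conventional df × subspace dimension; MS = SS / shape df for
shape, SS / conventional df for centroid size.  F-ratio denominators:

| design | effect | denominator |
|---|---|---|
| A1 | individual, part | individual × part |
| A1 | individual × part | error |
| A2 | part | symmetric error |
| A2 | reflection, part × reflection | asymmetric error |
| A3 | individual, part | individual × part |
| A3 | reflection(part) | individual × reflection(part) |
| A3 | individual × part | individual × reflection(part) |
| A3 | individual × reflection(part) | asymmetric error |

The A3 map is reconstructed from the published reference tables of the
lantern case study: every printed F value follows from the printed SS/df
under this map to <0.2% (asserted in the acceptance tests).

**Error df.** The matching design's error term carries `IJ(R−1)`
conventional df per the usual two-way bookkeeping.  The object designs
carry `J(I−1)(R−1)` per subspace — replicate contrasts centred within part
levels — consistent with the published tables and with the mean correction
applied when parts pooled across individuals are analysed (Analysis 2
subtracts per-individual and per-(individual, part) mean differences in both
subspaces; a `correct_asymmetric=False` switch keeps the asymmetric
component uncorrected).  The error *SS* is in both cases the plain
within-cell replicate SS.  This combination reproduces the reference tables
exactly; note it makes the object-design error MS conservative by a factor
(IJ(R−1))/(J(I−1)(R−1)) under a model without session effects.

**Estimation vs table df.** Because of that conservatism, the EMS-based
covariance recovery (below) divides the error SSCPs by the unbiased
contrast count `IJ(R−1)` rather than the table df.  Table df and estimation
df agree for every other term.

## Inference

**Goodall's F** assumes isotropic variation; P values come from the F
distribution at the shape df.  A zero denominator SS yields NA with a
warning.

**Pillai's trace** relaxes isotropy: `V = trace(H · ginv(H + E))` with a
Moore–Penrose generalized inverse (singular values below
`dim · eps · s_max` treated as zero) because shape subspaces are
rank-deficient.  The parametric P uses the standard F approximation with
dimensionality p = numerical rank of H + E and conventional hypothesis and
error df.  H is the effect SSCP, E the SSCP of the effect's design
denominator; when the two live in different subspaces (the nested design's
rotational-FA row against the bilateral-FA term) the statistic is not
meaningful and is reported NA.

**Permutation tests** (default 10,000 permutations, seed mandatory) use
restricted schemes matched to each effect:

- random main effect (individual): cell means shuffled across individuals
  within part strata;
- fixed part main effect: cell means shuffled across parts within
  individuals;
- nested reflection (bilateral DA): per-cell sign flips of the asymmetric
  cell mean — i.e. swapping the two reflection labels within each part;
- interaction and bilateral-FA terms: record-level residual randomization —
  replicate-level records are residualized on the fitted main effects and
  shuffled freely.  Cell-mean shuffling is *not* used here: doubly-centred
  cell residuals make the observed interaction SS the maximum of its
  permutation orbit, a degenerate test;
- A2 part × reflection: (individual, part) cell means centred on the
  overall DA and shuffled — cells, not records, are exchangeable because
  replicates within a cell share the cell's FA deviation.

The statistic (Goodall F or Pillai) is fully recomputed per permutation.
P values include the observed statistic, `P = (1 + #{stat* ≥ stat})/(1 + n)`;
when the permutation group is smaller than the requested count it is
enumerated exhaustively (with a notice) and `P = #{stat* ≥ stat}/|group|`.
Null simulations place the empirical type-I error of these schemes at the
nominal 5% level (the acceptance suite checks the nested-DA test over 200
runs × 999 permutations against the 99% binomial band).

One caveat, by construction: for the nested design's rotational-FA row the
printed F compares against the bilateral-FA mean square in the *other*
subspace, which a permutation of symmetric-subspace records cannot move.
The permutation P for that row therefore tests "rotational FA in excess of
error" (numerator exchangeability), not the cross-subspace ratio, and the
two P values need not agree.

## Effect covariances and PCA

Each effect's mean-square matrix is `SSCP / df` (estimation df, above).  A
random effect's covariance is `(MS_effect − MS_partner)/m`, where the EMS
partner is the term one multiplier level down (individual → interaction;
interaction → same-subspace error; bilateral FA → asymmetric error — note
the rotational-FA partner is the *symmetric error*, not its F-test
denominator) and m is the number of records per effect-level combination.
Error covariances are their MS matrices.  Subtraction can leave indefinite
matrices on real data; they are reported as-is with a warning because that
matrix is what standard workflows visualise, and `clip=True` truncates
eigenvalues at zero.  A plain `mode="ms"` skips subtraction.

PCA (symmetric eigendecomposition, eigenvalues non-increasing) reshapes
each component into k × 2 landmark displacements anchored at the consensus;
the lollipop export is numeric (consensus x, y and amplified dx, dy per
landmark per PC, default ten-fold amplification) with rendering left to an
optional matplotlib helper.  The bilateral DA displacement is the mean
asymmetric component — half the difference between the mean original and
mean reflected configurations.

## Synthetic data

The generator reads the nested model generatively at a stylized,
exactly-symmetric 12-landmark pyramid template: isotropic Gaussian draws on
the symmetric subspace for the individual term (σ₁) and rotational FA (σ₂),
on the asymmetric subspace for bilateral FA (σ₃), on the full tangent space
for measurement error (σ₄); fixed DA displacement vectors (rotational:
per-part, sum-to-zero, symmetric subspace; bilateral: common across parts,
asymmetric subspace — supplied vectors are validated by projection);
composition at the template plus a random similarity transform per record
so the GPA is genuinely exercised.  Centroid sizes carry log-normal
individual/FA/error components (defaults 0.05 / 0.01 / 0.002 on the log
scale — chosen as a plausible size-variation hierarchy, since the shape
model itself says nothing about size).

Defaults are the lantern study conditions: I = 10, J = 5, R = 2, σ₁–σ₄
back-solved once from the published mean squares via the EMS relations
(0.0111, 0.0019, 0.0027, 0.0017 shape units per tangent coordinate),
bilateral DA magnitude 0.01, rotational DA 0.  All randomness flows from a
single seed.

What the generator does *not* emulate: anisotropic or spatially correlated
landmark noise (an optional full-covariance mode would be needed to
demonstrate MANOVA's advantage over Goodall's F), digitising artefacts,
allometry, unbalanced designs, and 3-D structure.  Passing tests therefore
certify the decomposition, bookkeeping and inference machinery under the
isotropic model — not robustness to real-data pathologies.

## Problem sizes

The test and acceptance runs use the study-scale grid (100–200
configurations per dataset; one GPA ≈ 10 ms): 100 random datasets for
conservation properties, 200 runs × 999 permutations for test calibration,
200 replicates for variance-component recovery, 8 replicates at 50
individuals for DA recovery.  These sizes put Monte-Carlo standard errors
well inside the asserted tolerances while keeping a full run at a few
minutes on one CPU.

## Known limitations

- 2-D only for the symmetry subspace machinery; balanced designs only.
- Exactly two levels of hierarchy (reflection within parts); deeper nestings
  (e.g. bilateral within translational within rotational) would need new
  df bookkeeping, though translational matching symmetry itself is just a
  relabelling of "part".
- The A2/A3 error-df convention follows the published tables (see above);
  users comparing against software that uses `IJ(R−1)` will see slightly
  smaller error MS there.
- Permutation schemes are config-overridable only by editing the action
  registry; no Freedman–Lane variant comparison is shipped.
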