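# Methods

This note records the scientific and numerical choices behind the
package, in the spirit of a model-description document: what each
component assumes, which parameters matter, and what the synthetic data
do and do not establish.

## Molecule preparation

Descriptors are computed on a single prepared structure per molecule:
explicit hydrogens, one 3D conformer embedded with the ETKDG
distance-geometry method (deterministically seeded), relaxed with MMFF94
(UFF when MMFF parameters are missing), and Gasteiger–Marsili partial
charges. Two simplifications are deliberate:

- **Charges.** Semiempirical QM charges (e.g. AM1) would be the
  historical choice for CPSA-style descriptors; the package uses the
  Gasteiger empirical scheme by default because it is fast,
  deterministic and dependency-free. Absolute charge values differ from
  AM1 (Gasteiger hydroxyl H ≈ 0.21 e, typically above AM1's ≈ 0.03–0.1 e
  range), so charge-bearing descriptors (max H charge, HASA-2) are
  internally consistent but not numerically comparable with
  AM1-derived literature values. A charge-provider hook accepts a
  per-atom CSV so externally computed charges can be substituted.
- **Conformers.** One minimised conformer stands in for a conformational
  analysis; conformer-averaged descriptors are out of scope. Geometric
  descriptors therefore carry conformer noise of a few percent, which is
  acceptable because the pipeline autoscales descriptors before
  modelling.

Protonation states are taken as drawn; tautomer enumeration is not
attempted. Van der Waals radii are the Bondi set (H 1.20, C 1.70, N 1.55,
O 1.52, F 1.47, P/S 1.80, Cl 1.75, Br 1.85, I 1.98 Å); unknown elements
fall back to 1.70 Å with a warning.

## Descriptors

- **NSB / NAB.** Single-bond counts include bonds to explicit hydrogens —
  with drug-sized molecules this is what places NSB in the published
  26–90 range — while aromatic bonds follow the toolkit's default
  aromaticity perception (caffeine: 5 aromatic bonds, only the
  five-membered ring).
- **Relative element counts** divide by the total atom count including
  hydrogens, consistent with published ceilings of ~0.12 (O) and ~0.17
  (N) for this compound class.
- **Gravitational index** sums m_i·m_j/r_ij² over *all* atom pairs;
  GRAV-3 is its cube root. A bonded-pairs variant exists under a separate
  name but is not used by the pipeline.
- **SASA** is Shrake–Rupley with probe 1.4 Å and 960 sphere points per
  atom by default. Sphere points come from a Fibonacci (golden-spiral)
  lattice, so the computation is fully deterministic; doubling the point
  count moves totals by well under 1%. Accuracy is verified against the
  analytic area of isolated spheres and the additivity limit of
  well-separated atoms.
- **Acceptors** are all N and O atoms. This is the simplest deterministic
  rule; a configurable exclusion list (e.g. for pyrrole-type nitrogens)
  exists but is off by default.
- **HASA-2** is Σ_A |q_A|·√S_A (e·Å). CPSA-family definitions vary across
  the literature; the square-root area weighting with absolute charge was
  chosen as one published convention that yields positive values of the
  expected magnitude, and the formula is isolated in a single function.
- **SHDW-6.** Coordinates are centred and rotated to the principal axes
  of the coordinate covariance (axes ordered by decreasing variance;
  each eigenvector's sign fixed by making its largest-magnitude component
  positive, removing sign ambiguity). Atoms are projected on the YZ plane
  as disks of vdW radius, the union area is rasterised at 0.1 Å
  resolution, and the normalized descriptor divides by the bounding
  rectangle of the disks. The raw area is exposed alongside (published
  dataset ranges of ~30–110 Å² refer to the raw area; a normalized
  quantity cannot exceed 1). A single atom gives exactly π/4.
- **AlogP / PSA** use the vetted Ghose–Crippen and Ertl fragment schemes
  of the underlying toolkit.

## Splitting

Sphere exclusion is implemented as farthest-point-first selection in
autoscaled (zero-mean, unit-SD) descriptor space: the first training
compound is the one nearest the centroid, each subsequent pick is the
unassigned compound farthest from the current training set, and
unassigned compounds within the exclusion radius of a pick are assigned
to the test set. Ties break on the lowest row index, making the procedure
deterministic. Several sphere-exclusion variants exist in the literature;
this one was chosen because it is parameter-light and guarantees the
defining property directly (training-set pairwise distances all exceed
the radius). The radius achieving a desired training fraction is found by
bisection (train size is non-increasing in radius). The external set is
selected *before* sphere exclusion at quantile-spaced positions of sorted
%F including both extremes, so it spans the observed response range and
never influences scaling, radius tuning, or bandwidth selection (a
checksum assertion in the pipeline enforces this).

## Absorption-plane models

The ellipse model treats the well-absorbed class as bivariate normal in
(AlogP, PSA): sample mean, sample covariance (n−1), and a squared-
Mahalanobis cutoff at the χ²(2 df) quantile of the confidence level
(5.991 at 95%). The boundary is inclusive. "Well-absorbed" defaults to
%F ≥ 50, configurable. The decision tree is CART with Gini impurity,
midpoint thresholds, deterministic tie-breaking (lower feature index,
then lower threshold) and defaults max_depth 4, min_leaf 5 — a
reasonable stand-in for proprietary single-tree implementations, and
cross-checked against scikit-learn's CART in the tests.

## GRNN

The GRNN is the canonical Specht formulation: a Gaussian-kernel weighted
mean of training targets on autoscaled descriptors, numerically
stabilised by subtracting the maximum exponent so predictions remain
well-defined at any query distance. Its two limiting behaviours — exact
interpolation as σ→0 and collapse to the training mean as σ→∞ — are
asserted to 1e-6. A single isotropic σ is used (per-feature bandwidths
exist behind a flag); scaling is fitted on the training set only.
σ is selected by golden-section search on log₁₀σ over [−3, 2], refined to
1e-3, minimising test-set RMSE — the test set's role is precisely to
monitor overfitting of the bandwidth. With no test set the criterion
falls back to leave-one-out RMSE on the training set. Predictions are
convex combinations of training targets, so the optional [0, 100]
clipping is a no-op for %F-valued targets.

Descriptions of this architecture as a small fixed hidden layer (e.g.
"11-3-1") are inconsistent with the GRNN's structure, whose pattern layer
has one unit per training case; the canonical form is implemented.

## Synthetic data

The generator emulates the study conditions of a 217-compound
drug-like collection whose raw data are unavailable:

- descriptor columns are uniform (integer-uniform for counts) on the
  published per-column ranges; relative element counts are derived from a
  sampled drug-like total atom count (30–90 atoms) so count/total
  consistency holds exactly and the relative counts land inside their
  published ranges;
- the %F response rides on a single latent axis u, a fixed weighted
  combination of range-normalised GRAV-3, NSB (positive) and HASA-2,
  YZ-shadow (negative), standardised with fixed analytic constants;
  %F = 25·cos(u) + offset + ε, with ε ~ N(0, 5²) %F units, clipped to
  [0, 100]. The offset is set per table so 70% of noise-free responses
  exceed 50% — the high-%F bias characteristic of marketed-drug-like
  collections. The bump shape makes bioavailability peak at intermediate
  values of the latent size/hydrogen-bonding axis and fall off on both
  sides, so ordinary linear least squares underfits the response while a
  kernel regressor recovers it — the qualitative behaviour that motivates
  a nonlinear model. The coefficients are implementation constants chosen
  for that purpose, not estimates of any real structure–bioavailability
  relationship;
- absorption clouds: the well-absorbed class is bivariate normal at
  (AlogP 2.5, PSA 60 Å²) with SDs (1.5, 25) and correlation −0.3; the
  poorly absorbed class is a two-component mixture at PSA 140 Å²
  straddling the well cloud in AlogP — the classes overlap
  substantially, as real absorption classes do in this plane.

What passing tests on synthetic data do **not** show: that the eleven
descriptors capture real oral bioavailability, that the generator's
correlation structure matches any real compound collection (its columns
are independent by construction, unlike real descriptor tables), or that
the synthetic %F spread (≈ 10–75%) matches a real 0–100% dataset. They
do show that every algorithmic component behaves as specified under
controlled conditions with known ground truth.

## Problem sizes and numerical settings

Default problem sizes were chosen as the smallest that make the
statistical checks sharp: 5,000 points for ellipse coverage (binomial SE
≈ 0.3 percentage points), 217 rows for split structure (matching the
emulated study size), 800/400 train/test rows for parameter recovery,
and ≥10⁵ Monte-Carlo samples for the shadow-area oracle (relative error
well under the 2% assertion). Golden-section bandwidth selection is
deterministic, so no seed enters model fitting; all data generation and
embedding is seeded explicitly.

## Known limitations

- Gasteiger charges shift charge-bearing descriptors relative to
  AM1-derived values (see above); comparisons against published absolute
  descriptor values should use the charge-file hook.
- The sphere-exclusion variant, the HASA-2 functional form and the
  acceptor rule are each one of several published conventions; all three
  are isolated behind single functions and documented as choices.
- Quantile-based external-set selection concentrates the external
  compounds at response extremes, where kernel predictions are weakest
  (they are convex combinations of training targets and cannot
  extrapolate); external-set errors are accordingly pessimistic.
- Aromaticity, valence and hydrogen counts follow the toolkit's
  perception model; other toolkits may disagree on borderline
  heteroaromatic systems.
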