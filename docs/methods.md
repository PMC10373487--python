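# Methods

## Representation

A bead *i* of type *I* (one of *N* registered types) is described by a
body-order expansion of its local environment:

* **one-body**: the identity number *Z_I*, a unique positive integer
  assigned per bead type (default 1..N in registry order). CG bead types
  have no elemental number, so *Z* is arbitrary but fixed; uniqueness is
  what matters, because *Z* products separate interaction channels.
* **two-body**: for each neighbour type *J*, a radial histogram over
  (0, r_cutoff] of contributions w_ij · g(R_ij), with the London
  dispersion weight w_ij = ½ Z_I Z_J R_ij⁻⁶.
* **three-body**: for each unordered neighbour type pair {J, K}, an
  angular histogram over [0, π] of contributions v_ijk · g(θ_jik), with
  the Axilrod–Teller–Muto weight
  v_ijk = ⅓ Z_I Z_J Z_K (1 + 3 cos θ_jik cos θ_ijk cos θ_ikj) /
  (R_ij R_ik R_jk)³. The angle binned is the one at the center; distance
  dependence enters only through the weight. Both center–neighbour legs
  must lie inside the cutoff; the J–K leg is unconstrained (the
  environment is center-local). Same-type pairs enumerate each unordered
  bead pair once; cross-type pairs each (j, k) combination once.

Defaults (tuned for CG resolutions): kernel widths σ_r = 0.3 Å and
σ_θ = 0.2 rad, bin widths 0.2 Å and 0.2 rad, r_cutoff = 8 Å, giving 40
radial and 16 angular bins. Prefactors and exponents are overridable in
`SlatmParams` for ablation. The representation is invariant under
translation, rotation and bead relabelling and ignores covalent bonding,
so intramolecular solute structure is encoded (a switch excludes
solute–solute neighbours for ablation).

### Gaussian binning and boundaries

Contributions are smoothed by a Gaussian evaluated at the bin centers and
multiplied by the bin width — a discretized unit-mass kernel (cheap, and
within 0.2 % of per-bin integration at the default σ/width ratio). The
angular domain is bounded, and near-collinear triplets are common in
condensed phases, so angular kernels are *folded* at the support edges
(mass spilling past 0 or past the last bin edge is reflected back in);
a triplet at exactly θ = π therefore keeps its full weight. Radial
kernels are plainly truncated at the range edges; the radial cutoff
already damps edge mass by R⁻⁶. The σ → 0 limit concentrates all mass in
the containing bin but is no longer unit-normalized (midpoint rule);
σ well below the bin width is not a supported regime.

Beads closer than 1e-6 Å raise an error (corrupt geometry); collinear
triplets are handled analytically via clipped cosines, not as errors.

## Ensemble averaging and the molecular spectrum

The Boltzmann average ⟨x_i⟩ is approximated by the arithmetic time
average over snapshots (ergodicity). Each frame is first reduced to the
solute-centered local environment: the solute is made whole under the
minimum-image convention, coordinates are recentered on its centroid, and
beads farther than 11 Å (inclusive boundary) from every solute bead are
discarded. Frame selection by a caller-supplied score (e.g. |insertion
depth − target|, helper provided) keeps the k best frames with stable
ties.

Per-bead averages are summed over solute beads into the molecular
spectrum. Averaging precedes summation; the two commute for arithmetic
means (asserted by a test). Channel bookkeeping: the one-body block
becomes per-type counts × Z; a center of type I against neighbours of
type J pools into the unordered pair {I, J} (N(N+1)/2 channels); triplet
contributions pool into (center type, unordered pair), N·N(N+1)/2
channels when fully enumerated. With N = 14 this is 14 + 105 + 1470
channels before pruning.

## Reduction and difference order parameters

Each channel histogram collapses to a scalar. Four modes are exposed
because the normalization applied in prior condensed-phase work is not
uniquely determined:

* `total-mass` — Σ_b h_b (default of `collapse_channels`): preserves the
  magnitude heterogeneity that the subsequent log transform compresses;
* `total-abs-mass` — Σ_b |h_b|: identical for the non-negative two-body
  channels, but stable for three-body channels, whose *net* ATM mass can
  hover near zero with a noisy sign;
* `mean-mass` — total / number of bins;
* `weighted-coordinate` — mass-weighted mean bin coordinate (discards
  magnitude; exposed for completeness).

The per-compound feature is Δ_c = ln(s_c^A + ε) − ln(s_c^B + ε) with
ε = 1e-12, A the target and B the reference environment. The default
assumes non-negative scalars and errors loudly otherwise; a signed-log
option sign(s)·ln(|s| + ε) exists but is *not* recommended as a default:
for a channel whose net mass flips sign between environments it produces
a difference of order 2·ln(1/ε) that swamps genuine structure. Δ is
exactly antisymmetric under swapping environments and invariant under a
common rescaling of a channel.

### Channel pruning

The dataset assembler drops channels that are zero across every compound
(`observed-only` policy; `all` keeps the full index). The dataset
pipeline additionally zeroes channels whose *presence* is not systematic
— populated in exactly one of the two environments for some compound. An
on/off channel contributes |Δ| ≈ ln(s/ε) (tens of log units) of pure
rare-event noise; in dense condensed-phase ensembles, channels that carry
signal are populated in both environments or in neither. Both prunings
happen before PCA and are recorded in the kept-channel list.

## PCA mapping

PCA is fitted on the column-centered n × D matrix with no whitening
(scikit-learn backend; exact SVD below ~2·10⁶ matrix elements, seeded
randomized SVD above). Each eigenvector is sign-fixed so its
largest-magnitude entry is positive, making models bit-reproducible for
a given seed. Scores of training rows, eigenvalues λ_k (sample variance,
ddof = 1) and explained-variance ratios are stored on the results object;
models persist as a single JSON document so identical seeds yield
byte-identical files.

Interpretation tools:

* **scaled loadings** ℓ_kc = v_kc √λ_k. The √λ scaling is chosen so that
  ℓ reconstructs channel–score covariances (cov(X̂_c, Y_k) = λ_k v_kc,
  asserted in tests) and so that a meaningful absolute threshold (default
  1.0) is possible — raw unit-eigenvector entries are bounded by 1 and
  could never exceed such a threshold. Ties in |ℓ| order
  lexicographically by channel key.
* **dominant interactions**: channels with ℓ ≤ −t, ℓ ≥ t or |ℓ| ≥ t.
  When the target property is a free-energy difference (more negative =
  more selective) and the PC correlates positively with it, negative
  loadings flag selectivity-enhancing channels.
* **interaction graphs**: two-body channel {I, J} adds edge (I, J);
  three-body (I, {J, K}) is projected onto its center–neighbour edges
  (I, J) and (I, K) — the J–K leg is off by default (the center mediates
  the interaction) and available via a flag. Edge weights count
  occurrences, edges carry provenance and category tags
  (solute–solute / solute–environment / solvent). Exported as GraphML
  and DOT.
* **2-D maps (biplots)**: scores min–max scaled per axis to [−1, 1];
  arrows are the six (configurable) two-body channels with the largest
  combined |scaled loading| on the displayed axes.
* **correlation**: OLS of a descriptor on a single PC's scores, reported
  as R² plus the slope sign. Descriptors are normalized by solute bead
  count (once) to remove size effects.
* **classification**: a least-squares separating line on a chosen PC
  pair (labels encoded ±1). The fitted coefficients are reported so the
  line can be overridden by hand; points within numerical rounding of
  the line resolve deterministically to non-selective. One-class
  training sets are rejected.

One-body channels are retained in the matrix; a per-PC diagnostic
(`one_body_share`) reports their squared-loading mass, expected to be
negligible when the two environments share type populations.

The number of retained components d is a required user input: eigenvalue
spectra of these matrices decay smoothly, so no automatic elbow is
claimed.

## Synthetic data generator

The generator emulates a two-environment interface screen at desk scale;
it defines the package's study conditions and is first-class, tested
code.

* **Solutes**: 1–5 beads from the reduced alphabet {T1..T5, Q0},
  linear/branched graphs with exact 4.7 Å bonds and 120° angles, random
  dihedrals, 2 Å overlap floor; deterministic per seed. When an effect
  is planted the first bead carries the planted solute type, so every
  compound exposes the planted channel.
* **Environments**: per (solute type, environment type) radial shells —
  Poisson counts, Gaussian radii — plus a uniform condensed-phase bath
  (POL/C1/P4 at liquid-like densities within 12 Å). The bath keeps the
  common channels populated in every frame, which is what makes channel
  presence systematic, as in real dense liquids. The planted headgroup
  type (Nda) enters only through its shell around the charged solute
  bead. Frames are i.i.d. draws, not dynamics: the featurizer only needs
  an ensemble, and i.i.d. sampling gives exact control of the planted
  structure.
* **Planted signal**: compound i draws a log contrast u_i ~ N(0, 0.8)
  truncated at ±1.5 SD (unbounded draws make extreme shells physically
  unpackable); environment A scales the planted shell's mean count by
  exp(u_i). The target is y_i = β u_i + N(0, σ), σ defaulting to 25 % of
  the signal SD. A bimodal contrast mode produces two separated basins
  for classification tests. The truth record stores β, the channel and
  every u_i.
* **Defaults**: 200 compounds × 2 environments × 50 frames — small
  enough for a laptop, large enough that the planted channel's top-PC
  recovery is stable (best-PC R² ≈ 0.83 against the planted property,
  planted channel within the top-5 scaled loadings at these settings).

What the generator does *not* emulate: real bilayer geometry and
anisotropy, electrostatics, correlated dynamics between frames, and any
particular force field's shell structure. Passing tests on synthetic data
therefore demonstrate the *pipeline's* correctness and sensitivity, not
the transferability of any fitted map to real membranes.

## Numerical choices and limitations

* Internal units: Å and radians everywhere; nm-based inputs are scaled
  on ingest. Minimum-image convention for orthorhombic boxes only; no
  box means open boundaries (after 11 Å truncation, images are
  irrelevant for typical box sizes).
* The environment-shell boundary is inclusive (≤ radius); frame-selection
  ties break toward earlier frames.
* ε = 1e-12 in the collapsed-scalar units; recorded in output sidecars
  together with the collapse mode and kernel convention.
* Heavy-tailed R⁻⁶ weights make raw channel scalars span many orders of
  magnitude; all statistics downstream of the log transform assume the
  collapse mode produces non-negative scalars.
* The exact subset of triplet channels retained in prior work on the
  14-type system (1361 of 1470) follows a rule not recoverable here;
  data-driven pruning (observed-only + systematic presence) is the
  package's stand-in, and the kept-channel list always travels with the
  fitted model.
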