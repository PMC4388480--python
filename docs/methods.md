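# Methods

## Model and assumptions

All orientations are axial: an angle θ and θ + π denote the same
direction, so every statistic is built from even functions of 2θ. A
single construct's organization is the maximum eigenvalue of the mean
order tensor 𝕋 = 2⟨𝐤𝐤ᵀ⟩ − 𝕀 of its unit pseudo-vectors; for a 2×2
symmetric traceless matrix [[a, b], [b, −a]] that eigenvalue is
√(a² + b²), with a = ⟨cos 2θ⟩ and b = ⟨sin 2θ⟩ — equivalently the
resultant length of the doubled angles. The co-orientational order
parameter applies the identical construction to the relative-orientation
vectors 𝐟ᵢ = (cos(βᵢ − αᵢ), sin(βᵢ − αᵢ)) of index-paired constructs.

What the COOP assumes:

* pairs are index-aligned and co-localized; the parameter never sees the
  coordinates except through the pairing (and the grid pipeline's
  partitioning);
* correlation is first-order: a single mean tensor summarizes the joint
  arrangement. Spatially structured mixtures of distinct correlation
  modes in one sample (the anti-correlated construction) or systematic
  sorted pairings (the ultra-correlated construction) push the COOP
  outside [COOP_u, COOP_c] by design, which is why measurements are
  always reported against those bounds;
* the bounds themselves are functions only of the two individual OOPs.

## Numerical choices

* **Eigen-decomposition** is closed-form (√(a² + b²)); no iterative
  solver, hence bit-reproducible results. The eigenvector is assembled
  from whichever of (λ + a, b) / (b, λ − a) avoids cancellation, and its
  sign is canonicalized (first nonzero component positive). For the zero
  tensor every direction is an eigenvector; the x-axis is returned.
* **Angle canonicalization**: storage in [0, π). All formulas act on
  pseudo-vectors, so the representative is unobservable; the symmetry
  test-suite (π-flips of arbitrary subsets, P↔Q swap, global rotation)
  pins this at 1e−12.
* **Director → angle**: the four symmetry-equivalent inter-construct
  angles {θ₀, −θ₀, π−θ₀, θ₀−π} are collapsed by a branch rule keyed to a
  reference director (the sample's own director, or the
  director-of-directors n̂_ALL for multi-sample statistics): references
  with |n̂ₓ| < cos(π/4) (near-vertical mean) report in (0, π) via
  arccos of the x-component, all others in (−π/2, π/2] via arcsin of the
  y-component. This prevents a cluster of nearly equal axial angles from
  straddling a wrap-around (e.g. −5° averaged with 175°). The reported
  angle is the clockwise angle from 𝐩 to 𝐪 under the mathematical
  (y-up) convention; under raster (y-down) image coordinates the same
  number is the counter-clockwise angle.
* **Degenerate normalization**: when COOP_c − COOP_u < 1e−9 the
  normalized COOP is NaN and the regime is "degenerate" — the normal
  range has vanished (e.g. one OOP is 0, or both are 1) and division
  would be meaningless. Regime classification against the bounds uses a
  1e−6 tolerance; it is meant for analytic constructions — sampling
  noise of order n^(−1/2) will legitimately push an estimate a hair past
  a bound, which is a statistical statement, not a regime change, and is
  what the power analysis quantifies.
* **Bound corner conventions**: COOP_c(0, 0) = 1 (normal range [0, 1]);
  COOP_c(x, 0) = 0 for x > 0 (no normal range).

## Error propagation and power analysis

OOP_P and OOP_Q are assumed independent and normally distributed with
equal standard deviation σ_OOP. First-order (delta-method) propagation
gives σ_COOP_u = √(OOP_Q²σ_P² + OOP_P²σ_Q²) and, with the larger OOP in
the denominator, σ_COOP_c = √((lo/hi²·σ_hi)² + (σ_lo/hi)²); the two
branches coincide at equality, where the derivative of min/max does not
exist but the symmetric estimate stays finite. The null hypothesis
COOP_u = COOP_c is tested with a two-sample **Welch** t-test
(Satterthwaite degrees of freedom, two-tailed, α = 0.05 by default) with
per-group size N. Welch rather than pooled variance is pinned by a
regression test: it reproduces the reference maximum tolerable error of
0.18 at OOP_P = OOP_Q = 0.60, N = 4 (the pooled test gives ≈ 0.21).

* `max_tolerable_error` bisects on σ over [1e−6, 2] (tolerance 1e−4);
  the p-value is monotone increasing in σ, and the surface version runs
  the bisection vectorized over an OOP×OOP grid.
* `min_sample_size` exploits the monotone decrease of p in N:
  exponential search for a feasible N, then binary search for the
  smallest, starting at N = 2 and capped at 10⁶ (∞ is returned beyond
  the cap, and immediately when the bounds coincide — including the
  OOP_P = OOP_Q = 0 corner, where σ_COOP_c has no defined derivative).
  At the exact bisection root σ* the test sits at p = α, so the
  round-trip min N(σ* − ε) = N holds just below the root.

## Synthetic generators

The generators reproduce the validation regimes the parameter was
characterized with, and their defaults are those study conditions:

* aligned (OOP = 1) and isotropic (uniform on [0, π)) fields, with 10⁶
  samples for the limiting-case checks;
* truncated Gaussians: N(mean, σ) truncated to mean ± π/2 (the full
  axial period, making the density proper; truncation is applied before
  wrapping into [0, π)). The population OOP is E[cos 2θ] by symmetry,
  evaluated by quadrature; `sigma_for_oop` inverts it by bisection.
* independent pairs (two separate draws) converge to COOP_u;
  noise-coupled pairs (Q = P + independent truncated-Gaussian noise)
  converge to COOP_c. The noise width is calibrated analytically:
  order attenuates multiplicatively under independent noise
  (OOP_Q = OOP_P · E[cos 2θ_noise]), so the width solving
  E[cos 2θ] = target/OOP_P is found by quadrature + bisection — a
  deterministic alternative to recalibrating on sample OOPs; the
  empirical OOP_Q lands within ~1e−3 of target at n = 10⁵.
* the anti-correlated two-mode construction (equal counts of a
  perpendicular and a parallel pair type at ±α) with exact COOP = 0 and
  COOP_u = |cos 2α sin 2α| > 0 for generic α;
* the ultra-correlated sorted pairing (mirrored pairs (αᵢ, αᵢ + θ) and
  (−αᵢ, −αᵢ − θ)), valid when Σcos 2αᵢ ≥ 0, Σcos(2αᵢ + 2θ) ≥ 0 and
  cos 2θ ≥ 0, with COOP − COOP_c = Σ sin 2αᵢ sin 2θ / Σ cos 2αᵢ ≥ 0.

Random spec pairs for the bound-tracking validation draw σ from
U(0.2, 0.8) — spanning OOPs roughly 0.35–0.9, the moderately organized
regime where the normal range is widest and the parameter is informative
— with correlated targets at U(0.3, 0.95) × OOP_P and n = 10⁵ per pair.
Convergence is asserted against the bounds computed from the
**population** OOPs (the product, and the calibrated attenuation
factor): the sampling error of those comparisons is at most ~n^(−1/2),
so the 3/√n tolerance is a genuine three-sigma band; a comparison
against min/max of the *empirical* OOPs would be inflated by 1/max(OOP)
and is not what the bound formulas state.

What the generators do **not** emulate: spatial structure (angles are
exchangeable draws, not textured fields), imaging noise, segmentation
artifacts, or off-focus channel offsets. Passing synthetic tests
therefore validates the estimator and its bounds, not the upstream angle
extraction from micrographs.

## Grid pipeline

Real images are analyzed per grid-square rather than per pixel to
average out pixel-level detection error and small channel offsets.
Defaults and conventions:

* square size 30 px (~4.2 μm at the reference magnification — two
  Z-line spacings, so each square holds at least one sarcomere complex);
  half-open squares [k·s, (k+1)·s) in both axes from a configurable
  origin; raster coordinates (x right, y down), 0-based.
* squares are indexed over the full image extent; partial edge squares
  are kept, with density ρ = count / clipped area, so they are
  down-weighted rather than dropped. Empty squares carry ρ = 0 and an
  undefined (NaN) director and are excluded from pairing — never
  silently treated as angle 0.
* each square's representative is the tensor director (not the circular
  mean), keeping the pseudo-vector symmetry; the square weight is
  W_i = OOP_P,i·OOP_Q,i·ρ_P,i·ρ_Q,i, and the pair-level mean tensor is
  the W-normalized weighted average of the per-square 𝐟 outer products
  (the individual OOPs entering the bounds are weighted the same way).
  This is the natural averaging step consistent with the unweighted
  estimator — it reduces to it exactly when all W_i are equal, and to
  the pixel-level COOP in the one-pixel-per-square limit — though other
  uses of W (e.g. thresholded square selection) are conceivable;
  sensitivity to this choice is untested against real micrographs.
* the pairwise consistency matrix of one construct across co-registered
  samples is symmetric with a unit diagonal by construction; the
  off-diagonal mean is the reported consistency score. Cross-sample
  mean angles use the director-of-directors branch rule above and are
  flagged as unstable when the directors' own order parameter is < 0.1.

## Problem sizes

Analytic identities are asserted at 1e−10..1e−12; sampling-based checks
use 3/√n. The validation suite uses n = 10⁶ for limiting cases, 10⁵ ×
50 pairs for bound tracking, 10³–10⁴ pixels for grid reconstructions,
and 1000 randomized cases per symmetry property — sizes at which the
3/√n bands are decisive while the whole suite stays desk-scale.

## Known limitations

* The COOP is first-order: correlations more structured than the
  ultra-correlated construction are not captured, and a COOP
  significantly above COOP_c should prompt re-evaluating the parameter's
  applicability rather than a larger sample.
* Per-pixel angle detection from raw images is out of scope; the
  pipeline consumes pre-computed angle fields (CSV/TSV), and masking is
  represented by omitting pixels.
* The grid origin cannot be aligned to biological structure and no
  alignment search is attempted; grid-shift sensitivity is exactly zero
  only for block-constant fields.
* `coop_correlated(0, 0) = 1` makes the (0,0) corner discontinuous; the
  power analysis reports ∞ sample size there.
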