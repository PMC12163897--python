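# Methods

## Model and construction

The package computes spectra of combinatorial Laplacian and Dirac operators
attached to the Khovanov cochain complex of an oriented link diagram, with
real coefficients throughout (an inner-product structure is required for
adjoints, which rules out ℤ or ℤ[c] coefficients; real and rational
Khovanov homology have the same ranks).

Pipeline: PD code → cube of smoothings → bigraded basis enumeration →
differential matrices → Laplacian/Dirac assembly → symmetric
eigendecomposition.  The complex is the *unreduced, unsimplified* one: no
Bar-Natan/cancellation reductions are applied, because such reductions
preserve homology but change the non-harmonic spectra, and the non-harmonic
spectra are the point.  Consequently the cost is exponential in the
crossing number (the cube has 2ⁿ vertices and the complex Σ_α 2^{c(α)}
basis elements); the default cap is n ≤ 16 crossings, overridable.

## Conventions (load-bearing)

* **PD tuples.** `X[i,j,k,l]`: edge `i` enters on the under-strand, `j,k,l`
  follow counterclockwise.  Edges are numbered 1… along the orientation,
  one contiguous block per component, wrapping at the block end.  Component
  structure and over-strand directions are inferred by constraint
  propagation (each edge has exactly one successor); for two-edge
  components the over-pass direction cannot be read off the successor map,
  so it is recorded per crossing during validation.
* **Crossing sign.** Positive iff the over-strand direction is 90°
  counterclockwise from the under-strand direction; in tuple terms, over
  running j→l is positive, l→j negative.  This makes
  `X[1,4,2,5] X[3,6,4,1] X[5,2,6,3]` the *right* trefoil with n₊ = 3.
  Note this is the mirror of the Knot Atlas/KnotTheory` reading of the same
  tuple (there that PD is the left trefoil); PD codes imported from
  third-party tables therefore denote the mirror of the table's knot.
  Within the package everything is self-consistent, and mirror images are
  available via `mirror()`.
* **Smoothings.** For `X(i,j,k,l)`, the 0-smoothing joins (i,l) and (j,k);
  the 1-smoothing joins (i,j) and (k,l).  This is the unique pairing that
  reproduces the cycle counts of the trefoil cube (S_000 has 2 cycles,
  every height-1 state 1, S_111 has 3); a dedicated test pins it down.
  Cube bit order is the crossing order of the PD code.  Cycles are named by
  their least edge label.
* **Basis order.** Within a bigrading: by α as an integer, then by the sign
  vector with cycles in increasing label and v₊ < v₋.  Spectra are
  order-invariant; the order only stabilizes printed matrices and exports.
* **Up/down split.** `Δ^{r,q}_up = (d^{r,q})* d^{r,q}` and
  `Δ^{r,q}_down = d^{r−1,q}(d^{r−1,q})*`.  Under this naming the final
  diagonal block of the squared (r,q) Dirac is `Δ^{r+1,q}_down`, and the
  supersymmetry identity reads: nonzero spectrum of `Δ^{r,q}_up` equals
  nonzero spectrum of `Δ^{r+1,q}_down` as multisets.
* **Dirac indexing** starts at the minimal homological degree −n₋, where
  the first nonempty chain group can live; empty intermediate chain groups
  contribute zero-dimensional blocks and the assembly proceeds.

## Numerics

* Differentials are assembled as exact sparse integer matrices (entries in
  {−1,0,1}); floating point enters only at the eigensolver.
* **Kernel dimensions are exact.**  Ranks of the differentials are computed
  in exact integer arithmetic: unit pivots (almost all pivots, given ±1
  entries) are eliminated with pure integer row operations chosen by a
  minimum-fill heuristic, and any residual core without unit entries falls
  back to fraction-free Bareiss elimination.  The numerical zero count
  (threshold `N·ε·max(1, λ_max)`) is reconciled against this oracle; an
  unresolvable disagreement raises a diagnostic error instead of returning
  a silently wrong Betti number.
* Dense `eigvalsh` is used up to 2000×2000 per bigrading (far above any
  bundled fixture); larger blocks fall back to partial sparse
  eigendecomposition of the bottom and top of the spectrum.
* Jones normalization divides the alternating kernel sum by (q + q⁻¹)
  exactly in integer Laurent arithmetic, with the product checked by
  re-multiplication.

## Curve projection

A closed 3D curve (parametric sampler, CSV polyline, or seeded random
trigonometric-polynomial curve) is projected to a coordinate plane;
transverse self-intersections of the closed polyline become crossings with
the greater-depth strand over.  Genericity tolerances, after normalizing
the curve to unit diameter: intersection angle ≥ 10⁻³ rad, distinct
crossings ≥ 10⁻⁶ apart in the plane, depth gap ≥ 10⁻⁹; violations raise a
non-generic-projection error suggesting resampling.  These tolerances are
validated by reproducing the crossing counts 3 (x–z) and 7 (x–y) of the
classic trefoil parametrization, stably under sample-count doubling.

**Plane orientation.**  The two in-plane axes are ordered so that
(a, b, depth) is a *left-handed* triple for every plane (xy→(y,x),
xz→(x,z), yz→(z,y)).  With the package's sign convention this single global
choice makes all three projections of one curve yield diagrams of the same
knot (identical Betti tables — checked for the trefoil curve across xz, xy,
yz), and makes the x–z projection of the classic parametrization reproduce
the standard 3-crossing right-trefoil diagram, crossing for crossing.  The
opposite handedness would systematically mirror every projected diagram.

## Synthetic data

`random_fourier_knot(seed, n_modes=6, n_samples=512)` draws each coordinate
as Σ_m (a_m cos mu + b_m sin mu) with N(0,1)/m coefficients from a seeded
generator.  The 1/m decay with six modes yields smooth closed curves whose
generic projections spread over roughly 0–10 crossings (median ≈ 4):
mostly unknots and small knots, with occasional larger diagrams — enough to
exercise merges, splits, multi-cycle smoothings, and all sign paths.  These
curves emulate the *combinatorial* variety of small knot diagrams; they do
not emulate biomolecular geometry (no excluded volume, no fixed bond
lengths, no open-chain closure).  Passing the property sweep therefore
certifies the algebra (d² = 0, PSD, exact-rank agreement, supersymmetry,
Euler-characteristic and mirror identities) on generic small diagrams, not
any claim about real backbone statistics; real curves enter through the
polyline reader, and open chains must be closed upstream.

## Fixtures

Beyond unknot/Hopf/trefoil/figure-eight: `k8_12` is an 8-crossing, writhe-0
alternating diagram of the amphichiral two-bridge knot 8₁₂ (fraction 29/12,
Conway C(2,2,2,2)), generated from a rational-tangle twist construction.
Flype-equivalent diagrams of the same knot can differ in their non-harmonic
spectra: the fully symmetric 4-plat drawing has S^{r,q} = S^{−r,−q}
everywhere, whereas the bundled diagram realizes the asymmetric spectra
(S^{3,7} ≠ S^{−3,−7} with max eigenvalues 6.92542 vs 7.63299) while its
homology stays symmetric — exactly the phenomenon the chirality report is
built to expose.  `trefoil_xy7` is the frozen 7-crossing x–y projection of
the parametric trefoil; `trefoil_xy5` was obtained from it by removing its
one removable poke (an R2 bigon) by hand — diagram-transformation engines
are deliberately out of scope, so the reduction is shipped as a static PD.

## Limitations

* Exponential scaling in crossing number; no reduced complexes.
* Real coefficients only: no integral torsion, no ℤ[c] or Lee deformations.
* Spectra are diagram invariants, not knot invariants, by design; only the
  harmonic part is Reidemeister-invariant.
* Multi-component links are supported end-to-end, but the chirality report
  does not enumerate orientation-reversal variants of components.
* Zero-crossing components inside multi-component PD codes are not
  expressible and are rejected; the standalone 0-crossing unknot is
  special-cased.
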