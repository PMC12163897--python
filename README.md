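# khovlap

Khovanov Laplacian and Khovanov Dirac spectra of knot and link diagrams.

Knots and links appear throughout structural biology — knotted protein
backbones, linked mitochondrial DNA circles, RNA pseudoknots — and knot
data analysis describes such curves with knot-theoretic invariants.
Khovanov homology is a bigraded homology theory of link diagrams whose
graded Euler characteristic is the Jones polynomial, but as a homology it
discards all geometry of the particular diagram.  This package implements
the spectral refinement of that theory: combinatorial Laplacian and Dirac
operators built on the Khovanov cochain complex, whose *harmonic* spectra
(kernels) recover Khovanov homology exactly while their *non-harmonic*
spectra retain diagram-dependent information — useful, for instance, to
detect chirality in cases where Khovanov homology cannot.

## The operators

For an oriented link diagram `L` with `n` crossings (`n₊` positive, `n₋`
negative), every vertex `α ∈ {0,1}ⁿ` of the cube of smoothings resolves
`L` into `c(α)` disjoint cycles, carrying the graded vector space
`V^{⊗c(α)}{ℓ(α)}` with `V = span(v₊, v₋)`, `deg v± = ±1`.  A basis element
(a smoothing with a sign per cycle) has homological degree
`r = ℓ(α) − n₋` and quantum degree
`q = (#v₊ − #v₋) + ℓ(α) + n₊ − 2n₋`.  Cube edges act by the Frobenius
multiplication (merge) and comultiplication (split), with signs
`(−1)^{#1s before the flipped bit}`, and restrict to degree-preserving
differentials `d^{r,q}: C^{r,q} → C^{r+1,q}` over ℝ.

With the canonical basis orthonormal, the **(r,q) Khovanov Laplacian** is

    Δ^{r,q} = (d^{r,q})* d^{r,q} + d^{r−1,q} (d^{r−1,q})*

and the **(r,q) Khovanov Dirac** is the symmetric block-tridiagonal matrix
of the `d^{i,q}` for `i = −n₋ … r` whose square is
`blockdiag(Δ^{−n₋,q}, …, Δ^{r,q}, Δ^{r+1,q}_down)`.  Key facts, all
verified by the test suite:

* `dim ker Δ^{r,q} = dim H^{r,q}(L; ℝ)` — the real Khovanov homology;
* `Kh(L)(t,q) = Σ t^r q^q dim ker Δ^{r,q}`, and at `t = −1` this is the
  unnormalized Jones polynomial (also computed independently as the
  Kauffman state sum over the cube);
* Dirac eigenvalues are `±√μ` over the Laplacian block eigenvalues `μ`;
* `S^{r,q}(K) = S^{−r,−q}(mirror K)` as multisets, so an asymmetry
  `S^{r,q}(K) ≠ S^{−r,−q}(K)` witnesses chirality of the diagram even when
  the homology is mirror-symmetric.

Kernel dimensions are never left to floating point: every zero multiplicity
is reconciled against an exact integer-arithmetic rank of the differentials.

## Worked example

The right-handed trefoil (PD code `X[1,4,2,5] X[3,6,4,1] X[5,2,6,3]`, three
positive crossings):

```python
from khovlap import fixtures, KhovanovComplex, laplacian, spectrum, betti_table

cx = KhovanovComplex(fixtures("trefoil_R"))
betti_table(cx)
# {(0, 1): 1, (0, 3): 1, (2, 5): 1, (3, 9): 1}
op = laplacian(cx, 0, 3)
op.total
# [[3, 3], [3, 3]]
spectrum(op).eigenvalues        # -> [0.0, 6.0], kernel dimension 1
```

The Betti table says the trefoil has Khovanov homology of rank one at
(r,q) = (0,1), (0,3), (2,5), (3,9) — the signature of the right trefoil,
with Poincaré polynomial `q + q³ + t²q⁵ + t³q⁹`.  The Laplacian at (0,3) is
the 2×2 matrix above; its single zero eigenvalue is that rank-one homology
group, and the least nonzero eigenvalue 6 is diagram data beyond homology.

The same numbers from the command line:

```sh
$ khovlap spectra --fixture trefoil_R --r 1 --q 5
3 6 6
$ khovlap jones --fixture trefoil_R
1*q^2 + 1*q^6 + -1*q^8
```

Diagrams can come from PD text files (`khovlap compute --pd-file my.pd`) or
from closed 3D curves: `khovlap project --curve eq3 --plane xy` projects the
classic parametric trefoil `(sin u + 2 sin 2u, sin 3u, 2 cos 2u − cos u)`
onto the x–y plane (z as depth, greater-z over) and emits the resulting
7-crossing PD code.  `khovlap chirality --fixture k8_12` reports the
bigradings where the spectra of the amphichiral knot 8₁₂ fail to be
mirror-symmetric even though its homology is.

### File formats

* PD text: whitespace/comma-separated `X[a,b,c,d]` tokens, `#` comments.
* Polyline CSV: header `x,y,z`, one point per row, implicitly closed.
* Spectra CSV: columns `r,q,index,eigenvalue`; summary JSON keyed `"r,q"`
  with `dim`, `betti`, `lambda_min_nonzero`, `eigenvalues` (9 significant
  digits, fixed ordering).

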