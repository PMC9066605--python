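# Methods

## Representation and conventions

A spherical ellipse is stored as a unit center vector `c`, a unit major-axis
direction `u ⟂ c`, and *geodesic* angular semiaxes `0 < ξ₂ ≤ ξ₁ < π/2`
(radians). Its quadratic form is `A = uuᵀ/sin²ξ₁ + wwᵀ/sin²ξ₂`, `w = c×u`:
the eigenvalues are the inverse squared *projected* (sine) semiaxes and the
zero-eigenvector is ±c. The two conventions coexist deliberately: geodesic
semiaxes are what a user measures on the sphere, while growth and tangency
scale the sine semiaxes (growing by factor `F` divides the matrix by `F`,
i.e. multiplies each `sin ξ` by `√F`). The equal-circle calibration — two
circles of geodesic radius ρ touch at separation 2ρ with
`F = sin²(θ/2)/sin²ρ` — fixes this reading.

Great-circle ("lemon wedge") limits and inverted ellipses (`ξ₁ ≥ π/2`) are
rejected at construction: they have no meaning as particles, and admitting
them would make the contact branches ambiguous. `make_ellipse`
re-orthogonalizes the supplied major axis against the center (Gram–Schmidt)
rather than erroring on slight non-orthogonality; an axis within 1e-8 of
parallel to the center is an error.

The focal constructor uses `ξ₁ = η` and `sin ξ₂ = √(sin²η − sin²ψ)/cos ψ`
(ψ = half the focal separation), which the tests validate against the
defining focal-sum property by an independent 1-D root-find along the minor
axis, and on 1000 sampled boundary points per random ellipse.

Ellipse areas (needed only for packing fractions) are computed by
trapezoidal quadrature of `∫(1 − cos Θ(ψ)) dψ` over the geodesic polar
radius of the boundary; the integrand is smooth and periodic so node
doubling from 256 converges spectrally (relative tolerance 1e-10).

## Eigen kernel

Symmetric 3×3 eigenvalues are computed in closed form via the trigonometric
solution of the characteristic cubic (all roots real), with the `acos`
argument clamped to [−1, 1] to survive roundoff near degeneracies.
Eigenvectors come from cross products of rows of `M − λI` (best pair by
norm); eigenvalue gaps below `1e-8·‖M‖` switch to completing an orthonormal
frame around the well-separated eigenvector, and every vector's sign is
fixed so its largest-magnitude component is positive, making results
bit-reproducible. The suite cross-checks 1000 random PSD matrices against
LAPACK (`numpy.linalg.eigh`) at 1e-8. One deliberate exception: `omega`
(the smallest nonzero eigenvalue of the two forms, evaluated once per pair)
uses LAPACK directly, because circles make the relevant eigenvalue exactly
doubly degenerate where the closed form loses ~√ε accuracy.

## Contact search

`λ₁(t)` of `Q(t) = A(1−t) + Bt` is maximized on [0, 1] with a bounded Brent
method (golden-section with parabolic interpolation; golden-section only as
the `gss` option), default tolerance 1e-7 in `t`, counting eigenvalue
evaluations. The band vanishes at both endpoints and has a single interior
maximum, so the bracket [0, 1] always contains it. An optional
early-termination threshold aborts as soon as any sample exceeds it (enough
to decide "no overlap" for hard particles); a terminated run reports only a
lower bound and never an `F` value.

The interior minimum of the middle band (the second tangency, needed when
the first contact is with an antipode) is detected from 9 equally spaced
probes *plus* finite-difference slopes of the sorted band at those probes
(step 1e-4; one-sided at the endpoints). Slope sign changes bracket minima
far narrower than the probe spacing — which occur, e.g., for very unequal
circles near θ = π/2 — while remaining meaningful where bands touch, such
as the endpoint degeneracy of any circle. The middle band of a linear
pencil has at most one minimum and one maximum on the whole real line, so
this scan can only miss dips of vanishing depth (the merging-inflection
limit, where the clipped value is approached continuously anyway). Value
probing alone proved insufficient here; the slope scan is the package's
resolution of that gap.

After the optimizer converges, the stationary point is polished by a Brent
*root-find* on the band slope (finite differences, step 1e-6, xtol 1e-11).
This pins the envelope condition `vᵀ(B−A)v = 0` at the reported extremum to
below 1e-5 even for strongly curved bands, where a 1e-7 tolerance in `t`
alone can leave a visible residual; the polish is part of contact-geometry
extraction and is not counted in the optimizer's evaluation statistics.

Branch selection follows the sign test `(v·r_A)(v·r_B) > 0` with Λ₁ first,
then an interior Λ₂, each also requiring the value not to exceed Ω;
otherwise `F = Ω` with no contact point. Two zero-measure situations are
handled deterministically: a contact vector orthogonal to a center (sign
product 0) is retested at `t ± 10·tol` and, if still indeterminate, counted
as a true-pair contact (preferring the first branch); a degenerate
eigenplane at the extremum picks the in-plane direction extremizing the
sign-test product (the 2×2 eigenproblem of the restricted product form),
which is continuous in the closing-gap limit.

Normals of the grown ellipses at the contact point are `n ∝ (A − F·I)v`
(the tangential gradient of the form); at complete overlap (`F = 0`,
identical particles) the normal is undefined and reported absent.

`overlap()` adds the angular pre-tests — separation below `ξ₂ᴬ+ξ₂ᴮ` always
overlaps, above `ξ₁ᴬ+ξ₁ᴮ` never does — and runs the λ₁ search with early
termination at 1 before falling back to full branch selection.

## Brute-force oracle

Ground truth for tests only: overlap by dense boundary sampling (default
2048 points per ellipse) plus center-containment (covers nesting), and the
contact function by bisecting the common growth factor until the grown
pair first overlaps (bracket from 1e-4 up to the great-circle limit,
tolerance 1e-6). Boundary sampling biases the detected tangency scale late
by O((spacing)²), well below the 1e-4 comparison tolerance used. Where the
pair cannot touch in the valid regime the oracle returns its upper bracket,
the analogue of the Ω clip; such pairs are excluded from value comparisons.

## Soft potentials, forces and torques

Pair energies are overlap-only (zero for F ≥ 1): `−ln F`, `1−F` (finite at
complete overlap), and the inverse-power forms `1/F − 1` and
`1/F + 1/F² − 2`, the latter two shifted by constants so the energy is
continuous at contact (the shift does not affect forces). Force *direction*
is the contact normal; the common *magnitude* is `|dE/dF|·|dF/dθ|` with
`dF/dθ` a central difference (step 1e-5 rad) under rotation of one particle
along the center-joining great circle — the analytic pose-derivative of F
is not available in closed form, and the finite-difference magnitude is
validated against an independent energy gradient at 5%. Equal-and-opposite
forces applied at the shared contact point make Newton's third law and
total torque balance exact by construction. In the clipped `F = Ω` region
the potential is constant and forces are identically zero.

## Packing

`grow_and_relax` alternates a global growth step on the shared scale factor
(default 3–6%) with energy minimization, halving the step whenever the
relaxation cannot remove all overlaps, so accepted packing fractions are
monotone and the run ends overlap-free (`min pairwise F ≥ 1 − 1e-9`,
verified at tolerance 1e-7 in `t`). Relaxation is projected gradient
descent with backtracking on rigid per-particle rotations (two tangent
translations + one spin), gradients by central differences restricted to
particles currently in overlapping pairs; quaternion bookkeeping is
unnecessary at these particle counts since poses are renormalized each
step. Candidate pairs are pruned by the `ξ₁ᵢ+ξ₁ⱼ` separation bound instead
of cell lists, and only the lowest eigenvalue band is evaluated — touching
neighbours are always separated by far less than π/2 at these sizes, so
antipodal contacts are excluded by separation alone.

The default initial configuration places particles uniformly at a packing
fraction of ≈ 0.2 (the demo regime: far from jamming, so initial overlaps
are sparse and removable); the bidisperse variant shrinks half the
particles by a factor 1.4 in both semiaxes. The default demo sizes
(N ≈ 40–100, ≤ 8 growth cycles, ≤ 60–150 relaxation iterations) reach
fractions around 0.35–0.5. These runs demonstrate the contact machinery
inside a multi-particle energy minimization; they make no claim of
approaching the jamming point or global optimality, and reported fractions
are sums of particle areas (valid because final states are overlap-free).

## What the synthetic fixtures do and do not show

Random pair fixtures draw semiaxes uniformly (default 0.08–0.6 rad) and a
center separation uniformly between well inside the guaranteed-overlap
bound and past the no-overlap bound, so roughly half of the pairs overlap
and all three contact branches are exercised; fixtures are bit-reproducible
per seed. They cover generic shapes and poses but deliberately avoid the
rejected regimes (near-great-circle ellipses, ξ → π/2) and extreme aspect
ratios beyond ~7; conclusions from the tests apply to particle shapes
within those ranges. Degenerate configurations (identical particles,
concentric circles, antipodal placement, sign-test indeterminacy) are
covered by dedicated deterministic cases instead.

## Known limitations

* The contact function is intentionally undefined beyond the inversion
  limit (clipped to Ω); it is not an analytic continuation and should not
  be used as a long-range distance there.
* Force magnitudes use finite differences; step 1e-5 rad limits their
  relative accuracy to ~1e-4, and the NEG_LOG/INV kinds diverge at
  complete overlap.
* The packing relaxer is a local optimizer; different seeds give different
  (locally) dense packings.
* The brute-force oracle is O(n_boundary) per test by design and is not a
  performance baseline.
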