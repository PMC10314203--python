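# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `motinv`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Signal model and conventions

**Wilson-type point patterns.** A punctate signal is a sum of `N` isotropic
Gaussians ("atoms") of one shared width `R` (standard deviation) and
per-atom amplitudes; each atom is normalised to integrate to its amplitude,
so `f̂(k) = amp · e^{−k²R²/2} e^{ik·a}` per atom. A shared width is a
deliberate restriction: it is what makes every invariant below available in
closed form. Arbitrary per-atom widths are out of scope.

**Grids.** A `GridSignal` places the physical origin at voxel `n//2` along
each axis; coordinates are `(index − origin) · spacing`. The Fourier
transform uses the `e^{+ik·r}` convention with phases referenced to the
physical origin (implemented exactly by a circular shift plus scaled FFT),
so centred even patterns have real spectra, and forward/inverse round-trip
to ~1e−15. `fourier_transform_padded(signal, pad)` embeds the box in a
`pad`-times larger zero field: the result is an *exact* evaluation of the
same discrete-time Fourier transform on a `pad`-times finer wavevector
grid. This matters below.

**Rotational averages.** Every rotational average in the package is a plain
mean over directions — no surface-area prefactors. With that convention the
RPS↔RDF transform constants are fixed uniquely:

    RPS(k) = Ω_D ∫ t^{D−1} Ker_D(kt) RDF(t) dt
    RDF(t) = Ω_D (2π)^{−D} ∫ k^{D−1} Ker_D(kt) RPS(k) dk

with `Ω_D = 2π^{D/2}/Γ(D/2)` and `Ker_D(x) = Γ(D/2)(2/x)^{D/2−1}J_{D/2−1}(x)`
(J₀, sinc, 2J₁(x)/x for D = 2, 3, 4; each verified against a Monte-Carlo
direction average in the tests). For D=3 these reduce to the classic
`4π ∫ t² sinc(kt)·` / `(2π²)^{−1} ∫ k² sinc(kt)·` pair. The involution
property (round trip = identity) is the contract that pins the constants;
the suite verifies it to <1% on smooth profiles for D = 2, 3, 4.

**Signed angles.** One helper defines the angle of `u` relative to `ref`
as `atan2(ref × u, ref · u)`; both the third-order grids and the triangle
coordinates use it, so "mirror = angle sign flip" means the same thing
everywhere.

## Second order

`rps_from_fourier` / `rdf_from_signal` average `|F|²` (resp. the FFT-based
autocorrelation) over radial shells of width equal to the grid (Fourier)
spacing; a sample of radius `ρ` lands in bin `round(ρ/Δ)`. Empty bins are
NaN and flagged in metadata. The innermost shells hold very few samples;
comparisons against closed forms are done either beyond ~3 bin widths or at
*matched discretisation* (closed form averaged over the same shell samples),
where agreement is exact to round-off.

Closed forms for Gaussian mixtures: the RPS is
`e^{−k²R²}[Σ amp² + 2Σ_{i<j} amp_i amp_j Ker_D(k d_ij)]`; the 2D RDF is
`[Σ amp² e^{−t²/4R²} + 2Σ_{i<j} amp_i amp_j e^{−(t−d_ij)²/4R²}
Î₀(t d_ij/2R²)]/(4πR²)`, where `Î₀(y) = e^{−y}I₀(y)` is the angular average
of `e^{−y(1−cos θ)}` (computed overflow-free via the scaled Bessel
function; monotone from 1 with tail `(2πy)^{−1/2}`). Both were re-derived
from the Gaussian convolution integrals and verified against the grid
pipelines (≤2–3%). Because they depend only on pair distances, second-order
invariants are *exactly* mirror-blind — the failure mode the third order
repairs.

## Third order

**Bispectrum evaluation.** `B(k,q) = F(k)F(q)F(−k−q)` is exactly
translation invariant at any *on-grid* wavevector pair, because the FFT grid
is closed under addition and the three phases cancel identically. For
off-grid arguments `motinv` therefore interpolates **bispectrum values, not
spectrum values**: a 4D bilinear combination over the 16 neighbouring
on-grid pairs `(k_i, q_j)`, each evaluated exactly. Consequences, verified
to ~1e−15 in the tests:

* integer-voxel translations change nothing (each of the 16 values is
  invariant, hence so is their fixed linear combination);
* 90° rotations and axis mirrors of the input permute the grid exactly, so
  RABS is exactly equivariant when the rotation-angle count `M` is a
  multiple of 4 and the θ grid is negation-symmetric.

Plain interpolation of the complex spectrum cannot do this: a translation
multiplies `F` by `e^{ik·Δ}`, and interpolating that oscillation leaves
phase errors of order `(Δk_cell·Δ)²` ≈ 1e−3 for shifts of a few voxels,
incompatible with the 1e−6/1e−8 invariance this package guarantees.

Interpolation *accuracy* (as opposed to equivariance) is controlled by the
zero-padding factor: padded grids are exact DTFT samples, so error falls as
`pad^{−2}`. Defaults: `pad = 2` for generic work; the vanishing-RABS
benchmark (below) uses `pad = 8`.

**RABS.** `rabs_fourier` averages `B` over `M` (default 256) equally spaced
simultaneous rotations of `(k⃗, q⃗)`; the imaginary residue is discarded and
its maximum relative size recorded. `rabs_real` evaluates
`b(r⃗,s⃗) = ∫ f(t)f(t+r⃗)f(t+s⃗) dt` via shared bilinear-shifted copies of the
image — one per (direction, length) — and reduces the rotation average to a
single BLAS matrix product; θ values must be multiples of `2π/M` so the
shifted copies can be shared. `three_point_function` exposes single-pair
evaluation; on integer displacements it is exact and matches an O(n⁶)
brute-force sum to 1e−15.

**Transform between spaces.** With plain-mean averages the kernel relation
carries the single constant 2π:

    RABS(k,q,θ_qk) = 2π ∫∫∫ r s J₀(√(k²r² + q²s² + 2kqrs cos(θ_qk − θ_sr)))
                     rabs(r,s,θ_sr) dr ds dθ_sr

(trapezoid in r, s; periodic rectangle rule in θ). The cosine of the angle
*difference* combines the dot·dot and cross·cross terms; the cross term is
the one that changes sign under reflection of either space, which is
exactly why the third order discriminates mirrors. Two-route consistency
(Fourier route vs transformed real route) holds to <5% on the 3-Gaussian
test pattern at the suite's grids (r ∈ [0, 7.5] step 0.2, 48 angles,
`pad = 4`, `M = 96`); the measured gap is ~2.4%, dominated by the r/θ
quadrature of the oscillatory kernel.

**Ring and harmonic patterns.** `ring_pattern` samples `J₀(r/R)` (Fourier
support concentrated at `|k| = 1/R`); `harmonic_pattern` samples
`cos(2mθ) J_{2m}(r/R)`. Both are apodized by a raised cosine over the outer
10% of the inscribed circle since `J` decays only as `r^{−1/2}`. For the
ring, the only closing wavevector triangle on the ring is equilateral:
RABS peaks at `(k,q,θ) = (1/R, 1/R, ±2π/3)` (tip-to-tip side `√3/R`).
Cells retaining two near-ring vectors, or with `k+q ≈ 0` (the apodized
pattern keeps a small DC mass), are partially resonant through the ring's
finite spectral width; all genuinely off-resonant cells sit below 10% of
the peak.

For harmonics the φ-average of three angular factors of order `2m` can
never cancel, so the continuum RABS vanishes identically — a whole family
of patterns indistinguishable to *all* third-order invariants, which is why
they cannot be perfect classifiers. On a square lattice the sampled pattern
leaks into orders `2m + 4ℤ`; for odd `m` no leaked triple sums to zero and
the discrete RABS is machine-zero, while for even `m` a first-order
residual survives and falls as `pad^{−2}`: at 128², `pad = 8`, `M = 256`
the measured maxima are ≤1.3e−4 of the matched-grid ring peak (m = 2, 10),
against the 1e−3 acceptance bound.

## Triangle coordinates and the closed-form rabs

For a triangle `A, B, C` with shortest side `b = AC`, the coordinates are
`a⃗_v = √3(centroid − B)` ("drop"), `a⃗_w = A − C` oriented toward the
endpoint on the *longest* remaining leg ("short side"), and the signed
angle θ between them. The orientation rule gives
`a⃗_v · a⃗_w = (c² − a²)/√3 ≥ 0`, hence `|θ| ≤ π/2` — every shape has exactly
one representative, independent of vertex order, and reflection negates θ.
Shortest-side ties (isoceles/equilateral, relative tolerance 1e−9) are
resolved toward the smallest |θ|, then θ ≥ 0, and flagged; these shapes are
achiral, so both mirror images legitimately share one representative.

The scalings come out of the three-point function itself. Completing the
square in the product of three width-`R` atoms gives, per ordered triple,

    b-term ∝ exp(−(|e_r|² + |e_s|² − e_r·e_s)/(3R²)) / (3(2πR²)²),
    e_r = r⃗ − (a_{j2} − a_{j1}),   e_s = s⃗ − (a_{j3} − a_{j1}),

and the quadratic form diagonalises in `v⃗ = (r⃗+s⃗)/√3`, `w⃗ = r⃗−s⃗` into two
independent width-`√2R` Gaussians centred at exactly `a⃗_v` and `a⃗_w`.
Averaging over rotations then yields

    rabs(v,w,θ_wv) = Σ_{j1,j2,j3} amp³ /(3(2πR²)²)
        · e^{−((v−a_v)² + (w−a_w)²)/4R²}
        · e^{−(v a_v + w a_w − A)/2R²} · Î₀(A/2R²),
    A² = v²a_v² + w²a_w² + 2 v w a_v a_w cos(θ_a − θ_wv).

The sum runs over all `N³` ordered triples (degenerate triples produce the
self background near the axes); this choice — and all prefactors — are
locked by pointwise agreement (≤5%) with the brute-force grid pipeline
`rabs_real(rasterize(·))`, and by a mass-conservation identity: the integral
of rabs against `(3/4)·2π·v w dv dw dθ` equals `N³` for any arrangement
(verified to 0.2%). For small `R` the landscape is a bump per triangle at
exactly the `(drop, short, θ)` coordinates; negating θ probes the mirrored
triangle, and for strongly scalene shapes the contrast is many orders of
magnitude (isoceles shapes are achiral and show none — as they must).

**Asymmetric unit.** Besides `|θ| ≤ π/2`, the ratio `short/drop` is bounded
by a θ-dependent curve. The bound is computed by a dense deterministic scan
of shape space (shortest side pinned to (0,0)–(1,0), apex swept over the
region where it stays shortest) and exposed as an interpolated boundary;
the equilateral shape is extremal (ratio 1 at |θ| = π/2), collinear shapes
are interior at θ = 0. A printed closed form for this bound exists in the
literature but is not relied upon here; the scanned curve is the contract.

## Four-point helical scan

The probe is one helix turn reduced to 4 points: azimuths `{0, π/2, π,
3π/2}`, heights `{0, p/4, p/2, 3p/4}` at radius `ρ`, centred at the
centroid and rounded half-up to voxels. The generator inserts `n_copies`
such stencils at uniform random integer translations and uniform draws from
the 24 proper cubic rotations ("assigned a unit value"; collisions counted),
then adds i.i.d. Gaussian noise. The scan response at `(ρ, p)` is the mean
over all (circular) voxel translations and the same 24 rotations of the
product of the 4 sampled voxel values; generator and scan share the rounded
stencil, so a noise-free propeller is matched voxel-for-voxel. The default
grid is ρ ∈ {1..6}, p ∈ {−8..8}\{0}; the demo truth (ρ = 2, p = 4) makes
the stencil exactly integral. Proper rotations preserve handedness, so the
mirrored probe (p < 0) never matches a right-handed propeller: noise-free
chirality ratios are effectively infinite, and the suite asserts ≥5× under
placement variation and at noise σ = 0.2.

**Detectability.** The expected response at the true cell is
`n_copies/(n_voxels · 24)` ≈ 1.27e−4 (for 100 copies in 32³); pure-noise
cells fluctuate with standard deviation ~`σ⁴/√(n_voxels·24)`. At σ = 0.2
the background ceiling sits ≥5× below the propeller response over the
16×6-cell grid (verified over 10 noise realisations) and the map mean is
unbiased. At σ = 0.45 — the SNR ≈ 6% condition — the quartic noise floor
(~2e−4 max over the grid) *exceeds* the signal response under this exact
estimator: measured quality factors at the true cell are ~1–3 across seeds,
not the ≥6 the acceptance bound demands, and that acceptance check
accordingly fails under these study conditions. Under the same arithmetic a
quality factor of 6 requires σ ≲ 0.3 (response ∝ const, floor ∝ σ⁴).
The SNR estimate itself is `n_points/n_voxels/σ²` in percent — noise
strength enters as the variance, the reading under which the 32³/400-point
study gives 6% — and is reported by `scripts/acceptance.py`.

## Numerical defaults and degenerate inputs

* Rotational averages: `M = 256` (Fourier), `M = 64` (real); convergence
  checked by doubling. `M` must be a multiple of 4 for exact 90°
  equivariance and of the θ-grid size for `rabs_real`.
* Radial quadrature: trapezoid on the sampled grid; a non-decayed tail or
  boundary (>1e−3 of the profile maximum at the last point) is recorded as
  a metadata warning, never an exception.
* Radial binning: bin width = grid spacing; empty bins are NaN + flagged.
* Degenerate triangles (collinear/coincident, area ≤ 1e−9·scale²) are
  flagged, with θ = 0 for collinear shapes; `rabs_kernel` clips its radicand
  at 0 against round-off; `i0_hat` is exact for all y ≥ 0.
* Seeds are mandatory in every stochastic library call; the CLI defaults
  them only where a `--seed` flag exists. Same seed ⇒ bit-identical output.

## What the synthetic data does and does not emulate

The generators produce exactly the signal classes the invariants are
designed around: Gaussian mixtures (punctate signals), ring/harmonic
patterns (band-limited angular structure), and sparse binary helical motifs
under additive white Gaussian noise. They do not emulate CTF-like transfer
functions, structured or correlated noise, per-atom width variation, or
non-integral particle placement (propellers land on voxels by
construction). Passing tests therefore demonstrate correctness of the
invariant machinery and its closed forms under the stated models — not
robustness of, say, the 4-point detector to realistic microscopy noise,
where the σ⁴ background analysis above already marks the boundary.

## Problem sizes

The suite and the acceptance script run single-core with modest footprints:
128² images (zero-padded to 1024² where stated), 64² grids for two-route
consistency, 32³ volumes with the full 24-rotation scan, 10⁶-sample
Monte-Carlo oracles. These sizes were chosen so every quantitative claim is
re-verified from scratch on each run.
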