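# motinv — motion invariants of 2D/3D signals

`motinv` computes descriptors of images, volumes and point patterns that are
unchanged by simultaneous rotation and translation (the Euclidean "motion"
group). Such invariants let you compare, classify and search signals — e.g.
particle images in cryo-EM, textures, point clouds — **without aligning them
first**. The package implements the second-, third- and fourth-order members
of this family, in both real and Fourier space, together with the exact
transforms that connect the two representations, so you can always work in
whichever space your signal is most compact.

## What it computes

**Second order.** The radial power spectrum and radial distribution function,

```
RPS(k) = ⟨ |F(k k̂)|² ⟩_k̂          RDF(t) = ⟨ ∫ f(s) f(s + t t̂) ds ⟩_t̂
```

are an exact Hankel-type transform pair,

```
RPS(k) = Ω_D ∫ t^{D-1} Ker_D(kt) RDF(t) dt,
RDF(t) = Ω_D (2π)^{-D} ∫ k^{D-1} Ker_D(kt) RPS(k) dk,
```

with `Ker_D` the direction-average kernel (`J₀` in 2D, `sin x / x` in 3D,
`2J₁(x)/x` in 4D) and `Ω_D` the unit-sphere area. The transform is an
involution: the two invariants carry identical information. Both are blind to
mirror reflection — they depend only on pair distances.

**Third order (2D).** The bispectrum `B(k,q) = F(k)F(q)F(−k−q)` is
translation invariant because its wavevectors sum to zero. Its rotational
average `RABS(k, q, θ)` — a function of two lengths and the signed angle
between the vectors — measures the resonance of the signal with triangles of
a given shape. Its real-space sibling `rabs(r, s, θ)` is the rotationally
averaged three-point correlation, and the two are linked by a single-`J₀`
kernel whose cross-product term flips sign under reflection: **third-order
invariants see mirrors**, which second-order ones cannot.

**Triangle coordinates.** For punctate signals (sums of `N` identical
Gaussians — the Wilson model), `rabs` has a closed form: a sum of bumps, one
per ordered vertex triple, located at symmetric triangle-shape coordinates
`(drop, short side, signed angle θ)` with `|θ| ≤ π/2` and mirroring ≡
`θ → −θ`. A pattern of `N` points is thereby summarised by its C(N,3)
triangles — a strictly richer, chirality-aware alternative to the
pair-distance set.

**Fourth order (3D).** 3D chirality is invisible to third-order invariants;
`motinv` provides a 4-point helical probe (one turn of a helix reduced to 4
points; the sign of the pitch is the handedness) and a `(radius, signed
pitch)` resonance scan over noisy volumes that recovers the generating
parameters of helical "propellers" and distinguishes their handedness.

## Worked example

Generate a random 5-point pattern, tabulate its triangles, and compare it
with its mirror image:

```bash
$ motinv gen pattern --seed 7 --n-points 5 --out pat.csv
$ motinv triangles --points pat.csv --out tri.csv
wrote tri.csv (10 triangles)
$ head -3 tri.csv
i,j,k,drop,short,theta,degenerate,tie
0,1,2,2.985255435525347,0.4137834913081309,0.773722261612465,False,False
0,1,3,4.011493587753691,2.086269347211814,-0.11989242731248469,False,False
```

Each of the 10 = C(5,3) rows is one triangle in `(drop, short, theta)`
coordinates: the rescaled median toward the vertex opposite the shortest
side, the shortest side, and their signed angle (the chirality label).

```bash
$ motinv mirror-compare --points pat.csv --out mc.json
{
  "rps_max_rel_diff": 0.0,
  "rabs_separation": 0.006604380988536784,
  "rabs_after_mirror_map": 8.04561406683453e-17
}
```

The pattern and its mirror have *identical* radial power spectra
(`rps_max_rel_diff = 0`), yet their third-order landscapes differ
(`rabs_separation` ≈ 0.7% of the landscape peak) — and negating the angle
(`mirror_map`) restores agreement to machine precision: the two patterns are
mirror images and the invariants prove it.

The 4-point chirality demo — 20 helical propellers (radius 2, pitch 4
voxels) hidden in a 32³ volume under Gaussian noise of amplitude 0.2:

```bash
$ motinv propeller-demo --seed 3 --noise 0.2 --copies 20 --outdir demo
{
  "truth": { "radius": 2.0, "pitch": 4.0, "n_copies": 20, "noise_sigma": 0.2,
             "seed": 3, "collisions": 0 },
  "peak": { "radius": 2.0, "pitch": 4.0, "response": 5.499631852669398e-05 },
  "quality_factor_at_truth": 6.6371557789657345,
  "snr_percent": 6.103515624999999
}
```

The scan's maximum lands exactly on the true `(radius, pitch)` — including
the pitch *sign*, i.e. the handedness — at 6.6× the next-largest response,
at an estimated SNR of ~6%.

The same functionality is available as a library (`import motinv`):
`rasterize`, `fourier_transform`, `rps_from_fourier` / `rdf_from_signal`,
`rps_to_rdf` / `rdf_to_rps`, `bispectrum`, `rabs_fourier` / `rabs_real`,
`rabs_real_to_fourier`, `mirror_map`, `triangle_coordinates`,
`enumerate_triangles`, `rabs_closed_form`, `four_point_scan`,
`snr_estimate`, plus generators (`ring_pattern`, `harmonic_pattern`,
`propeller_volume`) for all the synthetic signal classes used in the tests.

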