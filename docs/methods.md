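# Methods

## Model and assumptions

The electrical source of an early ectopic beat is modelled as a single
current dipole with fixed position and time-varying moment. This is valid
only during the earliest part of the beat, when the activated myocardial
region is small; the package therefore works on maps covering the first
30 ms of an averaged beat (default 30 samples at 1000 Hz). The torso is a
passive piecewise-homogeneous, isotropic volume conductor with an insulating
exterior. Candidate source positions are restricted to the vertices of the
endo-epicardial ventricular surface mesh, so a localization result is always
one of those vertices and the localization error is quantised by the heart
mesh's edge length (~20 mm at the default refinement).

## Boundary element forward model

Surface potentials satisfy the classical second-kind integral equation for
nested homogeneous compartments; the primary term of a dipole with moment
`p` at `r0` is `g(r) = p.(r - r0)/(4 pi |r - r0|^3)`, independent of
conductivity. Discretisation choices:

- **Vertex collocation with lumped linear weights.** Potentials are carried
  at mesh vertices. Each triangle's solid angle at a collocation point is
  computed with the analytic plane-triangle (van Oosterom–Strackee) formula
  and lumped in equal thirds onto the triangle's corners. Electrodes and
  candidate sources are mesh vertices, so no interpolation is ever needed.
- **Auto solid angle by row sum.** Triangles incident to the collocation
  vertex are skipped (the analytic formula degenerates there) and the
  own-vertex coefficient is set so that each own-surface row totals exactly
  2 pi. This simultaneously handles the singular integrals and makes
  constant potentials an exact solution of the discrete system.
- **Deflation and referencing.** The assembled operator has a rank-1 null
  space (potentials are defined up to a constant). A rank-one term
  `(1/N) 1 1^T` on the outermost-surface block removes it; all outputs are
  then re-referenced to zero mean over torso vertices. Crucially, the
  fitting routines re-reference *both* the measured map columns and the
  transfer-matrix rows to zero mean over the electrodes actually used (the
  full montage or a reduced subset), making every fit independent of the
  recording reference. Without this pairing, exact recovery on noise-free
  data is impossible.
- **One factorisation per conductor.** The dense system is LU-factorised
  once and reused for all candidate sources (3 right-hand sides per source).

Accuracy against analytic sphere solutions (insulated homogeneous sphere,
radius 100 mm): central dipole 0.21% relative RMS error at 642 vertices;
eccentric dipole (55% radius, oblique moment, 60-term Legendre series)
1.9% / 0.34% / 0.07% at 162 / 642 / 2562 vertices — converging under
refinement. These numbers are recomputed by the test suite and the
acceptance script.

Default conductivities: torso 0.2 S/m, lungs 0.25x, blood cavities 3x
(all configurable). The ventricular surface itself is *not* a conductivity
interface: the myocardium is assigned bulk torso conductivity, and the
cavity surfaces live strictly inside it.

## Inverse solution

The moment fit at a candidate is the SVD pseudoinverse solution with a
relative singular-value cutoff of 1e-12; transfer blocks are 3-column and
well conditioned on sane geometry, so the cutoff only guards degenerate
inputs (a rank-deficient block triggers a RuntimeWarning). RRE lies in
[0, 1] by projection geometry; values are clipped at 1 against roundoff.
The winner over `(t, j)` uses the deterministic tie-break smallest `t`,
then smallest `j`. The full moment trajectory at the winner is retained for
diagnostics, not just the winning sample.

## Electrode significance

Subset scores are evaluated through the 3x3 Gram matrix `G = T_s^T T_s`:
its eigenvalues are the squared singular values, adding an electrode row is
a rank-1 update, and a closed-form trigonometric symmetric-3x3 eigensolve
vectorises over millions of subsets. The exhaustive best-4 stage at M = 128
enumerates all 10,668,000 quadruples in ~12 s; agreement of the Gram path
with direct LAPACK SVD is a tested invariant (< 1e-8 relative; in practice
~1e-15). Exact zeros of `sigma_2, sigma_3` return from the Gram path only
to sqrt(machine-eps) relative accuracy — irrelevant for ranking, documented
for metrology.

Deliberate policy choices where the method itself is silent:

- **Ties** resolve to the lexicographically smallest index set (exhaustive
  stage) or smallest electrode index (greedy steps) — determinism across
  platforms.
- **Criterion A degeneracy:** when `sigma_3 < 1e-12 sigma_1` the condition
  number gets a `+inf` sentinel (worst possible), keeping the ordering
  total.
- **Montages beyond 160 electrodes** would make C(M,4) enumeration
  burdensome; the search then subsamples 2,000,000 random quadruples with a
  RuntimeWarning unless full enumeration is forced. At the default M = 128
  enumeration is always full.
- Criterion B and C greedy score sequences must be non-decreasing (singular
  values cannot shrink when a row is added); this is asserted on every run,
  not only in tests.

## Two-step pipeline

The significance ranking is computed for the *estimated* origin from step
one, on the assumption that significance varies slowly with source position.
The second step re-scans the full candidate set (not a neighbourhood of the
first solution) with the stack and map restricted to the top-k electrode
rows; reduced maps are re-referenced over the retained subset. Each k also
carries a flatness diagnostic of the RRE surface — the ratio of the 5th
percentile to the median of per-position best RRE. Values near 1 mean the
surface has no identifiable minimum, which is typical for k <= 8; such
solutions are reported, not suppressed. Default reporting uses k = 32, 64
and the full montage.

## Synthetic phantoms

`PhantomSpec` fixes the emulated acquisition: 16 strips x 8 electrodes
(M = 128) snapped to torso vertices over the central 60% of the torso's
height, 30 samples at 1000 Hz, torso/lung/cavity conductivity ratios
1 / 0.25 / 3. Geometry is ellipsoidal (torso 150 x 110 x 280 mm semi-axes;
ventricular surface 45 x 40 x 55 mm; two lungs and two cavities available,
verified nested and disjoint), built from subdivided icosahedra so phantom
generation is bit-pure. The source trajectory is a fixed seeded random unit
direction with linearly ramping magnitude (peak 15 mA.mm, a field-typical
equivalent-dipole scale; RRE and LE are scale-free, so the peak only sets
absolute map amplitudes). Noise is white Gaussian scaled to a global SNR on
the vectorized clean map; default 20 dB. Problem sizes used throughout
(162-vertex candidate mesh, 642-vertex torso, 10-seed noise studies) keep
every experiment desk-scale while preserving the M = 128 montage and the
30-sample window of the emulated recordings.

What the phantoms do **not** emulate: anatomically realistic ventricular
geometry, propagating activation (the source never moves or spreads),
correlated or line-frequency noise, electrode-contact artefacts, and
segmentation error in the conductor geometry. Consequently, passing the
inverse-crime and noisy-recovery suites demonstrates algorithmic
correctness — the estimator recovers what its own forward model produced —
not clinical-grade accuracy on real recordings. The `inverse_crime=False`
mode simulates on a once-refined torso mesh (electrodes pinned to the same
physical sites) to expose forward-model discretisation error; localization
then degrades gracefully instead of being exact.

## Known limitations

- Single-dipole source model only; no distributed or multi-dipole variants.
- Isotropic, piecewise-constant conductivity; no anisotropy.
- Localization is quantised to heart-mesh vertices.
- The greedy ranking is locally optimal by construction; it does not claim
  the globally best k-subset for any k > 4.
- Lumped (rather than fully consistent linear-Galerkin) solid-angle weights
  trade a small amount of BEM accuracy for simplicity; the sphere oracles
  bound the effect.
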