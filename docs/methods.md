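# Methods

## Model and procedure

The reconstruction operator is classical parallel-beam FBP over a 180°
angular range: each sinogram row is convolved with the exact band-limited
ramp (Ram-Lak) kernel

    h(0) = 1/4,    h(n) = -1/(n·pi)^2  (n odd),    h(n) = 0  (n even, n != 0),

scaled by `1/bin_spacing^2`, then backprojected with the view-angle
quadrature weight `pi/n_views`.  No apodization window is applied.  Written
as a matrix, `A = B·H` with `H` the (symmetric Toeplitz) filter and `B` the
backprojector.

The MAR objective is the energy of the unphysical negative pixels of the
reconstruction,

    F(P) = || min(0, A·P) ||_2^2 ,

minimized over the metal-affected projection entries `P_M` only.  The trace
`P_M` is identified once, before the iteration: threshold the raw FBP image
at `seg_fraction · max` (default 1/3, ties kept), forward project the
thresholded metal-only image, and flag every sinogram bin receiving a
positive contribution (practically: above `1e-9 ×` the projection maximum,
to absorb interpolation-footprint rounding).  `min(0, ·)` is not
differentiable at zero; the subgradient `2·Aᵀ·min(0, A·P)` — zero taken at
the kink — drives the restricted descent

    P_M ← P_M − beta · D[ 2·Aᵀ·min(0, A·P) ] ,

where `D` zeroes everything off the trace.  Off-trace entries are therefore
bit-identical to the measurement at every iterate; this conservation is
asserted exactly in the tests.  After a fixed number of iterations the
final image is one more FBP.  The naive comparator `max(0, X_raw)` (clamp
negatives) is kept in the package because demonstrating that the iterative
result differs from it — at pixels that were never negative — is the
method's defining claim.

## Discretization and the matched adjoint

No standard discretization is canonical here, so the pair was chosen to
make the subgradient exact for the *discrete* objective:

* **Forward projector** — pixel-driven splat.  At each view the pixel
  centre projects to the continuous detector coordinate
  `t = x·cos(theta) + y·sin(theta)`; its value is split linearly between
  the two nearest bins with weight `pixel_spacing^2 / bin_spacing` (pixel
  area over detector pitch, which makes the accumulated value a line
  integral).  Rays beyond the grid contribute zero.
* **Backprojector** — the literal matrix transpose of the splat, times
  `pi/n_views`.  The dense-matrix identity `B = (pi/n_views)·Fᵀ` holds to
  better than 1e-10 (it is exact up to float rounding).
* **Adjoint of FBP** — `Aᵀ = (pi/n_views)·H·F`: forward projection followed
  by ramp filtration, carrying the same quadrature scalar so that
  `⟨A·s, x⟩ = ⟨s, Aᵀ·x⟩` holds to machine precision and a central-difference
  probe of `F` matches the subgradient to better than 1e-4 relative.
* **Filtration** — exact Toeplitz matrix product per view (equivalent to
  direct spatial convolution with zero extension); exactly symmetric and
  fast at these detector sizes.

With `pixel_spacing = bin_spacing` (true of both presets) this FBP is
quantitatively correct: the interior of a closed-form disk sinogram
reconstructs to ~0.1% of its true attenuation (the tests require 5%).
Pixel-driven splatting aliases worst at 45°, where single-bin line
integrals of a sharp disk deviate by up to ~10%; view-averaged profiles are
within ~2%.  This is inherent to the projector class and does not affect
the matched-adjoint property.

Image coordinates: origin at the grid centre, pixel centres at
`(idx − (n−1)/2)·spacing`, view `i` at angle `i·pi/n_views` in [0, pi),
detector centred on the rotation axis.

## Optimization parameters

* `beta = 1` (default), fixed iteration count `K = 500` (default), no
  early stopping; the objective history is recorded at every iterate for
  audit.  If a step would increase `F`, it is retried with the step halved
  (up to 20 times, persistent); exhausting the budget accepts the step and
  raises a divergence flag.  On the bundled phantoms `beta = 1` is accepted
  unhalved and the descent is monotone.
* `seg_fraction = 1/3` of the image maximum, inclusive at the threshold.
* An empty metal trace (nothing segmented, e.g. an all-zero image) is a
  warned no-op returning the raw reconstruction — the algorithm has nothing
  to optimize without metal.

## Synthetic data

The simulator exists because metal-corrupted scanner data cannot ship with
the package.  It uses a discrete-spectrum Beer–Lambert model: five energy
levels (40–120 keV), fluence weights (0.15, 0.30, 0.30, 0.15, 0.10), a
water-like soft material (0.0268 → 0.0160 mm⁻¹ across the spectrum) and an
iron-like metal (1.20 → 0.09 mm⁻¹).  These are documented model constants,
not physical table lookups.  Each material's *reference* attenuation is the
fluence-weighted mean of its curve (~0.021 and ~0.45 mm⁻¹; 22× contrast),
which by Jensen's inequality makes every polychromatic measurement
strictly smaller than its reference-energy monochromatic value — the
mechanism that produces dark streaks and negative undershoots.  With a
single-energy spectrum the model reduces exactly to the monochromatic line
integral, which the tests exploit.

The demo phantom is a soft tapered oval (cosine rim roll-off) with a
low-density inclusion and two sharp metal disks (5.5 and 4.5 mm radius,
positions jittered by the seed), sitting on a uniform soft pedestal
(0.012 mm⁻¹) that covers the whole grid — the object in a filled tray.  The
pedestal matters: it keeps the true attenuation positive everywhere, so
raw-FBP negativity is confined to the metal neighbourhood (hardening
undershoots plus edge ringing at the metal rim) rather than being dominated
by zero-mean ripple in air, which is the regime a negativity-penalizing
method addresses.  Generation asserts, and fails loudly otherwise, that the
raw FBP is negative near the metal and that the true metal attenuation
clears three times the segmentation threshold.  Optional Poisson noise on
the transmitted intensity is available behind a seeded flag but off by
default — the method targets deterministic bias, not noise.

What the simulator does **not** emulate: continuous tube spectra, scatter,
detector response, photon starvation, partial-volume metal edges, or any
specific scanner.  Passing tests therefore demonstrate the algorithm's
mechanics (descent, conservation, distinctness from clamping, artifact
reduction against a known truth) — not clinical or security-screening
performance on real data.

## Problem sizes

Two geometry presets are provided: the full scanner geometry (180 views,
597 bins, 420 × 420 image, 0.92 mm sampling) and a proportionally reduced
test preset (90 views, 128 bins, 96 × 96, same 0.92 mm pitch).  The test
suite and the acceptance script exercise the complete 500-iteration
protocol at the test preset (a run takes seconds); the full preset runs
through the same code path via `--preset scanner`.

## Known limitations

* The iteration count is fixed, not adaptive; `F` typically plateaus well
  before 500 iterations on the test preset.
* Minimizing the negativity *energy* does not minimize the negativity
  *count*; residual negatives of tiny amplitude can remain (and on
  phantoms whose truth is zero across large regions, symmetric
  reconstruction ripple makes the count an uninformative statistic).
* Step size `beta` is dimensionally tied to the documented operator
  scaling; other scalings would need the halving fallback or a different
  default.
* Parallel-beam only; no fan/cone geometry or rebinning.
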