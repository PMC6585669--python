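# Methods

## Scope and model

`myelinsim` predicts the susceptibility-weighted multi-echo GRE signal of
white matter from 2D cross-section geometry. The model chain is

1. **Geometry** — a label map (0 extra-axonal, 1 intra-axonal, 2 myelin) on a
   square raster with physical pixels (um). Axons are closed nested
   polygons; fibers are assumed straight and infinite along z, so everything
   is two-dimensional and the field problem lives on the k_z = 0 plane.
2. **Susceptibility** — only myelin carries susceptibility, expressed per
   pixel as a symmetric rank-2 tensor (ppb) relative to the aqueous
   reference. In the local bilayer frame the tensor is
   `chi_i I + chi_a diag(1, -1/2, -1/2)` with the distinct (long) axis along
   the bilayer normal, i.e. the radial direction of the sheath; it is rotated
   about z by the pixel's azimuth phi. The anisotropic part is traceless;
   this normalization of `chi_a` is fixed by requiring the solver to
   reproduce the hollow-cylinder intra-axonal shift
   `(3/4) chi_a sin^2(theta) ln(1/g) f0` (a rank-1 radial anisotropy of the
   same magnitude gives only 2/3 of that shift). Two empirical consequences
   confirm the choice: a concentric axon at g = 0.7, chi_a = -120 ppb,
   theta = pi/2, 7 T yields -9.6 Hz inside the axon, and the myelin-water
   frequency distribution develops its characteristic humps near 0 and
   +25 Hz.
3. **Field** — the k-space dipole expression
   `df = IFT{ H^T X H / 3 - (H.k)(k^T X H)/k^2 } * 1e-9 * f0`, evaluated
   component-wise with full FFTs on both axes and `f0 = gamma_bar * B0`
   (`gamma_bar` fixed at 42.58 MHz/T). The DC bin is set to zero, which
   makes the raw solution zero-mean over the grid (a gauge choice); the
   pipeline then shifts the field so the *extra-axonal modal frequency*
   (0.1 Hz bins) sits at 0 Hz, because the aqueous space is the physical
   reference against which measured peak positions and phase evolutions
   are quoted. At 64% fiber density the two gauges differ by ~1.5 Hz, so the
   explicit re-referencing step matters.
4. **Signal** — `S(t) = sum_n rho_n e^(-t/T2_n) sum_px e^(i s 2pi df t)`
   over the three compartments within a centred circular sampling mask
   (default half the grid area, which keeps the periodic-edge artefacts of
   the FFT out of the sampled region; no zero-padding is used). Magnitude is
   normalized to S(0) = sum rho_n N_n; phase is unwrapped along the echo
   axis, with zero-magnitude samples (beat nulls) interpolated from their
   neighbours. The default sign convention s = +1 makes phase follow
   frequency sign; s = -1 gives the conjugate convention, and phase
   comparisons are made on |phase|.
5. **Diffusion** (optional) — a 2D Monte Carlo random walk: Gaussian steps
   with per-axis sigma = sqrt(2 D dt), D = 2 um^2/ms outside myelin, myelin
   impermeable (steps into it are rejected by default; a reflect rule
   re-draws once) and its water immobile but phase-accruing with rho = 1/2.
   Spins leaving the grid wrap periodically, consistent with the field's
   FFT periodicity. Per-spin phase accumulates as s*2pi*df(pixel)*dt and is
   snapshotted (linearly interpolated) at the echo times.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| T2 intra / extra / myelin | 50 / 50 / 15 | ms | literature compartment values |
| rho intra / extra / myelin | 1 / 1 / 0.5 | – | myelin water fraction |
| chi_i, chi_a (myelin) | -60, -120 | ppb | variants: isotropic-only (-100, 0), reduced anisotropy (-60, -70) |
| B0, theta | 7, pi/2 | T, rad | fiber perpendicular to the field |
| gamma_bar | 42.58 | MHz/T | proton |
| packing | n = 1434, Gamma(shape 5.7, mean 0.46 um), g = 0.7 | | outer-radius distribution |
| fiber density | 0.64 | – | i.e. 36% extra-axonal space |
| echo presets | 0–55 ms x 100; TE 3–55 ms / 4 ms | ms | free-induction; multi-echo readout |
| D free / myelin | 2 / 0 | um^2/ms | along-axon diffusivity |
| step time | (4 px)^2 / (4 D) | ms | rms step ~4 pixels |

## The synthetic geometries

**Packing.** Outer radii are gamma-distributed; the inner radius is g times
the outer. Centres start uniformly at random and overlapping pairs are pushed
apart iteratively while the radii grow from 50% to full size (random
placement plus collision-resolving relaxation); a run fails loudly if
overlaps cannot be resolved. A 37-um square domain for 1434 fibers of mean
radius 0.46 um would imply ~82% fiber density, which is inconsistent with a
36% extra-axonal fraction — so the generator keeps the measured radius
distribution and count and sizes the domain so the realized fiber density is
exactly 64% (extent ~41.6 um). The dipole field is scale-free, so frequency
statistics are unaffected by this choice; the volume fractions, which do
affect the signal, are the EM-matched ones (myelin fraction 0.33 at g = 0.7,
matching the healthy myelin volume fraction ~0.32).

**Warp.** The non-circular packing is produced by the area-preserving
azimuthal swirl (r, theta) -> (r, theta + alpha(r)) about the domain centre
with alpha(r) = A ln(1 + r/r0) plus a small damped radial ripple (defaults
A = 0.7, r0 = 0.5 um). In polar form the map has unit Jacobian, so every
axon's areas, g-ratio and the global fiber density are conserved exactly (up
to polygon discretization, < 1e-5 relative), and since the map is a
bijection, disjoint axons stay disjoint at any amplitude. The logarithmic
profile gives near-uniform local shear r alpha'(r) ~ A, so ~90% of axons
drop below circularity 0.95.

**Irregular axons.** A synthetic stand-in for hand-segmented micrographs:
each packed circle's boundary is modulated by random radial harmonics
(orders 2–9, red 1/k spectrum, relative sd 0.15), the inner boundary gets a
partially independent modulation (azimuthally varying sheath thickness), and
each axon's g-ratio is drawn from N(0.70, 0.05) — micrograph-like scatter;
the population mean stays 0.70. Inter-axon collisions are resolved by
nudging whole axons apart, with roughness damping only as a fallback. The
g scatter is what blurs the intra-axonal frequency cluster (the interior
shift is second-order insensitive to shape and thickness variation at fixed
g, so without scatter the cluster stays as sharp as the circular model's).

**Demyelination.** Myelin is thinned from the inside out: the inner boundary
is scaled about the axon centroid (polygon sets, exact) or innermost myelin
pixels are reassigned to intra-axonal space in order of distance to the
axon (rasters, within one pixel-layer). Removed myelin becomes intra-axonal
water; outer boundaries, hence fiber density, never change. Whether cleared
myelin should become intra- or extra-axonal space is not dictated by the
observations being modeled; intra is chosen because g = sqrt(A_i/A_t) can
only increase at fixed A_t if A_i grows.

**What the generators do not emulate:** axonal undulation along the tract
(the model is strictly 2D), unmyelinated axons and glial/iron inclusions,
open or fragmented sheaths, and spatial correlations of a specific published
packing algorithm. Passing tests therefore validate the solver and the
stated population statistics, not the fine spatial texture of real tissue —
see "knife-edge observables" below.

## Numerical choices

- Pixel centres at (i + 0.5) * pixel_size, origin lower-left, azimuth
  counterclockwise from +x; rasterization is a hard centre-point test with
  first-come priority on conflicting claims (logged).
- Bilayer azimuth per myelin pixel about its axon's centroid; `wedge` mode
  (default) quantizes into per-axon azimuthal quadrilaterals with arc
  <= ~2 px (>= 16 wedges), `continuous` keeps the exact azimuth; the two
  differ by < 0.5 Hz in intra-axonal mean frequency. Myelin pixels of merged
  fiber components are attributed by signed distance to the outer boundary,
  ties to the lower index.
- Full fft2/ifft2 (not rfft2): the dipole coefficient is odd in k along the
  Nyquist column, which a half-spectrum cannot represent; with full
  transforms the solver agrees with a naive-DFT brute-force evaluation to
  1e-6 relative on 64-px grids (the suite's independent oracle).
- Static signal: pixel frequencies are quantized to 1 mHz so the sum
  collapses onto the compartment spectrum (phase error < 1e-3 rad over
  100 ms).
- Histograms: 0.5 Hz bins aligned so 0 Hz is a bin centre; peaks are
  reported as bin centres.
- Packed-model resolution: generation and measurement at the full 4454^2
  where it matters (volume fractions, the demyelination magnitudes, whose
  g = 0.98 sheath is ~1 px thick), 2227^2 in the test suite's repeated
  pipelines; the field statistics are converged between the two (< 0.05 Hz
  in the modal peaks).
- Monte Carlo defaults for the test suite: 10,000 spins with the step time
  coarsened ~20x from the 4-pixel rule; the step-halving check changes the
  55-ms magnitude by < 1%.

## Knife-edge observables and known limitations

The circular packed model's signal at TE = 55 ms sits at the interference
null between the intra-axonal cluster (-9.6 Hz) and the extra-axonal cluster
(0 Hz): the magnitude nearly vanishes and the unwrapped phase slews by ~2 pi
across the null. Whether the trajectory winds (|phase| ~ 4 rad) or stays
bounded (|phase| <= ~1.6 rad) depends on whether the coherent intra
amplitude exceeds the extra one *at the null*, which is set by the
extra-axonal frequency dispersion — a property of the packing's spatial
correlations, not of any stated parameter. With this package's homogeneous
relaxed packing the intra/extra amplitude ratio is ~1.4 and the phase winds;
orderly (lattice-like) arrangements move the system toward the bounded
branch. The 55-ms phase of the circular model should therefore be treated as
structurally unstable, unlike the frequency-domain observables (peak
positions, histogram shapes) and the magnitude curves, which are robust.

Likewise, with purely isotropic myelin susceptibility the positive
frequencies live in the myelin water, which decays with T2 = 15 ms, so the
late phase follows the aqueous pool and ends slightly negative even though
the total-distribution mean is positive.

Other limitations: no inter-compartment exchange; no nonlocal
white-/gray-matter interface fields beyond a uniform frequency-offset hook;
no RF/TR/flip-angle effects (fully relaxed magnitude scaling); diffusion is
unencoded free precession (no gradient pulses).
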