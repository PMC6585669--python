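# myelinsim

Simulation of the susceptibility-weighted multi-echo gradient-echo (GRE) MR
signal from two-dimensional white-matter microstructure.

Myelinated axons perturb the local magnetic field: the myelin sheath carries
an isotropic susceptibility offset relative to the surrounding water and, because
its phospholipid bilayers are stacked radially, an *anisotropic* component as
well. The resulting microscopic off-resonance field imprints itself on the
magnitude decay (T2\*) and phase of the GRE signal — which is why GRE phase is
used to probe myelination — but it depends not only on how much myelin is
present (g-ratio, fiber density) but also on the *shape* of the axon
cross-sections. `myelinsim` lets you build axon geometries of increasing
realism, compute the field they induce, and predict the signal under static or
diffusing magnetization, so that shape, demyelination and susceptibility
effects can be separated. It is aimed at researchers modelling
susceptibility-based myelin contrast (quantitative susceptibility, myelin
water, g-ratio mapping).

## Model

A geometry is a 3-valued label map (intra-axonal / extra-axonal / myelin) on a
square grid of physical pixels. Per myelin pixel, the susceptibility tensor in
the local bilayer frame is

```
chi_local = chi_i * I + chi_a * diag(1, -1/2, -1/2)        [ppb]
```

with the distinct axis along the bilayer normal (the radial direction of the
sheath), rotated about the fiber axis by the local azimuth phi. The aqueous
compartments are the zero reference. The off-resonance frequency map follows
from the k-space dipole expression, evaluated on the k_z = 0 plane (axons
uniform along z),

```
df(r) = FT^-1 { 1/3 H^T X(k) H  -  (H.k) (k^T X(k) H) / k^2 } * gamma_bar * B0
```

where `X(k)` is the Fourier transform of the tensor map, `H = [sin(theta), 0,
cos(theta)]` the unit field direction, and the result is referenced so the
extra-axonal mode sits at 0 Hz. For a circular axon this reproduces the
hollow-cylinder closed form `df_intra = (3/4) chi_a sin^2(theta) ln(1/g) *
gamma_bar * B0`. The complex signal is the three-compartment phasor sum

```
S(t) = sum_n rho_n exp(-t/T2_n) sum_{pixels in n} exp(i 2 pi df t)
```

optionally replaced by a Monte Carlo random walk in which each spin accrues
phase along its diffusion path (D = 2 um^2/ms outside myelin, myelin
impermeable and immobile).

Geometry generators cover: nested ellipses (eccentricity/rotation studies),
random close packings of 1434 gamma-distributed circular fibers (shape 5.7,
mean radius 0.46 um, g = 0.7, 36% extra-axonal space), an area-preserving
swirl warp (non-circular packings with identical g and density), irregular
synthetic axons with harmonic boundary roughness and micrograph-like g-ratio
scatter, inside-out myelin erosion (demyelination sweeps g = 0.70...0.98),
and import of segmented label images.

## Worked example

```python
from myelinsim import (CompartmentProperties, EchoGrid, FieldConfig, GridSpec,
                       analytic_hollow_cylinder, build_tensor_map, circular_mask,
                       compartment_histograms, forward_field,
                       make_single_ellipse_axon, orientation_map,
                       reference_to_extra, static_signal)
from myelinsim.geometry import EllipseSpec, INTRA

# one myelinated axon, g = 0.7, on a 512-px / 6-um grid
lmap = make_single_ellipse_axon(EllipseSpec(eccentricity=0.0), g=0.7,
                                grid=GridSpec(512, 6.0))
orient = orientation_map(lmap, mode="continuous")
props = CompartmentProperties.literature()   # T2 50/50/15 ms, rho 1/1/0.5, chi -60/-120 ppb
cfg = FieldConfig(b0=7.0)                # fiber perpendicular to a 7 T field
field = forward_field(build_tensor_map(lmap, orient, props), cfg)
field = reference_to_extra(field, lmap)

print(f"analytic intra shift : {analytic_hollow_cylinder(0.7, props, cfg):.2f} Hz")
print(f"simulated intra mean : {field.delta_f[lmap.labels == INTRA].mean():.2f} Hz")

mask = circular_mask(lmap.grid, area_fraction=0.5)
hist = compartment_histograms(field, lmap, mask)
print(f"modal peaks (Hz)     : {hist.peaks}")

signal = static_signal(field, lmap, props, EchoGrid.static_preset(), mask)
mag, phase = signal.at(55.0)
print(f"GRE signal at 55 ms  : |S| = {mag:.3f}, phase = {phase:+.3f} rad")
```

prints

```
analytic intra shift : -9.57 Hz
simulated intra mean : -9.51 Hz
modal peaks (Hz)     : {'intra': -9.5, 'extra': 4.5, 'myelin': 26.0, 'total': -9.5}
GRE signal at 55 ms  : |S| = 0.033, phase = -3.652 rad
```

The intra-axonal water precesses 9.5 Hz slow — the spectral solver agrees with
the hollow-cylinder closed form to better than 1% — while the myelin water is
shifted up by ~26 Hz. (The extra-axonal *mode inside this small sampling
mask* sits on the positive dipole lobe of the single axon; in packed models it
sits at 0 Hz.) By 55 ms the coherent intra pool has dephased against the rest,
leaving 3% of the initial magnitude and a large accrued phase.

Packed-model experiments run from the CLI:

```
myelinsim experiment compare --out results/compare      # circular vs warped vs irregular
myelinsim experiment sweep   --out results/sweep        # nine-stage demyelination
myelinsim experiment variant --name alt_chi --out results/alt
```

Each writes per-run signal/histogram CSVs, a summary table and a manifest
sufficient to re-run the deterministic stages bit-identically.

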