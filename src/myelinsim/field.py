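"""Susceptibility tensor maps and the Fourier off-resonance field solver.

The myelin sheath is modeled as radially stacked phospholipid bilayers: in
the local bilayer frame the susceptibility tensor is the isotropic offset
plus a traceless anisotropic part with its long axis along the bilayer
normal (the radial direction of the sheath),

    chi_local = chi_i * I + chi_a * diag(1, -1/2, -1/2)   (ppb).

This normalization of ``chi_a`` is what reproduces the hollow-cylinder
intra-axonal shift (3/4) chi_a ln(1/g) sin^2(theta).  A rotation about z by
the local azimuth ``phi`` transforms each pixel's tensor into the common
frame of the axon.  The intra- and extra-axonal spaces are the
zero-susceptibility reference.

The off-resonance frequency follows from the k-space dipole expression

    df = IFT{ (1/3) H^T X(k) H  -  (H.k) (k^T X(k) H) / k^2 } * f0 * 1e-9

evaluated on the k_z = 0 plane (axons are uniform along z), with the DC bin
set to zero so the computed field has zero spatial mean and the extra-axonal
reference sits at ~0 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .geometry import EXTRA, INTRA, MYELIN, LabelMap, OrientationMap
from .grids import GridSpec, SampleMask

__all__ = [
    "GAMMA_BAR_MHZ_PER_T",
    "CompartmentProperties",
    "FieldConfig",
    "TensorField",
    "FieldMap",
    "FrequencyHistogram",
    "build_tensor_map",
    "forward_field",
    "analytic_hollow_cylinder",
    "direct_convolution_oracle",
    "reference_to_extra",
    "compartment_histograms",
]

#: gyromagnetic ratio of the proton divided by 2 pi, MHz/T
GAMMA_BAR_MHZ_PER_T = 42.58

_COMPARTMENTS = ("intra", "extra", "myelin")
_LABEL_OF = {"extra": EXTRA, "intra": INTRA, "myelin": MYELIN}


@dataclass(frozen=True)
class CompartmentProperties:
    """Relaxation, proton density and susceptibility per compartment.

    T2 in ms, proton density dimensionless, susceptibilities in ppb.  The
    aqueous compartments are the susceptibility reference (chi = 0); only
    myelin carries isotropic (``chi_i``) and anisotropic (``chi_a``)
    components.
    """

    t2: dict = dc_field(default_factory=lambda: {"intra": 50.0, "extra": 50.0, "myelin": 15.0})
    rho: dict = dc_field(default_factory=lambda: {"intra": 1.0, "extra": 1.0, "myelin": 0.5})
    chi_i: float = -60.0
    chi_a: float = -120.0

    def __post_init__(self) -> None:
        for name in _COMPARTMENTS:
            if self.t2[name] <= 0:
                raise ValueError("T2 must be positive")
            if self.rho[name] < 0:
                raise ValueError("proton density must be non-negative")

    @classmethod
    def literature(cls) -> "CompartmentProperties":
        """Literature values: T2 50/50/15 ms, rho 1/1/0.5, chi -60/-120 ppb."""
        return cls()

    @classmethod
    def isotropic_only(cls) -> "CompartmentProperties":
        """Purely isotropic myelin susceptibility (chi_a = 0, chi_i = -100 ppb)."""
        return cls(chi_i=-100.0, chi_a=0.0)

    @classmethod
    def alt_chi(cls) -> "CompartmentProperties":
        """Reduced anisotropy variant (chi_a = -70 ppb, chi_i = -60 ppb)."""
        return cls(chi_a=-70.0)

    def with_chi(self, chi_i: float, chi_a: float) -> "CompartmentProperties":
        return replace(self, chi_i=chi_i, chi_a=chi_a)


@dataclass(frozen=True)
class FieldConfig:
    """Main field strength and fiber-to-field geometry.

    ``theta`` is the elevation of the fiber axis to B0; the unit field
    direction in the axon frame is ``[sin(theta), 0, cos(theta)]``.
    """

    b0: float = 7.0  # Tesla
    theta: float = math.pi / 2
    gamma_bar: float = GAMMA_BAR_MHZ_PER_T  # MHz/T

    @property
    def h_hat(self) -> np.ndarray:
        return np.array([math.sin(self.theta), 0.0, math.cos(self.theta)])

    @property
    def f0_hz(self) -> float:
        """Larmor frequency gamma_bar * B0 in Hz."""
        return self.gamma_bar * 1e6 * self.b0


_COMPONENT_KEYS = ("xx", "yy", "zz", "xy", "xz", "yz")
_IJ = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
       "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class TensorField:
    """Per-pixel symmetric susceptibility tensor (ppb), sparse by component.

    Only the stored components are nonzero; a fully absent component dict
    represents the zero tensor field.
    """

    grid: GridSpec
    components: dict

    def __post_init__(self) -> None:
        for key, arr in self.components.items():
            if key not in _COMPONENT_KEYS:
                raise ValueError(f"unknown tensor component {key!r}")
            if arr.shape != self.grid.shape:
                raise ValueError("tensor component shape does not match grid")

    def component(self, key: str) -> np.ndarray:
        if key in self.components:
            return self.components[key]
        return np.zeros(self.grid.shape)

    def full_tensor(self) -> np.ndarray:
        """Dense (ny, nx, 3, 3) tensor array; intended for small grids."""
        out = np.zeros(self.grid.shape + (3, 3))
        for key, arr in self.components.items():
            i, j = _IJ[key]
            out[..., i, j] = arr
            out[..., j, i] = arr
        return out

    def trace(self) -> np.ndarray:
        return self.component("xx") + self.component("yy") + self.component("zz")


@dataclass(frozen=True)
class FieldMap:
    """Off-resonance frequency map, Hz."""

    grid: GridSpec
    delta_f: np.ndarray

    def __post_init__(self) -> None:
        if self.delta_f.shape != self.grid.shape:
            raise ValueError("field map shape does not match grid")
        if not np.isfinite(self.delta_f).all():
            raise ValueError("field map contains non-finite values")

    def shifted(self, offset_hz: float) -> "FieldMap":
        """Uniform frequency offset, e.g. a nonlocal white/gray-matter shift."""
        if not np.isfinite(offset_hz):
            raise ValueError("offset must be finite")
        return FieldMap(self.grid, self.delta_f + offset_hz)


# ---------------------------------------------------------------------------
# tensor construction
# ---------------------------------------------------------------------------


def build_tensor_map(
    lmap: LabelMap,
    orient: OrientationMap,
    props: CompartmentProperties,
) -> TensorField:
    """Rotate the local bilayer tensor into the axon frame, per myelin pixel.

    With local tensor ``chi_i I + chi_a diag(1, -1/2, -1/2)`` (long axis
    radial) and rotation by ``phi`` about z, the in-plane components become

        xx = chi_i - chi_a/2 + (3/2) chi_a cos^2(phi)
        yy = chi_i - chi_a/2 + (3/2) chi_a sin^2(phi)
        zz = chi_i - chi_a/2
        xy = (3/2) chi_a sin(phi) cos(phi)

    The trace, 3 chi_i, is invariant under the rotation.
    """
    my = lmap.compartment_mask(MYELIN)
    phi = orient.phi
    if np.isnan(phi[my]).any():
        raise ValueError("orientation map undefined on some myelin pixels")
    c = np.where(my, np.cos(np.nan_to_num(phi)), 0.0)
    s = np.where(my, np.sin(np.nan_to_num(phi)), 0.0)
    mask = my.astype(float)
    chi_perp = props.chi_i - 0.5 * props.chi_a  # transverse local eigenvalue
    d = 1.5 * props.chi_a  # long-minus-transverse eigenvalue difference
    components = {
        "xx": mask * chi_perp + d * c**2,
        "yy": mask * chi_perp + d * s**2,
        "zz": mask * chi_perp,
        "xy": d * s * c,
    }
    if props.chi_a == 0.0:
        components.pop("xy")
    return TensorField(lmap.grid, components)


# ---------------------------------------------------------------------------
# spectral field solver
# ---------------------------------------------------------------------------


def _pair_coefficient(key, H, KX, KY, q):
    """k-space weight multiplying the transform of tensor component ``key``.

    Symmetric off-diagonal components are counted for both index orders.
    """
    kvec = {"x": KX, "y": KY, "z": 0.0}
    i, j = key
    Hi, Hj = H["xyz".index(i)], H["xyz".index(j)]
    if i == j:
        return (Hi * Hj) / 3.0 - q * kvec[i] * Hj
    return 2.0 * (Hi * Hj) / 3.0 - q * (kvec[i] * Hj + kvec[j] * Hi)


def forward_field(chi: TensorField, cfg: FieldConfig) -> FieldMap:
    """Off-resonance frequency map from the k-space tensor dipole expression.

    Each stored tensor component is Fourier transformed, combined with its
    k-dependent coefficient on the k_z = 0 plane, inverse transformed, and
    scaled from ppb to Hz by ``1e-9 * f0``.  The DC bin is zeroed, making the
    returned field zero-mean over the grid.
    """
    grid = chi.grid
    for arr in chi.components.values():
        if not np.isfinite(arr).all():
            raise ValueError("tensor field contains non-finite values")
    ny, nx = grid.shape
    d = grid.pixel_size
    # full transforms on both axes: the discrete operator is then identical
    # to the naive-DFT evaluation (the dipole coefficient is odd in k at the
    # Nyquist column, which a half-spectrum rfft cannot represent)
    KY = np.fft.fftfreq(ny, d=d)[:, None]
    KX = np.fft.fftfreq(nx, d=d)[None, :]
    k2 = KX**2 + KY**2
    H = cfg.h_hat
    hk = H[0] * KX + H[1] * KY  # H . k with k_z = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(k2 > 0, hk / k2, 0.0)
    bracket = np.zeros((ny, nx), dtype=complex)
    for key, arr in chi.components.items():
        if not arr.any():
            continue
        coeff = _pair_coefficient(key, H, KX, KY, q)
        if np.isscalar(coeff) and coeff == 0.0:
            continue
        bracket += coeff * np.fft.fft2(arr)
    bracket[0, 0] = 0.0
    delta_ppb = np.fft.ifft2(bracket).real
    return FieldMap(grid, delta_ppb * 1e-9 * cfg.f0_hz)


def reference_to_extra(
    fmap: FieldMap,
    lmap: LabelMap,
    mask: SampleMask | None = None,
    bin_width: float = 0.1,
) -> FieldMap:
    """Shift the field so the extra-axonal modal frequency sits at 0 Hz.

    The spectral solver returns the field in a zero-spatial-mean gauge (DC
    bin zeroed); physically the aqueous compartments are the susceptibility
    reference, so measured frequencies are quoted relative to the
    extra-axonal water.  The shift is the modal extra-axonal frequency on a
    fine (0.1 Hz) grid.
    """
    sel = mask.mask if mask is not None else np.ones(lmap.grid.shape, dtype=bool)
    vals = fmap.delta_f[sel & (lmap.labels == EXTRA)]
    if vals.size == 0:
        return fmap
    q = np.round(vals / bin_width).astype(np.int64)
    uniq, counts = np.unique(q, return_counts=True)
    mode = uniq[np.argmax(counts)] * bin_width
    return fmap.shifted(-mode)


def analytic_hollow_cylinder(
    g: float,
    props: CompartmentProperties,
    cfg: FieldConfig,
) -> float:
    """Closed-form intra-axonal frequency of the hollow cylinder model, Hz.

    For an infinite annular sheath with radial susceptibility anisotropy the
    field inside the axon is uniform:

        df_intra = (3/4) * chi_a * sin^2(theta) * ln(1/g) * f0 * 1e-9

    The isotropic component contributes nothing inside the cylinder.  Serves
    as the physics oracle for :func:`forward_field`.
    """
    if not 0 < g < 1:
        raise ValueError("g must lie in (0, 1)")
    return 0.75 * props.chi_a * math.sin(cfg.theta) ** 2 * math.log(1.0 / g) \
        * cfg.f0_hz * 1e-9


def direct_convolution_oracle(chi: TensorField, cfg: FieldConfig) -> FieldMap:
    """Brute-force evaluation of the same linear operator by naive DFT.

    Uses explicit DFT matrices and dense 3x3 tensor algebra per k-bin, with
    no fast transforms and no shared code with :func:`forward_field`; cost is
    O(N^3)-ish, so grids are limited to 128 pixels per side.
    """
    grid = chi.grid
    ny, nx = grid.shape
    if max(ny, nx) > 128:
        raise ValueError("direct oracle limited to grids <= 128 pixels per side")
    X = chi.full_tensor()
    jy = np.arange(ny)
    jx = np.arange(nx)
    Wy = np.exp(-2j * np.pi * np.outer(jy, jy) / ny)
    Wx = np.exp(-2j * np.pi * np.outer(jx, jx) / nx)
    Xhat = np.einsum("pm,mnab,nq->pqab", Wy, X.astype(complex), Wx)
    d = grid.pixel_size
    ky = np.fft.fftfreq(ny, d=d)
    kx = np.fft.fftfreq(nx, d=d)
    kvec = np.zeros((ny, nx, 3))
    kvec[..., 0] = kx[None, :]
    kvec[..., 1] = ky[:, None]
    H = cfg.h_hat
    HXH = np.einsum("a,pqab,b->pq", H, Xhat, H)
    kXH = np.einsum("pqa,pqab,b->pq", kvec, Xhat, H)
    k2 = np.einsum("pqa,pqa->pq", kvec, kvec)
    hk = np.einsum("pqa,a->pq", kvec, H)
    with np.errstate(divide="ignore", invalid="ignore"):
        dip = np.where(k2 > 0, hk / np.where(k2 > 0, k2, 1.0), 0.0)
    bracket = HXH / 3.0 - dip * kXH
    bracket[0, 0] = 0.0
    out = np.einsum("pm,mn,nq->pq", Wy.conj(), bracket, Wx.conj()) / (ny * nx)
    return FieldMap(grid, out.real * 1e-9 * cfg.f0_hz)


# ---------------------------------------------------------------------------
# frequency histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyHistogram:
    """Per-compartment frequency histograms over a sampling mask.

    ``peaks`` maps compartment name (or "total") to the centre of its
    highest-count bin, Hz; absent compartments map to None.
    """

    bin_edges: np.ndarray
    counts: dict
    peaks: dict
    means: dict

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compartment_histograms(
    fmap: FieldMap,
    lmap: LabelMap,
    mask: SampleMask | None = None,
    bin_width: float = 0.5,
) -> FrequencyHistogram:
    """Histogram the field per compartment within the sampling mask.

    Bin edges are aligned so that 0 Hz is a bin centre; the modal peak of a
    compartment is the centre of its highest-count bin.
    """
    if mask is not None and mask.grid.shape != lmap.grid.shape:
        raise ValueError("mask grid does not match label map")
    sel = mask.mask if mask is not None else np.ones(lmap.grid.shape, dtype=bool)
    if not sel.any():
        raise ValueError("empty sampling mask")
    f = fmap.delta_f[sel]
    lab = lmap.labels[sel]
    lo = math.floor(f.min() / bin_width - 0.5)
    hi = math.ceil(f.max() / bin_width + 0.5)
    edges = (np.arange(lo, hi + 1) + 0.5) * bin_width
    counts, peaks, means = {}, {}, {}
    total = np.zeros(len(edges) - 1, dtype=np.int64)
    for name in _COMPARTMENTS:
        vals = f[lab == _LABEL_OF[name]]
        c, _ = np.histogram(vals, bins=edges)
        counts[name] = c
        total += c
        if vals.size:
            centers = 0.5 * (edges[:-1] + edges[1:])
            peaks[name] = float(centers[int(np.argmax(c))])
            means[name] = float(vals.mean())
        else:
            peaks[name] = None
            means[name] = None
    counts["total"] = total
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks["total"] = float(centers[int(np.argmax(total))])
    means["total"] = float(f.mean())
    return FrequencyHistogram(edges, counts, peaks, means)
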