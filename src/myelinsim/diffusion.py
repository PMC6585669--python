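"""Monte Carlo spin diffusion through the simulated field map.

Spins random-walk in 2D (axons are uniform along z) with Gaussian steps of
per-axis standard deviation sqrt(2 D dt).  Myelin is impermeable and its
water immobile: spins seeded in myelin accrue phase at a fixed location, and
mobile spins whose step lands in myelin stay put for that step (``reject``
rule; ``reflect`` retries the step with a fresh draw).  Spins leaving the
grid wrap periodically, consistent with the Fourier field's periodicity.
Each spin accumulates phase s * 2 pi * df(position) * dt per step, and the
diffusion-weighted signal is the T2- and proton-density-weighted phasor sum
of the ensemble at the echo times.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import FieldMap, CompartmentProperties, _COMPARTMENTS, _LABEL_OF
from .geometry import MYELIN, LabelMap
from .grids import EchoGrid, SampleMask
from .signal import SignalSeries, unwrap_phase_series

__all__ = ["DiffusionConfig", "SpinEnsemble", "init_spins", "step_ensemble",
           "run_diffusion", "diffusion_signal", "simulate_diffusion_signal"]


@dataclass(frozen=True)
class DiffusionConfig:
    """Monte Carlo random-walk parameters.

    ``d_free`` is the free diffusivity of the aqueous compartments in
    um^2/ms (2.0 matches measurements along axons); myelin water does not
    diffuse.  When ``step_time`` is omitted it is set so the rms step spans
    about 4 pixels of the geometry: dt = (4 px)^2 / (4 D).
    """

    n_spins: int = 10_000
    d_free: float = 2.0  # um^2 / ms
    d_myelin: float = 0.0
    step_time: float | None = None  # ms
    n_steps: int | None = None
    duration: float = 55.0  # ms
    seed: int = 0
    boundary_rule: str = "reject"

    def __post_init__(self) -> None:
        if self.d_free <= 0:
            raise ValueError("d_free must be positive")
        if self.n_spins <= 0:
            raise ValueError("n_spins must be positive")
        if self.boundary_rule not in ("reject", "reflect"):
            raise ValueError("boundary_rule must be 'reject' or 'reflect'")

    def resolve_steps(self, pixel_size: float) -> tuple[float, int]:
        """(step_time ms, n_steps) honouring explicit values when given."""
        dt = self.step_time
        if dt is None:
            dt = (4.0 * pixel_size) ** 2 / (4.0 * self.d_free)
        n = self.n_steps
        if n is None:
            n = int(np.ceil(self.duration / dt))
        return dt, n


@dataclass
class SpinEnsemble:
    """Positions (um), accrued phases (rad) and static weights of the spins."""

    positions: np.ndarray  # (n, 2) wrapped positions, um
    raw_positions: np.ndarray  # (n, 2) unwrapped, for displacement statistics
    phase: np.ndarray  # (n,) rad
    home_compartment: np.ndarray  # (n,) label at initialization
    weight: np.ndarray  # (n,) proton density of home compartment
    mobile: np.ndarray  # (n,) bool
    time: float = 0.0  # ms


def init_spins(
    lmap: LabelMap,
    mask: SampleMask | None,
    cfg: DiffusionConfig,
    props: CompartmentProperties | None = None,
    rng: np.random.Generator | None = None,
) -> SpinEnsemble:
    """Seed spins uniformly at random over the masked pixels of all compartments.

    Each spin carries the proton density of its home compartment as a static
    weight; myelin-seeded spins are immobile.
    """
    if props is None:
        props = CompartmentProperties.literature()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sel = mask.mask if mask is not None else np.ones(lmap.grid.shape, dtype=bool)
    iy, ix = np.nonzero(sel)
    if iy.size == 0:
        raise ValueError("empty sampling mask")
    pick = rng.integers(0, iy.size, size=cfg.n_spins)
    px = lmap.grid.pixel_size
    pos = np.column_stack(
        [
            (ix[pick] + rng.random(cfg.n_spins)) * px,
            (iy[pick] + rng.random(cfg.n_spins)) * px,
        ]
    )
    home = lmap.labels[iy[pick], ix[pick]]
    rho_of_label = np.zeros(3)
    for name in _COMPARTMENTS:
        rho_of_label[_LABEL_OF[name]] = props.rho[name]
    mobile = home != MYELIN if cfg.d_myelin == 0.0 else np.ones(cfg.n_spins, bool)
    return SpinEnsemble(
        positions=pos,
        raw_positions=pos.copy(),
        phase=np.zeros(cfg.n_spins),
        home_compartment=home,
        weight=rho_of_label[home],
        mobile=mobile,
    )


def _lookup(lmap_labels, grid, pos):
    px = grid.pixel_size
    ix = np.floor(pos[:, 0] / px).astype(np.intp) % grid.n
    iy = np.floor(pos[:, 1] / px).astype(np.intp) % grid.ny
    return iy, ix


def step_ensemble(
    spins: SpinEnsemble,
    lmap: LabelMap,
    field: FieldMap,
    cfg: DiffusionConfig,
    dt: float,
    rng: np.random.Generator,
    sign_convention: int = +1,
) -> SpinEnsemble:
    """Advance every spin by one time step ``dt`` (ms), in place.

    Mobile spins take an isotropic Gaussian displacement (sigma =
    sqrt(2 D dt) per axis); steps landing in myelin are handled by the
    boundary rule.  After moving, each spin accrues phase from the field at
    its (pixel) position; immobile spins accrue phase where they sit.
    """
    grid = lmap.grid
    n = spins.phase.size
    sigma = np.sqrt(2.0 * cfg.d_free * dt)
    step = rng.normal(0.0, sigma, size=(n, 2))
    step[~spins.mobile] = 0.0
    trial = spins.positions + step
    Lx, Ly = grid.extent, grid.extent_y
    wrapped = np.column_stack([trial[:, 0] % Lx, trial[:, 1] % Ly])
    iy, ix = _lookup(lmap.labels, grid, wrapped)
    blocked = (lmap.labels[iy, ix] == MYELIN) & spins.mobile
    if cfg.boundary_rule == "reflect" and blocked.any():
        # one fresh re-draw for blocked spins; still-blocked ones stay put
        redo = np.flatnonzero(blocked)
        step2 = rng.normal(0.0, sigma, size=(redo.size, 2))
        trial2 = spins.positions[redo] + step2
        wrapped2 = np.column_stack([trial2[:, 0] % Lx, trial2[:, 1] % Ly])
        iy2, ix2 = _lookup(lmap.labels, grid, wrapped2)
        ok = lmap.labels[iy2, ix2] != MYELIN
        keep = redo[ok]
        trial[keep] = trial2[ok]
        wrapped[keep] = wrapped2[ok]
        blocked[keep] = False
    move = spins.mobile & ~blocked
    spins.raw_positions[move] += trial[move] - spins.positions[move]
    spins.positions[move] = wrapped[move]
    iy, ix = _lookup(lmap.labels, grid, spins.positions)
    spins.phase += (sign_convention * 2.0 * np.pi * 1e-3 * dt) * field.delta_f[iy, ix]
    spins.time += dt
    return spins


def run_diffusion(
    lmap: LabelMap,
    field: FieldMap,
    cfg: DiffusionConfig,
    props: CompartmentProperties | None = None,
    mask: SampleMask | None = None,
    echoes: EchoGrid | None = None,
    sign_convention: int = +1,
) -> tuple[SpinEnsemble, np.ndarray, np.ndarray]:
    """Run the walk and snapshot per-spin phases at the echo times.

    Returns ``(ensemble, echo_times_ms, phases)`` with ``phases`` of shape
    (n_echoes, n_spins); phases falling between steps are linearly
    interpolated in time.
    """
    if props is None:
        props = CompartmentProperties.literature()
    if echoes is None:
        echoes = EchoGrid.static_preset()
    dt, n_steps = cfg.resolve_steps(lmap.grid.pixel_size)
    if echoes.t_max > n_steps * dt + 1e-9:
        raise ValueError(
            f"echo at {echoes.t_max} ms beyond simulated duration {n_steps * dt:.3g} ms"
        )
    rng = np.random.default_rng(cfg.seed)
    spins = init_spins(lmap, mask, cfg, props, rng)
    snapshots = np.empty((echoes.times.size, cfg.n_spins))
    e = 0
    while e < echoes.times.size and echoes.times[e] <= 1e-12:
        snapshots[e] = 0.0
        e += 1
    for k in range(n_steps):
        prev_phase = spins.phase.copy()
        t_prev = spins.time
        step_ensemble(spins, lmap, field, cfg, dt, rng, sign_convention)
        while e < echoes.times.size and echoes.times[e] <= spins.time + 1e-12:
            frac = (echoes.times[e] - t_prev) / dt
            snapshots[e] = prev_phase + frac * (spins.phase - prev_phase)
            e += 1
        if e == echoes.times.size:
            break
    return spins, echoes.times, snapshots


def diffusion_signal(
    spins: SpinEnsemble,
    phases: np.ndarray,
    times_ms: np.ndarray,
    props: CompartmentProperties | None = None,
) -> SignalSeries:
    """Weighted phasor sum of the ensemble at each echo time.

    S(t) = sum_spins rho_home exp(-t / T2_home) exp(i phase(t)), normalized
    to its t = 0 value, exactly mirroring the static pixel sum.
    """
    if props is None:
        props = CompartmentProperties.literature()
    t2_of_label = np.ones(3)
    for name in _COMPARTMENTS:
        t2_of_label[_LABEL_OF[name]] = props.t2[name]
    t2 = t2_of_label[spins.home_compartment]
    envelope = np.exp(-times_ms[:, None] / t2[None, :])
    s = ((spins.weight[None, :] * envelope) * np.exp(1j * phases)).sum(axis=1)
    s0 = float(spins.weight.sum())
    return SignalSeries(
        times=times_ms,
        complex_signal=s,
        magnitude=np.abs(s) / s0,
        phase_unwrapped=unwrap_phase_series(s),
    )


def simulate_diffusion_signal(
    lmap: LabelMap,
    field: FieldMap,
    cfg: DiffusionConfig,
    props: CompartmentProperties | None = None,
    mask: SampleMask | None = None,
    echoes: EchoGrid | None = None,
    sign_convention: int = +1,
) -> SignalSeries:
    """Convenience driver: walk the spins, then sum the ensemble signal."""
    if props is None:
        props = CompartmentProperties.literature()
    spins, times, phases = run_diffusion(
        lmap, field, cfg, props, mask, echoes, sign_convention
    )
    return diffusion_signal(spins, phases, times, props)
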