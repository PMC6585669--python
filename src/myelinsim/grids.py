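"""Raster grids, sampling masks and echo-time grids.

Conventions used throughout the package:

* arrays are indexed ``[iy, ix]``; the physical origin is the lower-left
  corner of the raster;
* the centre of pixel ``(iy, ix)`` sits at ``((ix + 0.5) * pixel_size,
  (iy + 0.5) * pixel_size)`` in micrometres;
* azimuths are measured counterclockwise from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "SampleMask", "EchoGrid", "circular_mask"]


@dataclass(frozen=True)
class GridSpec:
    """Square (optionally rectangular) raster with a physical pixel size.

    Parameters
    ----------
    n : int
        Number of pixels along x (columns).
    extent : float
        Physical side length along x, in micrometres.
    ny : int, optional
        Number of rows; defaults to ``n`` (square grid).  Rectangular
        grids arise only from loaded label images.
    """

    n: int
    extent: float
    ny: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("grid size must be positive")
        if self.extent <= 0:
            raise ValueError("grid extent must be positive")
        if self.ny is None:
            object.__setattr__(self, "ny", self.n)

    @property
    def pixel_size(self) -> float:
        """Pixel edge length in micrometres."""
        return self.extent / self.n

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.n)

    @property
    def extent_y(self) -> float:
        return self.ny * self.pixel_size

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent / 2.0, self.extent_y / 2.0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1D arrays of pixel-centre coordinates (x along columns, y along rows)."""
        px = self.pixel_size
        x = (np.arange(self.n) + 0.5) * px
        y = (np.arange(self.ny) + 0.5) * px
        return x, y

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """2D pixel-centre coordinate arrays ``(X, Y)`` of shape ``(ny, n)``."""
        x, y = self.pixel_centers()
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class SampleMask:
    """Boolean raster restricting which pixels contribute to the signal.

    The default construction (:func:`circular_mask`) is a centred disk
    covering half the grid area, which keeps the Fourier solver's
    periodic-edge artefacts out of the sampled region.
    """

    grid: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def circular_mask(grid: GridSpec, area_fraction: float = 0.5) -> SampleMask:
    """Centred circular sampling mask covering ``area_fraction`` of the grid."""
    if not 0 < area_fraction <= 1:
        raise ValueError("area_fraction must lie in (0, 1]")
    radius = grid.extent * np.sqrt(area_fraction / np.pi)
    X, Y = grid.meshgrid()
    cx, cy = grid.center
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
    return SampleMask(grid, mask)


@dataclass(frozen=True)
class EchoGrid:
    """Strictly increasing echo-time grid in milliseconds."""

    times: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 55.0, 100))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("echo times must be a non-empty 1D array")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def static_preset(cls, t_max: float = 55.0, n: int = 100) -> "EchoGrid":
        """Free-induction sampling: ``n`` points from 0 to ``t_max`` ms."""
        return cls(np.linspace(0.0, t_max, n))

    @classmethod
    def cuprizone_preset(cls) -> "EchoGrid":
        """Multi-echo GRE readout: TE = 3..55 ms at 4 ms spacing."""
        return cls(np.arange(3.0, 55.0 + 1e-9, 4.0))

    @property
    def t_max(self) -> float:
        return float(self.times[-1])
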