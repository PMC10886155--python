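"""Scalar map containers used throughout the pipeline.

Two grid families appear in the pipeline:

* ``PolarMap`` — maps sampled on the topographer's native polar grid
  (azimuth x radial station), used for curvature/power/RPC work.
* ``GridMap`` — maps resampled onto the common Cartesian analysis grid
  (x, y in mm), used for field comparison (NCC / SSIM).

Both carry a boolean validity mask; invalid cells hold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PolarMap", "GridMap", "common_grid"]


@dataclass
class PolarMap:
    """Scalar values on a polar (azimuth, radial-station) grid.

    azimuths_deg : (n_az,) degrees, increasing in [0, 360)
    radii_mm     : (n_r,) mm, strictly increasing radial stations
    values       : (n_az, n_r) float; NaN where invalid
    mask         : (n_az, n_r) bool validity
    units        : free-text unit label (e.g. "D", "mm")
    """

    azimuths_deg: np.ndarray
    radii_mm: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.azimuths_deg.size, self.radii_mm.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.azimuths_deg.size}, {self.radii_mm.size})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    def copy(self) -> "PolarMap":
        return PolarMap(
            self.azimuths_deg.copy(),
            self.radii_mm.copy(),
            self.values.copy(),
            self.mask.copy(),
            self.units,
        )

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian (x, y) mm coordinates of every grid sample."""
        th = np.deg2rad(self.azimuths_deg)[:, None]
        r = self.radii_mm[None, :]
        return r * np.cos(th), r * np.sin(th)


@dataclass
class GridMap:
    """Scalar values on a uniform Cartesian grid (values indexed [iy, ix])."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.y_mm.size, self.x_mm.size):
            raise ValueError("values shape does not match (len(y), len(x))")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    def copy(self) -> "GridMap":
        return GridMap(
            self.x_mm.copy(), self.y_mm.copy(), self.values.copy(),
            self.mask.copy(), self.units,
        )

    @property
    def step(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_mm, self.y_mm)

    def to_csv(self, path) -> None:
        """Write a self-describing CSV grid (origin, step, units header)."""
        with open(path, "w") as fh:
            fh.write(f"# x0_mm,{self.x_mm[0]}\n# y0_mm,{self.y_mm[0]}\n")
            fh.write(f"# step_mm,{self.step}\n# units,{self.units}\n")
            out = np.where(self.mask, self.values, np.nan)
            for row in out:
                fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def common_grid(extent_mm: float = 8.0, step_mm: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """The common analysis grid: x, y spanning -extent..extent inclusive.

    Defaults give the standard 161 x 161 grid from -8 to 8 mm in 0.1 mm
    steps used for all map comparisons.
    """
    n = int(round(2 * extent_mm / step_mm)) + 1
    ax = np.linspace(-extent_mm, extent_mm, n)
    return ax, ax.copy()
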