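"""Wavenumber grids for FT-NIR diffuse-reflectance spectra.

Spectra are recorded on a uniform, descending wavenumber axis.  The
instrument emulated here scans 10,000 -> 3800 cm^-1 at 2 cm^-1
resolution, i.e. 3101 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform descending wavenumber axis.

    Parameters
    ----------
    start : float
        First (largest) wavenumber in cm^-1.
    end : float
        Last (smallest) wavenumber in cm^-1; must be < `start`.
    step : float
        Grid spacing in cm^-1; must divide ``start - end``.
    """

    start: float
    end: float
    step: float
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.end >= self.start:
            raise ValueError("grid must be descending: require end < start")
        span = self.start - self.end
        n_steps = span / self.step
        if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
            raise ValueError(
                f"step {self.step} does not divide the span {span}"
            )
        n = int(round(n_steps)) + 1
        vals = self.start - self.step * np.arange(n)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_points(self) -> int:
        return self.values.size

    def band_indices(self, high: float, low: float) -> np.ndarray:
        """Indices of grid points with ``low <= wavenumber <= high``."""
        if low > high:
            raise ValueError("expected low <= high")
        return np.nonzero((self.values >= low) & (self.values <= high))[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return (self.start, self.end, self.step) == (other.start, other.end, other.step)

    def __hash__(self) -> int:
        return hash((self.start, self.end, self.step))


#: The emulated FT-NIR acquisition grid: 10,000 -> 3800 cm^-1 at 2 cm^-1 (3101 points).
DEFAULT_GRID = WavenumberGrid(10_000.0, 3_800.0, 2.0)
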