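"""Instrument response function (IRF) models and the shared time axis.

Time-resolved plate readers record each well's emission as a waveform on a
uniform nanosecond grid.  The observed waveform is the underlying exponential
decay convolved with the instrument response — the system's reaction to an
instantaneous excitation pulse.  Two IRF shapes are supported:

* ``gaussian`` — a Gaussian pulse parameterised by its centre and FWHM,
  typical of microchip-laser / photomultiplier detection chains, and
  convenient because its convolution with an exponential has a closed form
  (the exponentially modified Gaussian).
* ``delta`` — an idealised instantaneous response, useful for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "IRFModel", "DEFAULT_GRID", "DEFAULT_IRF"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis: ``n`` points starting at ``start`` ns, spaced ``step`` ns."""

    start: float = 0.0
    step: float = 0.25
    n: int = 200

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.n < 2:
            raise ValueError(f"grid must have at least 2 points, got n={self.n}")

    @property
    def end(self) -> float:
        return self.start + self.step * (self.n - 1)

    def times(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n)

    @classmethod
    def from_times(cls, t: np.ndarray) -> "TimeGrid":
        t = np.asarray(t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time axis must be 1-D with at least 2 points")
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time axis must be strictly increasing and uniform")
        return cls(start=float(t[0]), step=float(steps[0]), n=int(t.size))


@dataclass(frozen=True)
class IRFModel:
    """Instrument response: ``gaussian`` (centre + FWHM, ns) or ``delta`` (centre only).

    The IRF is treated as a unit-area pulse; ``width`` is the full width at
    half maximum for the Gaussian shape and is ignored for ``delta``.
    """

    shape: str = "gaussian"
    center: float = 10.0
    width: float = 1.0
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "delta"):
            raise ValueError(f"unknown IRF shape {self.shape!r}; use 'gaussian' or 'delta'")
        if self.shape == "gaussian" and self.width <= 0:
            raise ValueError(f"gaussian IRF requires width > 0, got {self.width}")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation in ns (0 for a delta IRF)."""
        return 0.0 if self.shape == "delta" else self.width * _FWHM_TO_SIGMA

    def profile(self, grid: TimeGrid | None = None) -> np.ndarray:
        """Discretised IRF on ``grid`` (default: the model's own grid), summing to 1."""
        g = grid or self.grid
        t = g.times()
        if self.shape == "delta":
            out = np.zeros(g.n)
            out[int(np.argmin(np.abs(t - self.center)))] = 1.0
            return out
        out = np.exp(-0.5 * ((t - self.center) / self.sigma) ** 2)
        total = out.sum()
        if total <= 0:
            raise ValueError("IRF centre lies outside the grid: discretised profile is zero")
        return out / total


DEFAULT_GRID = TimeGrid(start=0.0, step=0.25, n=200)
DEFAULT_IRF = IRFModel(shape="gaussian", center=10.0, width=1.0, grid=DEFAULT_GRID)
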