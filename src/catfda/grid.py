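"""The common 288-point daily time grid.

All curves live on the midpoints of the 288 five-minute bins covering the
24-hour day: t_j = (5 j + 2.5) / 60 hours for j = 0..287.  Quadrature on this
grid uses the uniform weight w = 1/12 hour per point, so that for curves f, g

    <f, g> = w * sum_j f(t_j) g(t_j)

approximates the L2 inner product on [0, 24) hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MINUTES_PER_DAY = 1440
BIN_MINUTES = 5
N_BINS = N_MINUTES_PER_DAY // BIN_MINUTES  # 288


@dataclass(frozen=True)
class TimeGrid:
    """Midpoint grid of the 5-minute bins over one day, with quadrature weight."""

    n_bins: int = N_BINS
    day_hours: float = 24.0

    @property
    def bin_width(self) -> float:
        """Bin width in hours (1/12 h for the default grid)."""
        return self.day_hours / self.n_bins

    @property
    def weight(self) -> float:
        """Quadrature weight per grid point, in hours."""
        return self.bin_width

    @property
    def t(self) -> np.ndarray:
        """Bin midpoints in hours, shape (n_bins,)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in hours, shape (n_bins + 1,)."""
        return np.arange(self.n_bins + 1) * self.bin_width

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        """Quadrature inner product <f, g> = w * sum f g (hours units)."""
        f = np.asarray(f, dtype=float)
        g = np.asarray(g, dtype=float)
        return float(self.weight * np.sum(f * g, axis=-1))

    def norm(self, f: np.ndarray) -> float:
        """Quadrature L2 norm of a curve."""
        return float(np.sqrt(self.inner(f, f)))


DEFAULT_GRID = TimeGrid()
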