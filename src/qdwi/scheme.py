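"""Diffusion acquisition scheme and per-curve signal containers.

The acquisition is described by an ordered list of b-values (s/mm²) plus the
number of diffusion-encoding directions.  The default scheme is the 13-b-value
multi-shell protocol used throughout this package: b = 0, 10, 20, 30, 50, 70,
100, 150, 200, 400, 800, 1500, 2000 s/mm² with 30 directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BValueScheme", "DWISignal", "DEFAULT_B_VALUES", "default_scheme",
           "read_bval", "write_bval"]

DEFAULT_B_VALUES = (0.0, 10.0, 20.0, 30.0, 50.0, 70.0, 100.0, 150.0, 200.0,
                    400.0, 800.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion weightings (s/mm²) and direction count.

    Invariants: b-values strictly increasing, first element 0, all >= 0,
    n_directions >= 1.
    """

    b_values: tuple[float, ...]
    n_directions: int = 30

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("scheme needs at least two b-values")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if self.n_directions < 1:
            raise ValueError("n_directions must be a positive integer")
        object.__setattr__(self, "b_values", tuple(float(v) for v in b))

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    def __len__(self) -> int:
        return len(self.b_values)


def default_scheme(n_directions: int = 30) -> BValueScheme:
    """The 13-b-value, 30-direction multi-shell scheme."""
    return BValueScheme(DEFAULT_B_VALUES, n_directions)


@dataclass
class DWISignal:
    """A single signal-vs-b decay curve (already direction-averaged).

    ``signal`` holds intensities aligned with ``scheme.b_values``; ``s0`` is
    the b=0 intensity used for normalization.  The normalized curve
    ``signal/s0`` must start at 1 within tolerance.
    """

    scheme: BValueScheme
    s0: float
    signal: np.ndarray
    rtol_b0: float = field(default=0.05, repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.scheme.n_b,):
            raise ValueError("signal length must match the number of b-values")
        if not (self.s0 > 0):
            raise ValueError("s0 must be positive")
        if abs(self.signal[0] / self.s0 - 1.0) > self.rtol_b0:
            raise ValueError("signal at b=0 must equal s0 within tolerance")

    @property
    def normalized(self) -> np.ndarray:
        return self.signal / self.s0


def read_bval(path: str | Path) -> np.ndarray:
    """Read an FSL-style whitespace-separated bval text file."""
    return np.loadtxt(path, ndmin=1).ravel()


def write_bval(path: str | Path, b_values) -> None:
    """Write b-values as a single whitespace-separated line (FSL style)."""
    b = np.asarray(b_values, dtype=float).ravel()
    Path(path).write_text(" ".join(f"{v:g}" for v in b) + "\n")
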