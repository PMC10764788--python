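"""Well-tempered metadynamics bias along a linear, rotatable collective variable.

The collective variable (CV) is the linear projection ``s = x*cos(theta) +
y*sin(theta)``; theta = 0 is the x-coordinate, the optimal CV for both model
potentials, and rotating theta away from zero degrades the CV on purpose.

Hills are Gaussians of width ``sigma`` deposited every ``pace`` steps.  The
well-tempered rule scales the deposited height by
``exp(-V_b(s)/((gamma_B - 1) k_B T))`` with ``V_b`` the bias already present
at the new hill's centre, so the bias converges instead of growing linearly.
Energies are in k_B*T throughout.

The bias is accumulated on a uniform grid for O(1) queries: each deposited
hill adds its closed-form Gaussian to the energy grid and its closed-form
derivative to a parallel dV/ds grid, so the force retains the analytic
hill-sum form (up to linear interpolation between nodes) rather than being a
finite difference of the energy grid.

``record_exposure`` accumulates the infrequent-metadynamics acceleration
integral ``I = sum_t dt * exp(V_b(s(t), t))`` (bias in k_B*T) used to rescale
biased first-passage times back to unbiased ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .units import FS_PER_NS

__all__ = ["CVSpec", "MetaDConfig", "BiasState", "pace_from_bias_rate",
           "write_hills", "read_hills"]

#: hills are truncated at this many sigmas from their centre
HILL_CUTOFF_SIGMAS = 6.0
#: guard for exp() in the exposure integral
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class CVSpec:
    """Linear CV ``s(x, y) = x cos(theta) + y sin(theta)`` (theta in radians)."""

    theta: float = 0.0

    @property
    def cos(self) -> float:
        return math.cos(self.theta)

    @property
    def sin(self) -> float:
        return math.sin(self.theta)

    def value(self, x, y):
        return x * self.cos + y * self.sin


@dataclass(frozen=True)
class MetaDConfig:
    """Well-tempered metadynamics parameters.

    height is in k_B*T, sigma and the grid in angstrom; ``pace`` is the number
    of integration steps between depositions.
    """

    height: float = 0.5
    sigma: float = 1.3
    bias_factor: float = 10.0
    pace: int = 100
    grid_min: float = -400.0
    grid_max: float = 400.0
    grid_spacing: float = 0.01

    def __post_init__(self) -> None:
        if self.bias_factor <= 1.0:
            raise ValueError("well-tempered bias factor must exceed 1")
        if self.sigma <= 0:
            raise ValueError("hill width sigma must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1 step")
        if self.grid_max <= self.grid_min or self.grid_spacing <= 0:
            raise ValueError("invalid grid specification")

    @property
    def n_grid(self) -> int:
        return int(round((self.grid_max - self.grid_min) / self.grid_spacing)) + 1


def pace_from_bias_rate(bias_rate_per_ns: float, dt_fs: float = 1.0) -> int:
    """Steps between hills for a deposition rate in hills/ns.

    10^4 ns^-1 at dt = 1 fs maps to one hill every 100 steps.
    """
    if bias_rate_per_ns <= 0:
        raise ValueError("bias deposition rate must be positive")
    return max(1, round(FS_PER_NS / (bias_rate_per_ns * dt_fs)))


# --- JIT grid primitives (shared with the Langevin kernel) -----------------

@njit(cache=True, fastmath=True)
def _interp(grid, grid_min, inv_dx, s):
    """Linear interpolation; caller guarantees s is inside the grid."""
    u = (s - grid_min) * inv_dx
    i = int(u)
    if i >= grid.shape[0] - 1:
        i = grid.shape[0] - 2
    w = u - i
    return grid[i] * (1.0 - w) + grid[i + 1] * w


@njit(cache=True, fastmath=True)
def _deposit(vgrid, fgrid, grid_min, dx, center, sigma, height):
    """Add one Gaussian hill (energy and dV/ds) to the grids."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    half_width = HILL_CUTOFF_SIGMAS * sigma
    i_lo = int(math.ceil((center - half_width - grid_min) / dx))
    i_hi = int(math.floor((center + half_width - grid_min) / dx))
    if i_lo < 0:
        i_lo = 0
    if i_hi > vgrid.shape[0] - 1:
        i_hi = vgrid.shape[0] - 1
    for i in range(i_lo, i_hi + 1):
        d = grid_min + i * dx - center
        g = height * math.exp(-d * d * inv2s2)
        vgrid[i] += g
        fgrid[i] += -d / (sigma * sigma) * g


class BiasState:
    """Accumulated metadynamics bias along one CV.

    Maintains the energy grid, the matching dV/ds grid, a log of deposited
    hills, and the running iMetaD exposure integral for the current segment.
    """

    def __init__(self, config: MetaDConfig, cv: CVSpec | None = None):
        self.config = config
        self.cv = cv if cv is not None else CVSpec()
        n = config.n_grid
        self.vgrid = np.zeros(n)
        self.fgrid = np.zeros(n)  # dV_bias/ds at the nodes
        self.hills: list[tuple[float, float, float, float]] = []  # (t_fs, center, sigma, height)
        self.exposure = 0.0  # fs, rescaled

    # -- deposit / reset ----------------------------------------------------

    def deposit_hill(self, cv_now: float, time_fs: float = 0.0) -> float:
        """Deposit one well-tempered hill centred at ``cv_now``.

        Returns the deposited height (k_B*T) after well-tempered scaling.
        """
        cfg = self.config
        self._check_bounds(cv_now)
        scaled = cfg.height * math.exp(
            -self.bias_energy(cv_now) / (cfg.bias_factor - 1.0)
        )
        _deposit(self.vgrid, self.fgrid, cfg.grid_min, cfg.grid_spacing,
                 cv_now, cfg.sigma, scaled)
        self.hills.append((time_fs, cv_now, cfg.sigma, scaled))
        return scaled

    def reset(self) -> None:
        """Zero the bias and hill log and open a fresh exposure segment."""
        self.vgrid[:] = 0.0
        self.fgrid[:] = 0.0
        self.hills.clear()
        self.exposure = 0.0

    # -- queries ------------------------------------------------------------

    def bias_energy(self, s: float) -> float:
        """V_bias(s) in k_B*T by linear interpolation of the grid."""
        self._check_bounds(s)
        return float(_interp(self.vgrid, self.config.grid_min,
                             1.0 / self.config.grid_spacing, s))

    def bias_energy_from_hills(self, s: float) -> float:
        """Direct sum over the hill log (reference path for grid validation)."""
        total = 0.0
        for _, c, sig, h in self.hills:
            total += h * math.exp(-((s - c) ** 2) / (2.0 * sig * sig))
        return total

    def bias_force(self, x: float, y: float) -> tuple[float, float]:
        """-grad V_bias at (x, y) in k_B*T/A, via the chain rule through the CV."""
        s = self.cv.value(x, y)
        self._check_bounds(s)
        dvds = float(_interp(self.fgrid, self.config.grid_min,
                             1.0 / self.config.grid_spacing, s))
        return -dvds * self.cv.cos, -dvds * self.cv.sin

    def record_exposure(self, cv_now: float, dt_fs: float) -> float:
        """Advance the iMetaD exposure integral by one step; returns it (fs)."""
        v = min(self.bias_energy(cv_now), _EXP_CLIP)
        self.exposure += dt_fs * math.exp(v)
        return self.exposure

    def _check_bounds(self, s: float) -> None:
        if not (self.config.grid_min <= s <= self.config.grid_max):
            raise ValueError(
                f"CV value {s:.3f} A outside bias grid "
                f"[{self.config.grid_min}, {self.config.grid_max}] A"
            )


# --- HILLS-style I/O -------------------------------------------------------

_HILLS_COLUMNS = ["time", "cv_center", "sigma", "height", "bias_factor"]


def write_hills(path, bias: BiasState) -> None:
    """Write the hill log as a PLUMED-HILLS-dialect tab-separated file."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(_HILLS_COLUMNS) + "\n")
        for t, c, sig, h in bias.hills:
            fh.write(f"{t:.1f}\t{c:.6f}\t{sig:.6f}\t{h:.9f}\t"
                     f"{bias.config.bias_factor:.3f}\n")


def read_hills(path) -> pd.DataFrame:
    """Read a HILLS-dialect file back into a DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#", names=_HILLS_COLUMNS)
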