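"""NVT Langevin dynamics of a single 2D particle.

Trajectories start from a fixed position with Maxwell-Boltzmann velocities,
run under the analytic potential plus (optionally) a metadynamics bias, and
stop when a committor-style criterion on x first holds.  A resetting
schedule (Poisson or sharp) teleports the particle back to the start with
fresh velocities and zeroes the bias; the first-passage clock keeps running
across resets.

The production integrator is the JIT kernel in ``_kernels``; this module
owns configuration, seeding, and the record types.  A pure-Python
``advance_step`` / ``apply_reset`` pair mirrors the kernel step-for-step for
contract tests and didactic use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .metad import BiasState, CVSpec, MetaDConfig
from .potentials import Potential2D
from .units import FS_PER_NS, kbt_mech

__all__ = [
    "ThermoConfig", "StopCriterion", "ResetSchedule", "SimState",
    "TrajectoryRecord", "sample_velocities", "advance_step", "apply_reset",
    "run_trajectory", "make_streams",
]

DEFAULT_MAX_STEPS = 10 ** 9


@dataclass(frozen=True)
class ThermoConfig:
    """Thermostat and integration settings (LAMMPS-style Langevin NVT)."""

    temperature: float = 300.0   # K
    mass: float = 40.0           # g/mol (argon-like particle)
    friction: float = 0.01      # fs^-1
    dt: float = 1.0              # fs

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.mass <= 0 or self.friction < 0:
            raise ValueError("require dt > 0, mass > 0, friction >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt_mech(self) -> float:
        """k_B*T in g*A^2/(fs^2*mol)."""
        return kbt_mech(self.temperature)

    @property
    def velocity_sigma(self) -> float:
        """Maxwell-Boltzmann per-component velocity std, A/fs."""
        return math.sqrt(self.kbt_mech / self.mass)


@dataclass(frozen=True)
class StopCriterion:
    """First-passage criterion on the x coordinate, checked every step."""

    mode: str  # 'x_le' | 'x_lt' | 'x_between'
    a: float
    b: float = 0.0

    @classmethod
    def x_le(cls, c: float) -> "StopCriterion":
        return cls("x_le", c)

    @classmethod
    def x_lt(cls, c: float) -> "StopCriterion":
        return cls("x_lt", c)

    @classmethod
    def x_between(cls, lo: float, hi: float) -> "StopCriterion":
        if hi <= lo:
            raise ValueError("x_between needs lo < hi")
        return cls("x_between", lo, hi)

    def _encode(self) -> tuple[int, float, float]:
        code = {"x_le": _kernels.STOP_X_LE, "x_lt": _kernels.STOP_X_LT,
                "x_between": _kernels.STOP_X_BETWEEN}[self.mode]
        return code, self.a, self.b

    def hit(self, x: float) -> bool:
        if self.mode == "x_le":
            return x <= self.a
        if self.mode == "x_lt":
            return x < self.a
        return self.a < x < self.b


@dataclass(frozen=True)
class ResetSchedule:
    """Resetting specification: none, Poisson (rate in ns^-1) or sharp (period in ns)."""

    mode: str = "none"  # 'none' | 'poisson' | 'sharp'
    rate: float = 0.0    # ns^-1, poisson only
    period: float = 0.0  # ns, sharp only

    def __post_init__(self) -> None:
        if self.mode not in ("none", "poisson", "sharp"):
            raise ValueError(f"unknown resetting mode {self.mode!r}")
        if self.mode == "poisson" and self.rate <= 0:
            raise ValueError("poisson resetting needs rate > 0 (ns^-1)")
        if self.mode == "sharp" and self.period <= 0:
            raise ValueError("sharp resetting needs period > 0 (ns)")

    @classmethod
    def none(cls) -> "ResetSchedule":
        return cls("none")

    @classmethod
    def poisson(cls, rate_per_ns: float) -> "ResetSchedule":
        return cls("poisson", rate=rate_per_ns)

    @classmethod
    def sharp(cls, period_ns: float) -> "ResetSchedule":
        return cls("sharp", period=period_ns)

    def _encode(self, dt: float) -> tuple[int, float, int]:
        if self.mode == "poisson":
            return 1, self.rate / FS_PER_NS, 0
        if self.mode == "sharp":
            return 2, 0.0, max(1, round(self.period * FS_PER_NS / dt))
        return 0, 0.0, 0


@dataclass
class SimState:
    """Mutable state of the pure-Python integration path."""

    x: float
    y: float
    vx: float
    vy: float
    elapsed_steps: int = 0
    segment_steps: int = 0
    n_resets: int = 0
    fx: float = 0.0
    fy: float = 0.0

    @property
    def position(self) -> tuple[float, float]:
        return self.x, self.y


@dataclass(frozen=True)
class TrajectoryRecord:
    """Outcome of one first-passage run (possibly spanning many resets)."""

    traj_id: int
    seed: int
    fpt_steps: int
    fpt_fs: float
    n_resets: int
    censored: int               # 0 ok, 1 max_steps, 2 segment-buffer overflow
    exposure_fs: float = 0.0    # iMetaD-rescaled duration of the final segment
    segment_steps: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    segment_tau_fs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def fpt_ns(self) -> float:
        return self.fpt_fs / FS_PER_NS


def make_streams(seed) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Three independent Philox streams (dynamics, velocity init, reset times).

    Separate streams mean that switching resetting on does not perturb the
    thermal noise sequence.  ``seed`` may be an int or a SeedSequence.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return tuple(np.random.Generator(np.random.Philox(child)) for child in ss.spawn(3))


def sample_velocities(thermo: ThermoConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (vx, vy) from the Maxwell-Boltzmann distribution, A/fs."""
    sv = thermo.velocity_sigma
    return rng.normal(0.0, sv), rng.normal(0.0, sv)


def _total_force(potential: Potential2D, bias: BiasState | None, x: float, y: float):
    fx, fy = potential.force(x, y)
    if bias is not None:
        bfx, bfy = bias.bias_force(x, y)
        fx += bfx
        fy += bfy
    return fx, fy


def advance_step(
    state: SimState,
    potential: Potential2D,
    thermo: ThermoConfig,
    rng: np.random.Generator,
    bias: BiasState | None = None,
) -> SimState:
    """One BAOAB step in place (mirrors the JIT kernel exactly).

    The cached force on ``state`` must be initialised before the first call;
    use ``init_state``.
    """
    dt = thermo.dt
    m = thermo.mass
    kt = thermo.kbt_mech
    c1 = math.exp(-thermo.friction * dt)
    c2 = math.sqrt(kt / m * (1.0 - c1 * c1))
    half = 0.5 * dt / m

    state.vx += half * state.fx
    state.vy += half * state.fy
    state.x += 0.5 * dt * state.vx
    state.y += 0.5 * dt * state.vy
    state.vx = c1 * state.vx + c2 * rng.normal(0.0, 1.0)
    state.vy = c1 * state.vy + c2 * rng.normal(0.0, 1.0)
    state.x += 0.5 * dt * state.vx
    state.y += 0.5 * dt * state.vy
    fx, fy = _total_force(potential, bias, state.x, state.y)
    state.fx = fx * kt
    state.fy = fy * kt
    state.vx += half * state.fx
    state.vy += half * state.fy
    state.elapsed_steps += 1
    state.segment_steps += 1
    return state


def init_state(
    potential: Potential2D,
    thermo: ThermoConfig,
    init_position: tuple[float, float],
    rng_vel: np.random.Generator,
    bias: BiasState | None = None,
) -> SimState:
    vx, vy = sample_velocities(thermo, rng_vel)
    st = SimState(x=init_position[0], y=init_position[1], vx=vx, vy=vy)
    fx, fy = _total_force(potential, bias, st.x, st.y)
    st.fx = fx * thermo.kbt_mech
    st.fy = fy * thermo.kbt_mech
    return st


def apply_reset(
    state: SimState,
    potential: Potential2D,
    thermo: ThermoConfig,
    init_position: tuple[float, float],
    rng_vel: np.random.Generator,
    bias: BiasState | None = None,
) -> SimState:
    """Restart in place: fixed position, fresh velocities, bias zeroed.

    The overall step/time tally is untouched; only the segment clock restarts.
    """
    state.x, state.y = init_position
    state.vx, state.vy = sample_velocities(thermo, rng_vel)
    if bias is not None:
        bias.reset()
    fx, fy = potential.force(state.x, state.y)
    state.fx = fx * thermo.kbt_mech
    state.fy = fy * thermo.kbt_mech
    state.n_resets += 1
    state.segment_steps = 0
    return state


def run_trajectory(
    potential: Potential2D,
    thermo: ThermoConfig,
    stop: StopCriterion,
    init_position: tuple[float, float],
    seed,
    schedule: ResetSchedule | None = None,
    cv: CVSpec | None = None,
    metad: MetaDConfig | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    record_segments: bool = False,
    traj_id: int = 0,
    segment_capacity: int = 1 << 16,
    _grids: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrajectoryRecord:
    """Run one trajectory to first passage and return its record.

    ``seed`` may be an int or a ``np.random.SeedSequence``; three independent
    sub-streams are derived from it.  ``record_segments`` switches on the
    per-segment iMetaD exposure bookkeeping needed for kinetics inference.
    ``_grids`` lets batch drivers reuse preallocated bias grids.
    """
    schedule = schedule or ResetSchedule.none()
    stop_mode, stop_a, stop_b = stop._encode()
    reset_mode, rate_fs, period_steps = schedule._encode(thermo.dt)
    rng_dyn, rng_vel, rng_reset = make_streams(seed)

    use_metad = metad is not None
    if use_metad:
        cv = cv or CVSpec()
        if _grids is not None:
            vgrid, fgrid = _grids
            vgrid[:] = 0.0
            fgrid[:] = 0.0
        else:
            vgrid = np.zeros(metad.n_grid)
            fgrid = np.zeros(metad.n_grid)
        m_args = (True, cv.cos, cv.sin, metad.height, metad.sigma,
                  metad.bias_factor, metad.pace,
                  metad.grid_min, metad.grid_max, metad.grid_spacing,
                  vgrid, fgrid)
    else:
        empty = np.empty(0)
        m_args = (False, 1.0, 0.0, 0.0, 1.0, 10.0, 1,
                  -1.0, 1.0, 1.0, empty, empty)

    if record_segments:
        seg_steps = np.zeros(segment_capacity, np.int64)
        seg_tau = np.zeros(segment_capacity)
    else:
        seg_steps = np.zeros(0, np.int64)
        seg_tau = np.zeros(0)

    fpt_steps, n_resets, censored, n_segments, exposure = _kernels.simulate(
        float(init_position[0]), float(init_position[1]),
        thermo.dt, thermo.friction, thermo.mass, thermo.kbt_mech, int(max_steps),
        potential.params.pot_id, potential.params.as_array(),
        stop_mode, stop_a, stop_b,
        *m_args,
        record_segments,
        reset_mode, rate_fs, period_steps,
        seg_steps, seg_tau,
        rng_dyn, rng_vel, rng_reset,
    )

    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    return TrajectoryRecord(
        traj_id=traj_id,
        seed=int(seed_repr),
        fpt_steps=int(fpt_steps),
        fpt_fs=fpt_steps * thermo.dt,
        n_resets=int(n_resets),
        censored=int(censored),
        exposure_fs=float(exposure),
        segment_steps=seg_steps[:n_segments].copy(),
        segment_tau_fs=seg_tau[:n_segments].copy(),
    )
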