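"""Analytic 2D model potentials.

Two families of two-state model landscapes are provided, both symmetric in x
and in y, with energies in units of k_B*T (300 K) and lengths in angstrom:

``two_wells``
    A soft harmonic trap split by a Gaussian ridge,
    ``V(x, y) = A1*x^2 + A2*y^2 + B*exp(-C*x^2)``.
    With the default coefficients the two minima sit near x = +-2.6 A and are
    separated by a barrier of ~5 k_B*T at every y.

``faradjian_elber``
    A modified Faradjian-Elber landscape,
    ``V(x, y) = A1*(x^6 + y'^6) + A2*exp(-x^2/s1^2) * (1 - B*exp(-y'^2/s2^2))``
    with ``y' = y_scale * y``.  The central ridge is ~12 k_B*T high for most
    y but has a narrow ~3 k_B*T saddle around y = 0 -- the classic case of a
    good reaction channel that a 1D collective variable can miss.

``harmonic1d_test``
    ``V = 0.5*k*(x^2 + y^2)`` (k = 0 gives a free particle); only used for
    integrator validation against equipartition / Einstein-relation oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

__all__ = [
    "PotentialParams",
    "Potential2D",
    "make_potential",
    "barrier_summary",
    "FAMILIES",
]

FAMILIES = ("two_wells", "faradjian_elber", "harmonic1d_test")
_POT_ID = {name: i for i, name in enumerate(FAMILIES)}

_DEFAULTS = {
    "two_wells": dict(A1=1e-3, A2=1e-2, B=5.0, C=1.3),
    "faradjian_elber": dict(A1=1.2e-5, A2=12.0, B=0.75,
                            sigma1=1.0, sigma2=0.5, y_scale=0.1),
    "harmonic1d_test": dict(k=1.0),
}


@dataclass(frozen=True)
class PotentialParams:
    """Coefficients of an analytic model potential (energies in k_B*T, lengths in A)."""

    family: str
    A1: float = 0.0
    A2: float = 0.0
    B: float = 0.0
    C: float = 0.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    y_scale: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown potential family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "two_wells" and self.C <= 0:
            raise ValueError("two_wells requires C > 0 (Gaussian barrier width)")
        if self.family == "faradjian_elber":
            if self.sigma1 <= 0 or self.sigma2 <= 0:
                raise ValueError("faradjian_elber requires sigma1, sigma2 > 0")

    def as_array(self) -> np.ndarray:
        """Pack coefficients into the flat float64 layout used by the JIT kernels."""
        if self.family == "two_wells":
            return np.array([self.A1, self.A2, self.B, self.C], dtype=np.float64)
        if self.family == "faradjian_elber":
            return np.array(
                [self.A1, self.A2, self.B, self.sigma1, self.sigma2, self.y_scale],
                dtype=np.float64,
            )
        return np.array([self.k], dtype=np.float64)

    @property
    def pot_id(self) -> int:
        return _POT_ID[self.family]


# --- JIT evaluators shared with the Langevin kernel ------------------------

@njit(cache=True, fastmath=True)
def _energy(pot_id: int, p: np.ndarray, x: float, y: float) -> float:
    if pot_id == 0:  # two_wells
        return p[0] * x * x + p[1] * y * y + p[2] * math.exp(-p[3] * x * x)
    elif pot_id == 1:  # faradjian_elber
        yp = p[5] * y
        gx = math.exp(-x * x / (p[3] * p[3]))
        gy = math.exp(-yp * yp / (p[4] * p[4]))
        return p[0] * (x ** 6 + yp ** 6) + p[1] * gx * (1.0 - p[2] * gy)
    else:  # harmonic
        return 0.5 * p[0] * (x * x + y * y)


@njit(cache=True, fastmath=True)
def _force(pot_id: int, p: np.ndarray, x: float, y: float):
    """-grad V in k_B*T / A."""
    if pot_id == 0:
        e = p[2] * math.exp(-p[3] * x * x)
        fx = -2.0 * p[0] * x + 2.0 * p[3] * x * e
        fy = -2.0 * p[1] * y
        return fx, fy
    elif pot_id == 1:
        yp = p[5] * y
        gx = math.exp(-x * x / (p[3] * p[3]))
        gy = math.exp(-yp * yp / (p[4] * p[4]))
        dV_dx = 6.0 * p[0] * x ** 5 \
            + p[1] * gx * (-2.0 * x / (p[3] * p[3])) * (1.0 - p[2] * gy)
        dV_dyp = 6.0 * p[0] * yp ** 5 \
            + p[1] * gx * p[2] * gy * 2.0 * yp / (p[4] * p[4])
        return -dV_dx, -dV_dyp * p[5]
    else:
        return -p[0] * x, -p[0] * y


@dataclass(frozen=True)
class Potential2D:
    """Callable analytic potential with closed-form gradient."""

    params: PotentialParams
    _p: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_p", self.params.as_array())

    @property
    def family(self) -> str:
        return self.params.family

    def energy(self, x, y):
        """V(x, y) in k_B*T.  Accepts scalars or numpy arrays."""
        if np.isscalar(x) and np.isscalar(y):
            return _energy(self.params.pot_id, self._p, float(x), float(y))
        x, y = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float))
        out = np.empty(x.shape)
        flat_x, flat_y, flat_o = x.ravel(), y.ravel(), out.ravel()
        for i in range(flat_x.size):
            flat_o[i] = _energy(self.params.pot_id, self._p, flat_x[i], flat_y[i])
        return out

    def force(self, x: float, y: float) -> tuple[float, float]:
        """-grad V at (x, y), in k_B*T / A."""
        return _force(self.params.pot_id, self._p, float(x), float(y))

    def gradient(self, x: float, y: float) -> tuple[float, float]:
        fx, fy = self.force(x, y)
        return -fx, -fy


def make_potential(family: str, overrides: dict | None = None) -> Potential2D:
    """Build a model potential from its family name, with the published defaults.

    Parameters
    ----------
    family : str
        One of ``two_wells``, ``faradjian_elber``, ``harmonic1d_test``.
    overrides : dict, optional
        Coefficient overrides keyed by symbol name (``A1``, ``B``, ``sigma2``,
        ``y_scale``, ...).  Unknown keys raise.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown potential family {family!r}; expected one of {FAMILIES}")
    kwargs = dict(_DEFAULTS[family])
    if overrides:
        unknown = set(overrides) - set(kwargs)
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)} for family {family!r}")
        kwargs.update(overrides)
    return Potential2D(PotentialParams(family=family, **kwargs))


def barrier_summary(
    potential: Potential2D,
    y: float = 0.0,
    x_range: tuple[float, float] = (-10.0, 10.0),
    scan_step: float = 1e-3,
) -> dict:
    """Locate minima and the central barrier of a 1D section V(x, y=const).

    A dense scan at ``scan_step`` locates candidate stationary points, which
    are then refined by bounded scalar minimisation (Brent).  The barrier
    height is V(max) - V(min) for the highest interior maximum between the
    two outermost minima.

    Returns
    -------
    dict with keys ``minima`` (list of x positions), ``barrier_x``,
    ``barrier_height`` (k_B*T), ``v_min``, ``v_max``.
    """
    xs = np.arange(x_range[0], x_range[1] + scan_step / 2, scan_step)
    vs = potential.energy(xs, np.full_like(xs, y))

    interior = np.arange(1, len(xs) - 1)
    is_min = (vs[interior] <= vs[interior - 1]) & (vs[interior] <= vs[interior + 1])
    is_max = (vs[interior] >= vs[interior - 1]) & (vs[interior] >= vs[interior + 1])
    min_idx = interior[is_min]
    max_idx = interior[is_max]
    if len(min_idx) < 2:
        raise ValueError("section has fewer than two minima; no barrier to report")

    def refine(i: int, sign: float) -> float:
        lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
        res = minimize_scalar(
            lambda x: sign * potential.energy(x, y), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    minima = sorted(refine(i, +1.0) for i in _dedupe(min_idx))
    lo_min, hi_min = minima[0], minima[-1]
    between = [i for i in max_idx if lo_min < xs[i] < hi_min]
    if not between:
        raise ValueError("no interior maximum between the outermost minima")
    top_i = max(between, key=lambda i: vs[i])
    barrier_x = refine(top_i, -1.0)

    v_min = min(float(potential.energy(m, y)) for m in minima)
    v_max = float(potential.energy(barrier_x, y))
    return {
        "minima": minima,
        "barrier_x": barrier_x,
        "v_min": v_min,
        "v_max": v_max,
        "barrier_height": v_max - v_min,
    }


def _dedupe(idx: np.ndarray, gap: int = 5) -> list[int]:
    """Collapse runs of adjacent flagged grid indices to one representative."""
    out: list[int] = []
    for i in idx:
        if not out or i - out[-1] > gap:
            out.append(int(i))
        else:
            out[-1] = int(i)
    return out
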