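"""JIT-compiled inner loops for Langevin dynamics with metadynamics + resetting.

One particle in 2D, BAOAB splitting, forces in k_B*T/A converted to
mechanical units (g*A/fs^2/mol) by multiplying with k_B*T_mech.  The same
kernel serves unbiased, metadynamics-only, resetting-only and combined runs;
branches are flag-controlled and loop-invariant.

Step ordering (one iteration):
  B (half kick) - A (half drift) - O (exact Ornstein-Uhlenbeck) - A - B,
then first-passage check, then reset check, then (if due) hill deposition.
A first passage and a reset on the same step resolve in favour of the first
passage.
"""

import math

import numpy as np
from numba import njit

from .potentials import _force
from .metad import _interp, _deposit, _EXP_CLIP

#: censoring codes
NOT_CENSORED = 0
CENSORED_MAX_STEPS = 1
CENSORED_SEGMENT_OVERFLOW = 2
CENSORED_GRID_EXIT = 3

#: stop-criterion modes
STOP_X_LE = 0
STOP_X_LT = 1
STOP_X_BETWEEN = 2


@njit(cache=True, fastmath=True)
def _stop_hit(mode, a, b, x):
    if mode == STOP_X_LE:
        return x <= a
    elif mode == STOP_X_LT:
        return x < a
    else:
        return a < x < b


@njit(cache=True, fastmath=True)
def simulate(
    x0, y0,
    dt, gamma, mass, kt_mech, max_steps,
    pot_id, pp,
    stop_mode, stop_a, stop_b,
    use_metad, costh, sinth, height, sigma, bias_factor, pace,
    grid_min, grid_max, dx, vgrid, fgrid,
    record_segments,
    reset_mode, reset_rate_per_fs, reset_period_steps,
    seg_steps, seg_tau,
    rng_dyn, rng_vel, rng_reset,
):
    """Run one trajectory to first passage (or censoring).

    Returns (fpt_steps, n_resets, censored, n_segments, exposure_fs) where
    exposure_fs is the iMetaD-rescaled duration of the final segment and the
    per-segment records are written into seg_steps / seg_tau (lengths = the
    returned n_segments; the last segment is the transition segment unless
    the run was censored).
    """
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kt_mech / mass * (1.0 - c1 * c1))
    sv = math.sqrt(kt_mech / mass)
    half = 0.5 * dt / mass
    inv_dx = 1.0 / dx

    x = x0
    y = y0
    vx = rng_vel.normal(0.0, sv)
    vy = rng_vel.normal(0.0, sv)

    n_resets = 0
    n_segments = 0
    seg_step = 0          # steps since last reset
    exposure = 0.0        # fs, current segment

    if _stop_hit(stop_mode, stop_a, stop_b, x):
        if record_segments and seg_steps.shape[0] > 0:
            seg_steps[0] = 0
            seg_tau[0] = 0.0
            n_segments = 1
        return 0, 0, NOT_CENSORED, n_segments, 0.0

    # next reset, in segment steps (0 = never)
    next_reset = 0
    if reset_mode == 1:
        next_reset = int(math.ceil(rng_reset.exponential(1.0 / reset_rate_per_fs) / dt))
        if next_reset < 1:
            next_reset = 1
    elif reset_mode == 2:
        next_reset = reset_period_steps

    fx, fy = _force(pot_id, pp, x, y)
    if use_metad:
        s = x * costh + y * sinth
        if s < grid_min or s > grid_max:
            return 0, 0, CENSORED_GRID_EXIT, 0, 0.0
        dvds = _interp(fgrid, grid_min, inv_dx, s)
        fx -= dvds * costh
        fy -= dvds * sinth
    fx *= kt_mech
    fy *= kt_mech

    for step in range(1, max_steps + 1):
        # BAOAB
        vx += half * fx
        vy += half * fy
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        vx = c1 * vx + c2 * rng_dyn.normal(0.0, 1.0)
        vy = c1 * vy + c2 * rng_dyn.normal(0.0, 1.0)
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy

        fx, fy = _force(pot_id, pp, x, y)
        s = 0.0
        if use_metad:
            s = x * costh + y * sinth
            if s < grid_min or s > grid_max:
                # runaway hill-surfing excursion: report, don't abort the ensemble
                return step, n_resets, CENSORED_GRID_EXIT, n_segments, exposure
            dvds = _interp(fgrid, grid_min, inv_dx, s)
            fx -= dvds * costh
            fy -= dvds * sinth
        fx *= kt_mech
        fy *= kt_mech
        vx += half * fx
        vy += half * fy

        seg_step += 1

        if record_segments:
            if use_metad:
                vb = _interp(vgrid, grid_min, inv_dx, s)
                if vb > _EXP_CLIP:
                    vb = _EXP_CLIP
                exposure += dt * math.exp(vb)
            else:
                exposure += dt

        # first passage wins over a same-step reset
        if _stop_hit(stop_mode, stop_a, stop_b, x):
            if record_segments:
                if n_segments >= seg_steps.shape[0]:
                    return step, n_resets, CENSORED_SEGMENT_OVERFLOW, n_segments, exposure
                seg_steps[n_segments] = seg_step
                seg_tau[n_segments] = exposure
                n_segments += 1
            return step, n_resets, NOT_CENSORED, n_segments, exposure

        if next_reset > 0 and seg_step >= next_reset:
            if record_segments:
                if n_segments >= seg_steps.shape[0]:
                    return step, n_resets, CENSORED_SEGMENT_OVERFLOW, n_segments, exposure
                seg_steps[n_segments] = seg_step
                seg_tau[n_segments] = exposure
                n_segments += 1
            # restart: position, velocities, bias, segment clocks
            x = x0
            y = y0
            vx = rng_vel.normal(0.0, sv)
            vy = rng_vel.normal(0.0, sv)
            if use_metad:
                vgrid[:] = 0.0
                fgrid[:] = 0.0
            n_resets += 1
            seg_step = 0
            exposure = 0.0
            if reset_mode == 1:
                next_reset = int(math.ceil(
                    rng_reset.exponential(1.0 / reset_rate_per_fs) / dt))
                if next_reset < 1:
                    next_reset = 1
            else:
                next_reset = reset_period_steps
            fx, fy = _force(pot_id, pp, x, y)
            fx *= kt_mech
            fy *= kt_mech
            # bias force is zero right after a reset (grids cleared)
            if _stop_hit(stop_mode, stop_a, stop_b, x):
                return step, n_resets, NOT_CENSORED, n_segments, 0.0
            continue

        if use_metad and seg_step % pace == 0:
            vb = _interp(vgrid, grid_min, inv_dx, s)
            h_dep = height * math.exp(-vb / (bias_factor - 1.0))
            _deposit(vgrid, fgrid, grid_min, dx, s, sigma, h_dep)
            # force changes discontinuously at deposition; next B uses it
            fx, fy = _force(pot_id, pp, x, y)
            dvds = _interp(fgrid, grid_min, inv_dx, s)
            fx = (fx - dvds * costh) * kt_mech
            fy = (fy - dvds * sinth) * kt_mech

    return max_steps, n_resets, CENSORED_MAX_STEPS, n_segments, exposure


@njit(cache=True, fastmath=True)
def sample_trajectory(
    x0, y0, vx0, vy0,
    dt, gamma, mass, kt_mech, n_steps, stride,
    pot_id, pp,
    use_metad, costh, sinth, height, sigma, bias_factor, pace,
    grid_min, grid_max, dx, vgrid, fgrid,
    rng_dyn,
):
    """Fixed-length run recording (x, y, vx, vy) every ``stride`` steps.

    Used by statistical-mechanics validation (equipartition, Einstein
    relation, Boltzmann histograms); no stopping, no resetting.
    """
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kt_mech / mass * (1.0 - c1 * c1))
    half = 0.5 * dt / mass
    inv_dx = 1.0 / dx

    n_out = n_steps // stride
    out = np.empty((n_out, 4))
    x = x0
    y = y0
    vx = vx0
    vy = vy0
    fx, fy = _force(pot_id, pp, x, y)
    if use_metad:
        s = x * costh + y * sinth
        dvds = _interp(fgrid, grid_min, inv_dx, s)
        fx -= dvds * costh
        fy -= dvds * sinth
    fx *= kt_mech
    fy *= kt_mech
    k = 0
    for step in range(1, n_steps + 1):
        vx += half * fx
        vy += half * fy
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        vx = c1 * vx + c2 * rng_dyn.normal(0.0, 1.0)
        vy = c1 * vy + c2 * rng_dyn.normal(0.0, 1.0)
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        fx, fy = _force(pot_id, pp, x, y)
        if use_metad:
            s = x * costh + y * sinth
            if s < grid_min or s > grid_max:
                raise ValueError("CV left the bias grid; widen the grid bounds")
            dvds = _interp(fgrid, grid_min, inv_dx, s)
            fx -= dvds * costh
            fy -= dvds * sinth
        fx *= kt_mech
        fy *= kt_mech
        vx += half * fx
        vy += half * fy
        if use_metad and step % pace == 0:
            s = x * costh + y * sinth
            vb = _interp(vgrid, grid_min, inv_dx, s)
            h_dep = height * math.exp(-vb / (bias_factor - 1.0))
            _deposit(vgrid, fgrid, grid_min, dx, s, sigma, h_dep)
            dvds = _interp(fgrid, grid_min, inv_dx, s)
            fxp, fyp = _force(pot_id, pp, x, y)
            fx = (fxp - dvds * costh) * kt_mech
            fy = (fyp - dvds * sinth) * kt_mech
        if step % stride == 0 and k < n_out:
            out[k, 0] = x
            out[k, 1] = y
            out[k, 2] = vx
            out[k, 3] = vy
            k += 1
    return out
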