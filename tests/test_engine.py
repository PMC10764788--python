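"""Langevin engine validation: units, equipartition, diffusion, resetting semantics."""

import math

import numpy as np
import pytest
import scipy.constants as const
import scipy.stats

import resetmetad as rm
from resetmetad import _kernels
from resetmetad.engine import (advance_step, apply_reset, init_state,
                               make_streams, run_trajectory, sample_velocities)
from resetmetad.metad import BiasState, CVSpec, MetaDConfig
from resetmetad.potentials import make_potential


@pytest.fixture(scope="module")
def harmonic():
    # 10 kBT/A^2 spring: position relaxation ~0.16 ps at the default thermostat,
    # so a 20 ns run holds ~6e4 independent position samples
    return make_potential("harmonic1d_test", {"k": 10.0})


def _run_samples(pot, thermo, n_steps, stride, seed, v0=(0.0, 0.0), x0=(0.0, 0.0)):
    empty = np.empty(0)
    rng = np.random.Generator(np.random.Philox(seed))
    return _kernels.sample_trajectory(
        x0[0], x0[1], v0[0], v0[1],
        thermo.dt, thermo.friction, thermo.mass, thermo.kbt_mech,
        n_steps, stride, pot.params.pot_id, pot.params.as_array(),
        False, 1.0, 0.0, 0.0, 1.0, 10.0, 1,
        -1.0, 1.0, 1.0, empty, empty, rng)


def test_mechanical_kbt_against_scipy_constants(thermo):
    """k_B*T converted to g*A^2/(fs^2*mol) via an independent unit chain."""
    # J/mol -> g A^2 fs^-2 mol^-1: 1 J = 1e3 g * 1e20 A^2 / 1e30 fs^2
    expected = const.k * 300.0 * const.Avogadro * 1e3 * 1e20 / 1e30
    assert thermo.kbt_mech == pytest.approx(expected, rel=1e-5)
    assert thermo.kbt_mech == pytest.approx(2.494e-4, rel=1e-3)


def test_maxwell_boltzmann_velocities(thermo):
    rng = np.random.default_rng(5)
    v = np.array([sample_velocities(thermo, rng) for _ in range(200_000)])
    target_var = thermo.kbt_mech / thermo.mass  # ~6.24e-6 (A/fs)^2
    for comp in range(2):
        se = math.sqrt(target_var / len(v))
        assert abs(v[:, comp].mean()) < 4 * se
        assert v[:, comp].var() == pytest.approx(target_var, rel=0.01)
    # determinism contract
    a = sample_velocities(thermo, np.random.default_rng(9))
    b = sample_velocities(thermo, np.random.default_rng(9))
    c = sample_velocities(thermo, np.random.default_rng(10))
    assert a == b and a != c


def test_equipartition_in_harmonic_well(harmonic, thermo):
    """Stationary variances: var(x) = kBT/k and var(vx) = kBT/m, within 2%."""
    out = _run_samples(harmonic, thermo, n_steps=20_000_000, stride=20, seed=42)
    burn = 1000  # discard >100 relaxation times
    x, vx = out[burn:, 0], out[burn:, 2]
    k_mech = 10.0 * thermo.kbt_mech
    assert x.var() == pytest.approx(thermo.kbt_mech / k_mech, rel=0.02)
    assert vx.var() == pytest.approx(thermo.kbt_mech / thermo.mass, rel=0.02)
    assert out[burn:, 1].var() == pytest.approx(thermo.kbt_mech / k_mech, rel=0.02)


def test_einstein_relation_free_particle(thermo):
    """Free diffusion: per-axis MSD(t) = 2 D t with D = kBT/(m*gamma), within 5%."""
    free = make_potential("harmonic1d_test", {"k": 0.0})
    t_steps = 100_000
    n_walkers = 1500
    disp = np.empty((n_walkers, 2))
    for i in range(n_walkers):
        out = _run_samples(free, thermo, n_steps=t_steps, stride=t_steps, seed=10_000 + i)
        disp[i] = out[-1, :2]
    D = thermo.kbt_mech / (thermo.mass * thermo.friction)  # ~6.24e-4 A^2/fs
    expected = 2.0 * D * t_steps * thermo.dt
    assert disp[:, 0].var() == pytest.approx(expected, rel=0.05)
    assert disp[:, 1].var() == pytest.approx(expected, rel=0.05)


def test_boltzmann_statistics_in_harmonic_well(harmonic, thermo):
    """Long-run positions are Boltzmann-distributed (chi^2 on a coarse grid)."""
    out = _run_samples(harmonic, thermo, n_steps=20_000_000, stride=1000, seed=8)
    x = out[10:, 0]  # samples 1 ps apart; position correlation time ~0.16 ps
    edges = np.linspace(-0.8, 0.8, 11)
    obs, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = np.exp(-harmonic.energy(centers, np.zeros_like(centers)))
    sd = math.sqrt(1.0 / 10.0)
    inside = scipy.stats.norm.cdf(0.8, scale=sd) - scipy.stats.norm.cdf(-0.8, scale=sd)
    p = p / p.sum() * 1.0
    n_in = obs.sum()
    chi2 = ((obs - n_in * p) ** 2 / (n_in * p)).sum()
    pval = scipy.stats.chi2.sf(chi2, df=len(obs) - 1)
    assert pval > 1e-3
    assert n_in / len(x) == pytest.approx(inside, abs=0.02)


def test_python_step_matches_jit_kernel(thermo):
    """The pure-Python BAOAB path reproduces the JIT kernel step-for-step."""
    pot = make_potential("two_wells")
    n = 2000
    # kernel trajectory (no stop: criterion far away)
    rng_dyn, rng_vel, _ = make_streams(314)
    out = _kernels.sample_trajectory(
        3.0, 0.0, *sample_velocities(thermo, rng_vel),
        thermo.dt, thermo.friction, thermo.mass, thermo.kbt_mech,
        n, 1, pot.params.pot_id, pot.params.as_array(),
        False, 1.0, 0.0, 0.0, 1.0, 10.0, 1, -1.0, 1.0, 1.0,
        np.empty(0), np.empty(0), rng_dyn)
    # python trajectory with identical streams
    rng_dyn2, rng_vel2, _ = make_streams(314)
    st = init_state(pot, thermo, (3.0, 0.0), rng_vel2)
    for i in range(n):
        advance_step(st, pot, thermo, rng_dyn2)
    np.testing.assert_allclose([st.x, st.y, st.vx, st.vy], out[-1], rtol=1e-12)


def test_poisson_reset_intervals_are_exponential(thermo):
    """Inter-reset intervals (from segment records on a no-transition setup)
    pass a KS test against Exp(rate) at n = 1e4."""
    pot = make_potential("harmonic1d_test", {"k": 1.0})
    stop = rm.StopCriterion.x_le(-1e9)  # never fires
    rate = 1.0e-3  # fs^-1 -> mean interval 1000 steps
    rec = run_trajectory(
        pot, thermo, stop, (0.0, 0.0), seed=99,
        schedule=rm.ResetSchedule.poisson(rate * 1e6),  # ns^-1
        max_steps=int(1.2e7), record_segments=True, segment_capacity=1 << 15)
    intervals = rec.segment_steps[:-1].astype(float)  # last segment cut by max_steps
    assert len(intervals) > 10_000
    # subtract half a step: intervals are exponential times rounded *up* to steps
    stat, pval = scipy.stats.kstest(intervals[:10_000] - 0.5, "expon",
                                    args=(0, 1.0 / rate))
    assert pval > 0.01


def test_sharp_reset_bookkeeping(thermo):
    """Censored no-transition run: n_resets = floor(elapsed / period)."""
    pot = make_potential("harmonic1d_test", {"k": 1.0})
    stop = rm.StopCriterion.x_le(-1e9)
    period_ns = 1e-3  # 1000 steps
    rec = run_trajectory(pot, thermo, stop, (0.0, 0.0), seed=1,
                         schedule=rm.ResetSchedule.sharp(period_ns),
                         max_steps=25_500)
    assert rec.censored == _kernels.CENSORED_MAX_STEPS
    assert rec.n_resets == 25_500 // 1000
    assert rec.fpt_steps == 25_500  # elapsed time tallied across resets


def test_stop_already_true_gives_zero_fpt(thermo):
    pot = make_potential("two_wells")
    rec = run_trajectory(pot, thermo, rm.StopCriterion.x_le(5.0), (3.0, 0.0), seed=4)
    assert rec.fpt_steps == 0 and rec.censored == 0


def test_trajectory_determinism(two_wells, thermo, tw_stop):
    a = run_trajectory(two_wells, thermo, tw_stop, (3.0, 0.0), seed=123)
    b = run_trajectory(two_wells, thermo, tw_stop, (3.0, 0.0), seed=123)
    c = run_trajectory(two_wells, thermo, tw_stop, (3.0, 0.0), seed=124)
    assert a.fpt_steps == b.fpt_steps
    assert a.fpt_steps != c.fpt_steps


def test_apply_reset_contracts(thermo):
    """Reset restores position, zeroes the bias, keeps the global clock."""
    pot = make_potential("two_wells")
    md = MetaDConfig(pace=10, sigma=1.3, grid_min=-50, grid_max=50)
    bias = BiasState(md, CVSpec(0.0))
    bias.deposit_hill(3.0)
    bias.deposit_hill(2.0)
    assert bias.bias_energy(3.0) > 0
    rng_dyn, rng_vel, _ = make_streams(77)
    st = init_state(pot, thermo, (3.0, 0.0), rng_vel, bias=bias)
    for _ in range(50):
        advance_step(st, pot, thermo, rng_dyn, bias=bias)
    elapsed_before = st.elapsed_steps
    apply_reset(st, pot, thermo, (3.0, 0.0), rng_vel, bias=bias)
    assert (st.x, st.y) == (3.0, 0.0)
    assert st.elapsed_steps == elapsed_before       # overall tally untouched
    assert st.segment_steps == 0 and st.n_resets == 1
    assert np.all(bias.vgrid == 0) and not bias.hills


def test_unbiased_two_wells_cov_near_reference(tw_baseline):
    """Unbiased FPT ensemble is broad: COV ~ 1 (slightly above)."""
    s = rm.summarize(tw_baseline)
    assert 0.85 < s["cov"] < 1.35


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        rm.ThermoConfig(dt=-1.0)
    with pytest.raises(ValueError):
        rm.ResetSchedule("poisson", rate=0.0)
    with pytest.raises(ValueError):
        rm.ResetSchedule("sharp", period=-2.0)
    with pytest.raises(ValueError):
        rm.StopCriterion.x_between(2.0, 1.0)
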