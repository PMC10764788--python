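"""Configuration-driven experiment runner and synthetic FPT ensembles.

An :class:`ExperimentConfig` bundles everything that defines one set of
simulations -- potential, thermostat, collective variable, metadynamics
parameters, resetting schedule, stop criterion, trajectory count and base
seed -- and is YAML round-trippable.  Re-running the same config with the
same seed reproduces every output bit for bit: per-trajectory seeds are
spawned from the base seed with numpy's SeedSequence, so trajectory j is
reproducible in isolation.

``replicate_figure`` reruns the published model-system sweeps (resetting-
rate scans, bias-rate scans, CV-rotation scans) at a configurable fraction
of the original 10^4 trajectories per point.  ``synthesize_fpt_ensemble``
draws FPT samples from analytic distributions with known mean and COV, for
exercising the statistics layer without any simulation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import (ResetSchedule, StopCriterion, ThermoConfig,
                     TrajectoryRecord, run_trajectory)
from .fpt import (FPTEnsemble, ensemble_from_records, speedup, summarize,
                  write_fpt_table)
from .metad import CVSpec, MetaDConfig, pace_from_bias_rate
from .potentials import Potential2D, make_potential
from .units import FS_PER_NS

__all__ = [
    "ExperimentConfig", "SyntheticEnsembleSpec", "run_ensemble",
    "run_experiment", "replicate_figure", "synthesize_fpt_ensemble",
    "FIGURES",
]

#: trajectories per point in the published sweeps
FULL_SCALE_N = 10_000
DEFAULT_SCALE = 0.02


def run_ensemble(
    potential: Potential2D,
    thermo: ThermoConfig,
    stop: StopCriterion,
    init_position: tuple[float, float],
    n_traj: int,
    seed,
    schedule: ResetSchedule | None = None,
    cv: CVSpec | None = None,
    metad: MetaDConfig | None = None,
    max_steps: int = 10 ** 9,
    record_segments: bool = False,
) -> list[TrajectoryRecord]:
    """Run ``n_traj`` independent trajectories with per-trajectory derived seeds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grids = None
    if metad is not None:
        grids = (np.zeros(metad.n_grid), np.zeros(metad.n_grid))
    records = []
    for j, child in enumerate(ss.spawn(n_traj)):
        records.append(run_trajectory(
            potential, thermo, stop, init_position, child,
            schedule=schedule, cv=cv, metad=metad, max_steps=max_steps,
            record_segments=record_segments, traj_id=j, _grids=grids))
    return records


@dataclass(frozen=True)
class ExperimentConfig:
    """Full, serialisable description of one simulation ensemble."""

    potential: str = "two_wells"
    potential_overrides: dict = field(default_factory=dict)
    temperature: float = 300.0
    mass: float = 40.0
    friction: float = 0.01
    dt: float = 1.0
    init_position: tuple[float, float] = (3.0, 0.0)
    stop_mode: str = "x_le"
    stop_a: float = -3.0
    stop_b: float = 0.0
    cv_theta: float = 0.0
    metad: bool = False
    bias_height: float = 0.5
    bias_sigma: float = 1.3
    bias_factor: float = 10.0
    bias_rate_per_ns: float = 1e4
    grid_min: float = -400.0
    grid_max: float = 400.0
    grid_spacing: float = 0.01
    reset_mode: str = "none"
    reset_rate_per_ns: float = 0.0
    reset_period_ns: float = 0.0
    n_trajectories: int = 100
    seed: int = 0
    max_steps: int = 10 ** 9
    record_segments: bool = False

    # -- builders -----------------------------------------------------------

    def build(self) -> dict:
        """Materialise the config into engine objects."""
        thermo = ThermoConfig(temperature=self.temperature, mass=self.mass,
                              friction=self.friction, dt=self.dt)
        stop = StopCriterion(self.stop_mode, self.stop_a, self.stop_b)
        schedule = ResetSchedule(self.reset_mode, rate=self.reset_rate_per_ns,
                                 period=self.reset_period_ns)
        metad = None
        cv = None
        if self.metad:
            metad = MetaDConfig(height=self.bias_height, sigma=self.bias_sigma,
                                bias_factor=self.bias_factor,
                                pace=pace_from_bias_rate(self.bias_rate_per_ns, self.dt),
                                grid_min=self.grid_min, grid_max=self.grid_max,
                                grid_spacing=self.grid_spacing)
            cv = CVSpec(theta=self.cv_theta)
        return {
            "potential": make_potential(self.potential, self.potential_overrides),
            "thermo": thermo, "stop": stop, "schedule": schedule,
            "metad": metad, "cv": cv,
        }

    # -- (de)serialisation --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["init_position"] = list(d["init_position"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "init_position" in d:
            d["init_position"] = tuple(d["init_position"])
        return cls(**d)


def run_experiment(config: ExperimentConfig, out_dir=None,
                   seed: int | None = None) -> tuple[list[TrajectoryRecord], dict]:
    """Run one configured ensemble; optionally write table + summary to disk."""
    parts = config.build()
    base_seed = config.seed if seed is None else seed
    records = run_ensemble(
        parts["potential"], parts["thermo"], parts["stop"],
        config.init_position, config.n_trajectories, base_seed,
        schedule=parts["schedule"], cv=parts["cv"], metad=parts["metad"],
        max_steps=config.max_steps, record_segments=config.record_segments)
    ensemble = ensemble_from_records(records, dt_fs=config.dt)
    summary = summarize(ensemble)
    summary["seed"] = base_seed
    summary["config_potential"] = config.potential

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fpt_table(out / "fpt.tsv", records)
        config.to_yaml(out / "config.yaml")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if config.record_segments:
            rows = []
            for rec in records:
                for k in range(len(rec.segment_steps)):
                    rows.append((rec.traj_id, k, int(rec.segment_steps[k]),
                                 rec.segment_tau_fs[k]))
            pd.DataFrame(rows, columns=["traj_id", "seg_index", "steps",
                                        "rescaled_fs"]).to_csv(
                out / "segments.tsv", sep="\t", index=False)
    return records, summary


# --- published model-system sweeps ----------------------------------------

_TW = dict(potential="two_wells", stop_mode="x_le", stop_a=-3.0,
           init_position=(3.0, 0.0), bias_sigma=1.3)
_FE = dict(potential="faradjian_elber", stop_mode="x_lt", stop_a=-1.0,
           init_position=(3.0, 0.0), bias_sigma=0.15)

FIGURES = {
    # SR-only resetting-rate sweep on the two wells model
    "fig1b": dict(system=_TW, kind="sr_sweep",
                  rates=[5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 500.0]),
    # MetaD-only bias-deposition-rate sweep
    "fig1c": dict(system=_TW, kind="bias_sweep",
                  bias_rates=[20.0, 100.0, 1e3, 1e4]),
    # MetaD at 1e4 hills/ns + SR rate sweep
    "fig1d": dict(system=_TW, kind="metad_sr_sweep", bias_rate=1e4,
                  rates=[10.0, 30.0, 60.0, 125.0, 250.0, 500.0, 1000.0]),
    # COV and predicted-vs-simulated additional speedup at two bias rates
    "fig2": dict(system=_TW, kind="cov_and_predict", bias_rates=[20.0, 1e4],
                 rates=[10.0, 30.0, 60.0, 125.0, 250.0, 500.0]),
    # CV-rotation sweep on the Faradjian-Elber potential, with/without SR
    "fig3c": dict(system=_FE, kind="rotation_sweep", bias_rate=1e4,
                  sin_thetas=[0.0, 0.1, 0.2, 0.3, 0.407]),
}


def replicate_figure(name: str, scale: float = DEFAULT_SCALE, seed: int = 0,
                     out_dir=None, baseline: FPTEnsemble | None = None
                     ) -> pd.DataFrame:
    """Rerun one of the published model-system sweeps at reduced scale.

    ``scale`` multiplies the published 10^4 trajectories per point (at least
    4 are always run).  If ``baseline`` (an unbiased ensemble for the same
    system) is not given, it is simulated first at the same scale.
    Returns a tidy DataFrame; also written as TSV when ``out_dir`` is set.
    """
    if name not in FIGURES:
        raise ValueError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    spec = FIGURES[name]
    n = max(4, round(scale * FULL_SCALE_N))
    sys_kw = spec["system"]
    base_cfg = ExperimentConfig(n_trajectories=n, seed=seed, **sys_kw)
    ss = np.random.SeedSequence(seed)
    s_base, s_sweep = ss.spawn(2)

    if baseline is None:
        parts = base_cfg.build()
        base_records = run_ensemble(parts["potential"], parts["thermo"],
                                    parts["stop"], base_cfg.init_position, n, s_base)
        baseline = ensemble_from_records(base_records, dt_fs=base_cfg.dt)

    rows = []
    kind = spec["kind"]

    def one(cfg: ExperimentConfig, child) -> FPTEnsemble:
        parts = cfg.build()
        recs = run_ensemble(parts["potential"], parts["thermo"], parts["stop"],
                            cfg.init_position, n, child,
                            schedule=parts["schedule"], cv=parts["cv"],
                            metad=parts["metad"], max_steps=10 ** 8)
        return ensemble_from_records(recs, dt_fs=cfg.dt)

    if kind == "sr_sweep":
        children = s_sweep.spawn(len(spec["rates"]))
        for rate, child in zip(spec["rates"], children):
            cfg = dataclasses.replace(base_cfg, reset_mode="poisson",
                                      reset_rate_per_ns=rate)
            ens = one(cfg, child)
            sp = speedup(baseline, ens)
            rows.append(dict(reset_rate_per_ns=rate, **summarize(ens),
                             speedup=sp["speedup"], speedup_sem=sp["sem"]))
    elif kind == "bias_sweep":
        children = s_sweep.spawn(len(spec["bias_rates"]))
        for br, child in zip(spec["bias_rates"], children):
            cfg = dataclasses.replace(base_cfg, metad=True, bias_rate_per_ns=br)
            ens = one(cfg, child)
            sp = speedup(baseline, ens)
            rows.append(dict(bias_rate_per_ns=br, **summarize(ens),
                             speedup=sp["speedup"], speedup_sem=sp["sem"]))
    elif kind == "metad_sr_sweep":
        children = s_sweep.spawn(len(spec["rates"]))
        for rate, child in zip(spec["rates"], children):
            cfg = dataclasses.replace(base_cfg, metad=True,
                                      bias_rate_per_ns=spec["bias_rate"],
                                      reset_mode="poisson", reset_rate_per_ns=rate)
            ens = one(cfg, child)
            sp = speedup(baseline, ens)
            rows.append(dict(reset_rate_per_ns=rate,
                             bias_rate_per_ns=spec["bias_rate"], **summarize(ens),
                             speedup=sp["speedup"], speedup_sem=sp["sem"]))
    elif kind == "cov_and_predict":
        pairs = [(br, r) for br in spec["bias_rates"] for r in [0.0] + spec["rates"]]
        children = s_sweep.spawn(len(pairs))
        for (br, rate), child in zip(pairs, children):
            cfg = dataclasses.replace(
                base_cfg, metad=True, bias_rate_per_ns=br,
                reset_mode="none" if rate == 0 else "poisson",
                reset_rate_per_ns=rate)
            ens = one(cfg, child)
            rows.append(dict(bias_rate_per_ns=br, reset_rate_per_ns=rate,
                             **summarize(ens)))
    elif kind == "rotation_sweep":
        children = s_sweep.spawn(2 * len(spec["sin_thetas"]))
        from .fpt import speedup_curve
        for i, sin_t in enumerate(spec["sin_thetas"]):
            theta = math.asin(sin_t)
            cfg = dataclasses.replace(base_cfg, metad=True, cv_theta=theta,
                                      bias_rate_per_ns=spec["bias_rate"])
            ens = one(cfg, children[2 * i])
            sp = speedup(baseline, ens)
            rows.append(dict(sin_theta=sin_t, sr="none", **summarize(ens),
                             speedup=sp["speedup"], speedup_sem=sp["sem"]))
            # optimal-SR branch: rate picked by the renewal predictor
            r_star = speedup_curve(ens).r_star
            if r_star > 0:
                cfg_sr = dataclasses.replace(cfg, reset_mode="poisson",
                                             reset_rate_per_ns=r_star)
                ens_sr = one(cfg_sr, children[2 * i + 1])
                sp = speedup(baseline, ens_sr)
            rows.append(dict(sin_theta=sin_t, sr="optimal", reset_rate_per_ns=r_star,
                             **summarize(ens_sr if r_star > 0 else ens),
                             speedup=sp["speedup"], speedup_sem=sp["sem"]))

    df = pd.DataFrame(rows)
    df.insert(0, "figure", name)
    df.insert(1, "n_per_point", n)
    df.insert(2, "scale", scale)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest = dict(figure=name, scale=scale, n_per_point=n, seed=seed,
                        rng="numpy SeedSequence -> Philox, 3 streams/trajectory")
        with open(out / f"{name}.manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return df


# --- synthetic ensembles ---------------------------------------------------

@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Analytic FPT distribution for statistics-layer tests.

    Families and parameters:
      exponential:  rate (ns^-1); mean 1/rate, COV 1
      deterministic: tau0 (ns); COV 0
      lognormal:    mu, sigma of log; COV = sqrt(exp(sigma^2) - 1)
      two_exponential_mixture: weight w on rate1, (1-w) on rate2
    """

    family: str
    n: int
    seed: int = 0
    rate: float = 1.0
    tau0: float = 1.0
    mu: float = 0.0
    sigma: float = 1.0
    w: float = 0.5
    rate1: float = 1.0
    rate2: float = 1.0

    _FAMILIES = ("exponential", "deterministic", "lognormal",
                 "two_exponential_mixture")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {self._FAMILIES}")
        if self.n < 1:
            raise ValueError("need n >= 1 samples")

    def analytic_mean(self) -> float:
        if self.family == "exponential":
            return 1.0 / self.rate
        if self.family == "deterministic":
            return self.tau0
        if self.family == "lognormal":
            return math.exp(self.mu + self.sigma ** 2 / 2)
        return self.w / self.rate1 + (1 - self.w) / self.rate2

    def analytic_cov(self) -> float:
        if self.family == "exponential":
            return 1.0
        if self.family == "deterministic":
            return 0.0
        if self.family == "lognormal":
            return math.sqrt(math.exp(self.sigma ** 2) - 1.0)
        m = self.analytic_mean()
        m2 = 2 * (self.w / self.rate1 ** 2 + (1 - self.w) / self.rate2 ** 2)
        return math.sqrt(m2 - m * m) / m


def synthesize_fpt_ensemble(spec: SyntheticEnsembleSpec) -> FPTEnsemble:
    """Draw a seeded synthetic FPT ensemble (times in ns)."""
    rng = np.random.default_rng(spec.seed)
    if spec.family == "exponential":
        samples = rng.exponential(1.0 / spec.rate, spec.n)
    elif spec.family == "deterministic":
        samples = np.full(spec.n, spec.tau0)
    elif spec.family == "lognormal":
        samples = rng.lognormal(spec.mu, spec.sigma, spec.n)
    else:
        pick = rng.random(spec.n) < spec.w
        samples = np.where(pick, rng.exponential(1.0 / spec.rate1, spec.n),
                           rng.exponential(1.0 / spec.rate2, spec.n))
    return FPTEnsemble(samples_ns=samples,
                       metadata={"synthetic": True,
                                 "family": spec.family,
                                 "analytic_mean_ns": spec.analytic_mean(),
                                 "analytic_cov": spec.analytic_cov()})
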