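"""Unbiased Langevin first-passage sampling on the two-wells model.

Runs a small ensemble of trajectories from the fixed start (3, 0) A until
x <= -3 A and reports the mean first-passage time (MFPT), its standard
error, and the coefficient of variation (COV).  At full statistics the MFPT
is ~7.5 ns and the COV is ~1.05; COV > 1 means a small resetting rate is
guaranteed to accelerate the process.  (~40 s)
"""

import resetmetad as rm
from resetmetad.experiments import run_ensemble
from resetmetad.fpt import ensemble_from_records, summarize

pot = rm.make_potential("two_wells")
thermo = rm.ThermoConfig()          # 300 K, argon-like mass, gamma=0.01/fs, dt=1 fs
stop = rm.StopCriterion.x_le(-3.0)

records = run_ensemble(pot, thermo, stop, (3.0, 0.0), n_traj=150, seed=0)
s = summarize(ensemble_from_records(records))
print(f"n = {s['n']} trajectories")
print(f"MFPT = {s['mfpt_ns']:.2f} +- {s['sem_ns']:.2f} ns   (published scale: ~7.5 ns)")
print(f"COV  = {s['cov']:.2f}   (full-statistics value ~1.05; COV > 1 means a"
      f" small resetting rate is guaranteed to help)")
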