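"""Predict the resetting speedup curve from resetting-free samples.

The renewal identity <tau>_r = (1 - f(r)) / (r f(r)), with f(r) the
empirical Laplace transform of the first-passage times, turns ONE ensemble
simulated without resetting into the whole speedup-vs-rate curve.  Here we
verify it against direct simulations with Poisson resetting.  (~60 s)
"""

import numpy as np

import resetmetad as rm
from resetmetad.experiments import run_ensemble
from resetmetad.fpt import (ensemble_from_records, mfpt_under_resetting,
                            speedup_curve, summarize)

pot = rm.make_potential("two_wells")
thermo = rm.ThermoConfig()
stop = rm.StopCriterion.x_le(-3.0)

base = ensemble_from_records(
    run_ensemble(pot, thermo, stop, (3.0, 0.0), 150, seed=1))
curve = speedup_curve(base, rates=np.logspace(0, 3, 40))
print(f"no-resetting MFPT: {summarize(base)['mfpt_ns']:.2f} ns, "
      f"COV {curve.cov:.2f}")
print(f"predicted optimal rate r* = {curve.r_star:.0f} /ns, "
      f"max speedup {curve.max_speedup:.1f}  (published scale: ~4 at 50/ns)")

print("\nrate (1/ns)   predicted MFPT   simulated MFPT")
for rate in [25.0, 50.0, 100.0]:
    sim = ensemble_from_records(run_ensemble(
        pot, thermo, stop, (3.0, 0.0), 100, seed=int(rate),
        schedule=rm.ResetSchedule.poisson(rate), max_steps=10 ** 8))
    print(f"{rate:8.0f}    {mfpt_under_resetting(base, rate):10.2f} ns"
          f"    {summarize(sim)['mfpt_ns']:10.2f} ns")
print("\nThe prediction uses only the resetting-free samples; agreement with"
      "\nthe direct resetting simulations is the point.")
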