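"""Combine well-tempered metadynamics with stochastic resetting.

MetaD along the optimal CV (the x-coordinate) accelerates the two-wells
transition ~20x at the fastest published deposition pace; zeroing the bias
at Poisson resets and restarting from the initial state multiplies that to
~130x at the optimal resetting rate.  (~30 s)
"""

import resetmetad as rm
from resetmetad.experiments import run_ensemble
from resetmetad.fpt import ensemble_from_records, speedup, summarize

pot = rm.make_potential("two_wells")
thermo = rm.ThermoConfig()
stop = rm.StopCriterion.x_le(-3.0)
metad = rm.MetaDConfig(pace=100, sigma=1.3)   # 10^4 hills/ns, 0.5 kBT, gamma_B=10

base = ensemble_from_records(
    run_ensemble(pot, thermo, stop, (3.0, 0.0), 120, seed=2))
print(f"unbiased MFPT: {summarize(base)['mfpt_ns']:.2f} ns")

md_only = ensemble_from_records(run_ensemble(
    pot, thermo, stop, (3.0, 0.0), 200, seed=3,
    cv=rm.CVSpec(0.0), metad=metad, max_steps=10 ** 8))
sp = speedup(base, md_only)
print(f"MetaD only:     speedup {sp['speedup']:6.1f} +- {sp['sem']:.1f}"
      f"   (published scale ~20)")

for rate in [60.0, 125.0, 250.0]:
    combined = ensemble_from_records(run_ensemble(
        pot, thermo, stop, (3.0, 0.0), 200, seed=int(10 + rate),
        schedule=rm.ResetSchedule.poisson(rate),
        cv=rm.CVSpec(0.0), metad=metad, max_steps=10 ** 8))
    sp = speedup(base, combined)
    print(f"MetaD+SR {rate:4.0f}/ns: speedup {sp['speedup']:6.1f} +- {sp['sem']:.1f}")
print("(published scale: max ~130 at 125/ns -- resetting helps even with the"
      "\n optimal CV, because fast deposition broadens the FPT distribution)")
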