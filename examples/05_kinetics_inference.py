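"""Infer the unbiased MFPT from metadynamics trajectories with sharp resetting.

Between resets the trajectory is an ordinary infrequent-MetaD run and the
bias is zeroed at each reset, so segments are independent.  Each segment's
duration is rescaled by the exposure integral sum dt*exp(V_bias); segments
ending by reset are right-censored.  A Kaplan-Meier survival estimate over
the rescaled times, fitted with S(t) = exp(-kt) at short times, recovers
the unbiased rate.  (~90 s)
"""

import resetmetad as rm
from resetmetad.experiments import run_ensemble
from resetmetad.fpt import ensemble_from_records, summarize
from resetmetad.inference import infer_mfpt, prediction_error

pot = rm.make_potential("two_wells")
thermo = rm.ThermoConfig()
stop = rm.StopCriterion.x_le(-3.0)

# reference truth from unbiased simulation
base = ensemble_from_records(
    run_ensemble(pot, thermo, stop, (3.0, 0.0), 100, seed=4))
tau_true = summarize(base)["mfpt_ns"]
print(f"unbiased reference MFPT: {tau_true:.2f} ns")

# iMetaD + sharp resetting: slow-ish deposition, 0.5 ns resetting period
metad = rm.MetaDConfig(pace=20_000, sigma=1.3)   # 50 hills/ns
records = run_ensemble(
    pot, thermo, stop, (3.0, 0.0), 150, seed=5,
    schedule=rm.ResetSchedule.sharp(0.5), cv=rm.CVSpec(0.0), metad=metad,
    max_steps=10 ** 8, record_segments=True)
biased = summarize(ensemble_from_records(records))
print(f"biased MFPT {biased['mfpt_ns']:.2f} ns "
      f"-> speedup {tau_true / biased['mfpt_ns']:.1f}")

res = infer_mfpt(records, dt_fs=thermo.dt)
err = prediction_error(tau_true, res.tau_est_ns)
print(f"inferred unbiased MFPT: {res.tau_est_ns:.2f} ns "
      f"(fit R^2 {res.r_squared:.3f}, KS score {res.ks_score:.3f})")
print(f"prediction error |true - est|/true = {err:.2f}")
print("\nThe biased simulations are several times faster than the unbiased"
      "\nreference, yet the survival fit recovers its MFPT; the R^2/KS scores"
      "\nflag when over-deposition makes the estimate unreliable.")
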