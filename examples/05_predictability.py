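"""Internal predictability: how well does the model predict exposure?

The Level-A correlation is judged by percent prediction error (%PE) on
AUC and Cmax: the average absolute %PE across doses must not exceed 10%
and no single dose may exceed 15%.  Here the model predicts a study it
itself generated, using each subject's individual parameters.  Note that
Cmax is a single noisy sample, so residual assay error alone pushes its
%PE well above the AUC values.
"""

from ivring.evaluation import internal_predictability
from ivring.population import Arm, simulate_study
from ivring.synthetic import SERUM_SCHEDULE_H, VITRO_PARAMS, default_population

pop = default_population()
arms = [Arm(dose=d, batch=b, n=10, vitro=VITRO_PARAMS[d])
        for d, b in [(125.0, "A"), (375.0, "B"), (750.0, "C"), (1500.0, "D")]]
study = simulate_study(pop, arms, SERUM_SCHEDULE_H, rng_seed=21)

report = internal_predictability(study, pop, VITRO_PARAMS)
print("absolute %PE on AUC(0-t), per dose then averaged:")
print(report.auc_pe.round(2).to_string())
print("\nabsolute %PE on Cmax:")
print(report.cmax_pe.round(2).to_string())
print(f"\nFDA criteria: AUC pass = {report.auc_pass}, Cmax pass = {report.cmax_pass}")
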