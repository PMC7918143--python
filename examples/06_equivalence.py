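"""Batch comparison (f1/f2) and a virtual bioequivalence trial.

Two release batches are compared in vitro by the FDA difference and
similarity factors (pass: f1 <= 15 and f2 >= 50), and in silico by
simulating a parallel two-arm trial and testing whether the 90% CI of the
AUC ratio F falls inside the 0.80-1.25 bioequivalence range.
"""

import numpy as np

from ivring.equivalence import compare_batches, virtual_be_trial
from ivring.release import InVitroReleaseParams, eval_cumulative_vitro
from ivring.synthetic import VITRO_PARAMS, default_population

ref = VITRO_PARAMS[375.0]
# a candidate batch with slightly slower release phases
test = InVitroReleaseParams(dose=ref.dose, P0=ref.P0, A=ref.A,
                            alpha=0.93 * ref.alpha, beta=0.93 * ref.beta)

t = np.arange(24.0, 361.0, 24.0)
cmp = compare_batches(eval_cumulative_vitro(ref, t)[None, :],
                      eval_cumulative_vitro(test, t)[None, :])
print(f"in vitro: f1 = {cmp.f1:.2f} (pass <= 15), f2 = {cmp.f2:.2f} (pass >= 50)"
      f" -> {'similar' if cmp.passes else 'not similar'}")

pop = default_population()
be = virtual_be_trial(pop, ref, test, n_per_arm=200, rng_seed=31)
lo, hi = be.ci90
print(f"virtual BE: F = {be.F:.3f}, 90% CI [{lo:.3f}, {hi:.3f}]"
      f" -> {'bioequivalent' if be.passes else 'not bioequivalent'}")
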