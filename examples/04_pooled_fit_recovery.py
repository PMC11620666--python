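"""Recover population parameters from simulated profiles by naive-pooled fit.

Simulates noise-free single-dose profiles for three subjects with different
weights and renal function, then refits the structural parameters by pooled
least squares on log concentrations starting from deliberately wrong values.
"""

import numpy as np
from dataclasses import replace

from dialypk import (
    CovariateSet,
    DoseEvent,
    EventSchedule,
    default_fixed_effects,
    derive_individual_parameters,
    fit_pooled,
    simulate_profile,
)

truth = default_fixed_effects()
schedule = EventSchedule(doses=(DoseEvent(0.0, 123.0),))
times = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48, 72], dtype=float)

data = []
for weight, egfr in [(70, 90), (60, 50), (80, 110)]:
    cov = CovariateSet(weight=weight, egfr=egfr)
    ind = derive_individual_parameters(truth, cov)
    data.append((simulate_profile(ind, schedule, times).profile, schedule, cov))

init = replace(truth, cl=12.0, v2=28.0, q=4.0, v3=18.0, ka_intercept=0.5)
fit = fit_pooled(data, init)

print(f"converged in {fit.n_iterations} evaluations, "
      f"residual cost {fit.cost:.2e} ({fit.n_obs} observations)")
for name in ("cl", "v2", "q", "v3", "ka_intercept"):
    est, tru = getattr(fit.estimate, name), getattr(truth, name)
    print(f"  {name:13s} estimate {est:8.4f}  truth {tru:8.4f}  "
          f"rel err {abs(est - tru) / tru:.2e}")
# Noise-free data: every structural parameter returns to the truth, which is
# the identifiability check behind the simulator's parameterisation.
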