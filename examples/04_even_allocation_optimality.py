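"""Even allocations win: simplex path and stochastic gradient ascent.

First evaluates the expected utility along the one-dimensional path that
chains the even points t1e -> t2e -> ... -> t10e (each even point is a
critical point by symmetry) and reports where the best symmetric point sits.
Then runs projected stochastic gradient ascent from random allocations in a
20-dimensional simplex and shows the allocation in use becoming even (the
coefficient of variation of the active coordinates goes to zero).
"""

import numpy as np

from breadthdepth import (
    CapacityParams,
    PriorSpec,
    simplex_path_utilities,
    stochastic_gradient_ascent,
)

prior = PriorSpec.gaussian(0.5, 1.0)
params = CapacityParams(T=0.1, sigma=1.0)  # capacity C = 0.1

profile = simplex_path_utilities(prior, params, range(1, 10))
print("even-point utilities along the path:")
for m, u in sorted(profile.symmetric_utility.items()):
    mark = "  <-- best symmetric point" if m == profile.best_m else ""
    print(f"  t{m}e: U = {u:.5f}{mark}")

print("\nprojected stochastic gradient ascent, 3 random starts (dims=20):")
for seed in range(3):
    tr = stochastic_gradient_ascent(prior, params, dims=20, seed=seed,
                                    steps=600, batch=10_000)
    print(f"  seed {seed}: {len(tr.cv)} steps, active options "
          f"{tr.final_active_count}, CV(active) {tr.cv_active[-1]:.3f}, "
          f"U = {tr.utilities[-1].value:.5f} +- {tr.utilities[-1].stderr:.5f}")

print("\nEvery run concentrates the budget on a handful of options and splits")
print("it evenly among them (CV near zero), matching the best even breadth.")
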