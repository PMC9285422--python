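"""The breadth-depth tradeoff: expected utility versus number of sampled options.

For a fixed capacity the utility starts at the prior mean (M=1: no choice),
rises to an interior maximum, and decays back toward the prior mean as the
budget is spread too thin. At small capacity the maximum sits at M=5.
"""

import numpy as np

from breadthdepth import CapacityParams, PriorSpec, expected_utility_even

prior = PriorSpec.gaussian(0.5, 1.0)
ms = [1, 2, 3, 4, 5, 6, 8, 12, 20, 50, 200]

for C in (0.1, 10.0):
    params = CapacityParams.for_prior(prior, C=C)
    us = [expected_utility_even(prior, M, params).value for M in ms]
    best = ms[int(np.argmax(us))]
    print(f"\ncapacity C={C}")
    for M, u in zip(ms, us):
        marker = "  <-- optimum" if M == best else ""
        print(f"  M={M:4d}  U={u:.5f}{marker}")

print("\nU is the expected drift of the chosen option; 0.5 would be obtained")
print("by picking blindly. The optimum shifts right as capacity grows.")
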