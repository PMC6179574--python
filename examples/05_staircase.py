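"""Adaptive probe-jitter staircase: convergence to ~80% correct.

The staircase starts at 15 deg, moves up 1 deg after an error and down
0.5488 deg after two consecutive correct responses.  A stochastic observer
with a cumulative-Gaussian psychometric function is driven through 20,000
trials; the asymptotic percent correct matches the pair-approximation
equilibrium sqrt(1/1.5488) ~= 80.4%.
"""

import numpy as np
from scipy.stats import norm

from gazedecode import equilibrium_p_correct, simulate_observer

def psychometric(jitter):
    return 0.5 + 0.5 * norm.cdf((jitter - 8.0) / 3.0)

res = simulate_observer(psychometric, 20000, seed=0)
tail = res.jitter_trace[res.burn_in:]

print(f"theoretical equilibrium:   {100 * equilibrium_p_correct():.2f}% correct")
print(f"simulated (last 10k):      {100 * res.proportion_correct:.2f}% correct")
print(f"jitter at equilibrium:     {tail.mean():.2f} +/- {tail.std():.2f} deg")
print(f"observer's 80.4%-point:    "
      f"{8.0 + 3.0 * norm.ppf(2 * equilibrium_p_correct() - 1):.2f} deg")

# The staircase parks the jitter where the observer's psychometric function
# crosses the equilibrium percent-correct, whatever the starting value.
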