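"""Cluster-based sign-flip permutation test on decoding time courses.

Simulates a small cohort whose decoding profiles carry an effect confined to
a known time window, and shows that the cluster test recovers that window
while controlling false positives elsewhere.
"""

import numpy as np

from gazedecode import cluster_permutation_test

rng = np.random.default_rng(0)
times = np.linspace(-0.2, 3.0, 65)
effect = (times >= 0.5) & (times <= 1.5)       # true effect window

chance = 1.0 / 3.0
maps = chance + 0.04 * rng.standard_normal((10, len(times)))
maps[:, effect] += 0.08                        # ~8 points above chance there

result = cluster_permutation_test(maps, chance=chance, n_perm=2000, seed=1)
print(f"{len(result.clusters)} cluster(s); "
      f"{result.n_permutations} permutations")
for c in result.clusters:
    span = times[c.mask]
    print(f"  sign {c.sign:+d}, mass {c.mass:8.2f}, p = {c.p_value:.4f}, "
          f"extent {span.min():.2f}..{span.max():.2f} s")

sig = result.significant(sign=+1)
print(f"\nsignificant positive clusters: {len(sig)} "
      f"(true effect window 0.50..1.50 s)")
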