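"""Why the burn-in is 200 host generations.

Under neutral (uniform-fitness) reproduction the host population is a
haploid Wright-Fisher model, and the whole population traces its
ancestry to a single founder after about 2 N generations.  With
N_H = 100 hosts that is ~200 generations — the burn-in length used so
microbial communities stabilize before environmental change begins.
"""

import numpy as np

from holosim import mean_neutral_coalescence_time

rng = np.random.default_rng(1)
for n in (25, 50, 100):
    mean = mean_neutral_coalescence_time(n, 300, rng)
    print(f"N_H = {n:>3}: mean generations to a single founder = {mean:6.1f} "
          f"(~2N = {2 * n})")
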