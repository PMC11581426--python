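"""Count fluorophores per supercomplex by stepwise photobleaching.

Generates a population of bleaching traces whose planted stoichiometry
follows the 63/24/13% (one/two/more) pattern typical of scaffold-protein
supercomplexes, runs the Chung-Kennedy filter + t-statistic step counter
on every trace, and compares the recovered distribution with the truth.
"""

import numpy as np

from smx import count_steps_batch, generate_trace_set, stoichiometry_distribution

pairs = generate_trace_set(
    stoichiometry_weights=(0.63, 0.24, 0.13),  # P(1), P(2), P(>2) fluorophores
    n_traces=5000,
    noise_sd=50.0,                             # SNR 20 at 1000-count steps
    seed=42,
)
traces = np.array([trace for trace, _ in pairs])
fits = count_steps_batch(traces, window=12, peak_threshold=75.0, t_threshold=0.1)

hist, mean_steps = stoichiometry_distribution(fits)
n = len(fits)
planted = np.bincount([t.n_steps for _, t in pairs], minlength=4)[1:4]

print(f"traces analyzed: {n}")
print(f"recovered counts  1: {hist.get(1, 0)}  2: {hist.get(2, 0)}  "
      f">2: {sum(v for k, v in hist.items() if k >= 3)}")
print(f"planted counts    1: {planted[0]}  2: {planted[1]}  >2: {planted[2]}")
print(f"mean steps per trace with >=1 step: {mean_steps:.2f}")
print()
print("Each count is the number of discrete bleach events in one "
      "diffraction-limited spot, i.e. the number of tagged proteins in "
      "that supercomplex; the mean is the average copy number.")
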