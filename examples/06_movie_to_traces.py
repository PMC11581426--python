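"""From a raw movie to intensity traces: spot detection end to end.

Renders a small synthetic TIRF photobleaching movie (Gaussian spots on a
noisy camera background), detects spots in the first frame with the
prominence-based maxima finder, extracts per-spot traces, and counts
steps -- the same path a real TIFF stack takes through the pipeline.
"""

import numpy as np

from smx import count_steps, extract_traces, find_spots
from smx.simulate import generate_trace_set, render_stack

pairs = generate_trace_set((0.5, 0.3, 0.2), n_traces=16, n_frames=200,
                           noise_sd=0.0, seed=9)
xy = np.array([[40 + 60 * (i % 4), 40 + 60 * (i // 4)] for i in range(16)], float)
traces = np.array([tr for tr, _ in pairs])
stack = render_stack(xy, traces, shape=(256, 256), psf_sigma=1.5,
                     background=100.0, noise="poisson", seed=1)

spots = find_spots(stack[0], prominence=500.0)
measured = extract_traces(stack, spots, aperture_radius=1)
fits = [count_steps(m.values, peak_threshold=40.0) for m in measured]

planted = sorted(t.n_steps for _, t in pairs)
recovered = sorted(f.n_steps for f in fits)
print(f"spots detected: {len(spots)} of {len(xy)} planted")
print(f"planted step counts:   {planted}")
print(f"recovered step counts: {recovered}")
print()
print("The 3x3-pixel aperture captures ~55% of each spot's photons, so "
      "the differential peak threshold is set below the movie-level 75 "
      "counts used on full-intensity traces.")
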