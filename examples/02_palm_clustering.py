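"""Cluster super-resolved localizations into supercomplexes.

Simulates an SMLM localization table (blinking fluorophores, truncated-
normal precision), merges repeated blinks into fluorophore objects,
groups objects within 160 nm into clusters, and reports the stoichiometry
distribution and the Fourier-ring-correlation image resolution.
"""

from smx import (cluster_objects, consolidate_blinks, frc_resolution,
                 generate_localization_field, ingest_localizations,
                 stoichiometry_fractions)

table, truth = generate_localization_field(
    n_clusters=800,
    stoichiometry_weights=(0.76, 0.12, 0.12),  # P(1), P(2), P(>2) per cluster
    precision_model=5.0,                       # nm, high-precision regime
    blink_mean=2.0,
    field_size_nm=80_000.0,
    seed=7,
)
locs = ingest_localizations(table, precision_max_nm=40.0)
# merge radius = 3x precision: repeat blinks of one fluorophore scatter by
# ~1.4x precision (Rayleigh), so the literal 1x radius would split them
objects = consolidate_blinks(locs, radius_factor=3.0)
clusters = cluster_objects(objects, radius_nm=160.0)
f1, f2, fmulti = stoichiometry_fractions(clusters)
frc = frc_resolution(locs)

import numpy as np
planted = np.bincount(truth.clusters["n_fluorophores"], minlength=4)[1:4]
planted = planted / planted.sum()

print(f"localizations: {len(locs)}  ->  objects after blink merging: {len(objects)}")
print(f"clusters (supercomplexes): {len(clusters)}")
print(f"recovered fractions  1: {f1:.1%}  2: {f2:.1%}  >2: {fmulti:.1%}")
print(f"planted fractions    1: {planted[0]:.1%}  2: {planted[1]:.1%}  "
      f">2: {planted[2]:.1%}")
print(f"FRC resolution: {frc.resolution_nm:.1f} nm ({frc.status})")
print()
print("Fractions are the share of supercomplexes containing one, two, or "
      "more than two labeled proteins.  Repeat blinks that escape the "
      "merge radius split a fluorophore into several objects, inflating "
      "the apparent multimer fraction -- the residual gap seen here; "
      "single-appearance probes (see example 03) recover exactly.  FRC is "
      "the spatial resolution the rendered image supports (1/7 threshold).")
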