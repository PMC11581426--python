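"""Measure the intramolecular separation of dimers by class averaging.

Plants 1000 two-protein clusters separated by exactly 12.7 nm, aligns each
dimer to a common frame, sums their precision-width Gaussian densities,
and reads the dominant separation off the averaged profile.
"""

from smx import (align_dimers, cluster_objects, consolidate_blinks,
                 generate_dimer_field, ingest_localizations, peak_separation,
                 render_class_average)

table, truth = generate_dimer_field(
    n_dimers=1000,
    separation_nm=12.7,       # planted truth
    precision_nm=4.0,         # rendering width per molecule
    position_noise=False,
    seed=11,
)
objects = consolidate_blinks(ingest_localizations(table))
dimers = [c for c in cluster_objects(objects, radius_nm=160.0)
          if c.stoichiometry == 2]
avg = render_class_average(align_dimers(dimers, seed=0), grid_nm=1.0)
est = peak_separation(avg)

print(f"dimers averaged: {avg.n_dimers}")
print(f"planted separation: {truth.dimer_separation_nm} nm")
print(f"recovered separation: {est.separation_nm:.2f} nm  "
      f"(peaks at {est.peak_positions_nm[0]:+.2f} / {est.peak_positions_nm[1]:+.2f} nm)")
print()
print("The small inward bias (~0.2 nm) is the expected mode shift of two "
      "overlapping Gaussians at this width-to-separation ratio.")
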