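"""Nuclear morphology near vessels: circularity and fractal dimension.

Healthy nuclei are smooth and round (circularity near 1, boundary
dimension near 1); apoptotic nuclei fragment into jagged lobes, which
lowers circularity and raises the box-counting dimension of the grouped
boundary.  The analysis is restricted to nuclei within 80 um of a vessel,
where antibody exposure is highest.
"""

import numpy as np

from histoflux import (SyntheticSpec, distance_field, extract_nuclei,
                       generate_section, proximal_filter, segment_vessels)

base = dict(image_shape=(640, 640), n_nuclei=150, nucleus_radius_um=8.0,
            fragmentation_severity=2.0)

for label, frac in (("intact cohort    ", 0.0), ("fragmented cohort", 1.0)):
    section, truth = generate_section(
        SyntheticSpec(rng_seed=42, frac_fragmented=frac, **base))
    objects = extract_nuclei(section, merge_radius_px=8.0)
    depth = distance_field(segment_vessels(section).mask, section.pixel_size_um)
    near = proximal_filter(objects, depth, max_dist_um=80.0)
    circ = np.nanmean([o.circularity for o in near])
    fd = np.nanmean([o.fractal_dimension for o in near])
    print(f"{label}: {len(near):3d} perivascular nuclei | "
          f"circularity {circ:.2f} | fractal dimension {fd:.2f}")
# The fragmented cohort should show lower circularity and higher fractal
# dimension - the morphological signature of treatment-induced apoptosis.
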