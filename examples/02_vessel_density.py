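"""Segment functional vessels with fuzzy c-means and report vascular density.

Pixel intensities of the lectin channel are clustered into two fuzzy
classes; the brighter cluster is the vessel class.  Density is the
fraction of tumor area covered by vessel pixels.
"""

import numpy as np

from histoflux import SyntheticSpec, generate_section, segment_vessels

section, truth = generate_section(SyntheticSpec(rng_seed=42, noise_sd=300.0))
vm = segment_vessels(section)

inter = (vm.mask & truth.vessel_mask).sum()
dice = 2 * inter / (vm.mask.sum() + truth.vessel_mask.sum())

print(f"FCM centroids          : {np.round(vm.fcm_centroids, 1)} AU "
      "(background vs vessel)")
print(f"vascular density       : {vm.vascular_density:.3f} "
      f"(ground-truth tube area {truth.vessel_area_fraction():.3f})")
print(f"vessel/non-vessel ratio: {vm.vessel_to_nonvessel_ratio:.3f}")
print(f"Dice vs ground truth   : {dice:.3f}")
# Density near the ground-truth tube fraction and Dice near 1 show the
# clustering recovers the perfused-vessel map even at 10% noise.
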