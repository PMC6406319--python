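# histoflux

Quantification of antibody delivery in multi-channel fluorescence images
of tumor sections.

Monoclonal antibodies such as trastuzumab penetrate solid tumors poorly:
signal concentrates around perfused vessels and falls off within tens of
micrometers.  Co-administered drugs can change that micro-distribution,
and the evidence lives in three-channel section images — DAPI (nuclei),
rhodamine-lectin (functional vessels), FITC (labelled antibody).
`histoflux` turns such images into numbers:

- **Vessels** — fuzzy c-means segmentation of the lectin channel into a
  binary functional-vessel mask and a vascular density (vessel area /
  tumor area).
- **Penetration** — Euclidean distance transform from the vessel mask (or
  tumor surface), mean antibody intensity per depth bin, trapezoidal AUC
  over 0–80 µm, peak depth, and total accumulation per tumor area
  (AU/µm²) with percent changes between treatment groups.
- **Nuclear morphology** — Laplacian-of-Gaussian nucleus extraction,
  circularity 4πA/P² and box-counting fractal dimension of the nuclear
  boundary, restricted to nuclei within 80 µm of vessels; fragmented
  (apoptotic) nuclei score low circularity and high FD.
- **Reporting** — group mean ± SD, percent change vs a reference group,
  one-way ANOVA, and the caliper tumor-volume formula width² × length × 0.4.
- **Synthetic sections** — a generator producing all three channels with
  known ground truth (vessel geometry, antibody decay length, nucleus
  shape class), so every stage is verifiable without raw microscope data.

The library is the primary interface; `examples/` holds one short script
per capability, and a thin `histoflux` CLI (`simulate`, `analyze-vessels`,
`analyze-penetration`, `analyze-nuclei`, `report`) wraps the same
functions for shell use.  See `docs/methods.md` for models, estimator
calibrations and limitations.

## Worked example

```python
import numpy as np
from histoflux import (SyntheticSpec, generate_section, segment_vessels,
                       distance_field, intensity_profile, accumulation,
                       extract_nuclei, proximal_filter, percent_change)

# a synthetic section: 6 vessels, antibody decaying with lambda = 25 um
spec = SyntheticSpec(rng_seed=42, decay_length_um=25.0, noise_sd=50.0)
section, truth = generate_section(spec)

vessels = segment_vessels(section)
depth = distance_field(vessels.mask, section.pixel_size_um)
profile = intensity_profile(section, depth, bin_width_um=1.0)
acc = accumulation(section)

print(f"vascular density     {vessels.vascular_density:.3f}")
print(f"AUC 0-80 um          {profile.auc_0_80:.0f} AU*um")
print(f"accumulation density {acc.accumulation_density:.2f} AU/um^2")
```

prints

```
vascular density     0.180
AUC 0-80 um          24033 AU*um
accumulation density 1408.42 AU/um^2
```

The density is the fraction of the tumor area covered by segmented
vessels (here matching the generator's tube-area fraction of 0.180); the
AUC summarizes how much antibody sits within 80 µm of a vessel; the
accumulation density is total antibody signal per µm² of tumor — the
quantity whose group-to-group percent change (`percent_change`) expresses
how strongly a co-administered drug improves delivery, e.g.
`percent_change(3.10, 1.72)` → `80.2`.

Running `python examples/04_nuclear_radiomics.py` adds the morphology
readout:

```
intact cohort    :  98 perivascular nuclei | circularity 1.00 | fractal dimension 1.04
fragmented cohort: 100 perivascular nuclei | circularity 0.26 | fractal dimension 1.17
```

— fragmentation drives circularity down and boundary fractal dimension
up, the signature used to score treatment-induced apoptosis near vessels.

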