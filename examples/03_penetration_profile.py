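"""Antibody penetration from vessels: profile, AUC to 80 um, accumulation.

The distance transform of the vessel mask gives each pixel's depth into
tissue; mean antibody intensity per 1-um depth bin yields the penetration
profile, summarized by its area under the curve over 0-80 um and by the
depth of maximal signal.
"""

from histoflux import (SyntheticSpec, accumulation, distance_field,
                       fit_decay_length, generate_section, intensity_profile,
                       segment_vessels)

spec = SyntheticSpec(rng_seed=42, decay_length_um=25.0, noise_sd=50.0)
section, truth = generate_section(spec)

vessels = segment_vessels(section).mask
depth = distance_field(vessels, section.pixel_size_um)
profile = intensity_profile(section, depth, bin_width_um=1.0, max_depth_um=80.0)
acc = accumulation(section)
amp, lam = fit_decay_length(profile)

print(f"AUC 0-80 um          : {profile.auc_0_80:.0f} AU*um")
print(f"peak depth           : {profile.peak_depth_um:.1f} um "
      f"(raw argmax {profile.peak_depth_um_raw:.1f} um)")
print(f"accumulation density : {acc.accumulation_density:.2f} AU/um^2 "
      f"over {acc.tumor_area_um2:.0f} um^2 of tumor")
print(f"fitted decay length  : {lam:.1f} um (generator used "
      f"{spec.decay_length_um} um)")
# A decaying profile peaks in the first bin; treatments that improve
# delivery raise the AUC and push the peak deeper into tissue.
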