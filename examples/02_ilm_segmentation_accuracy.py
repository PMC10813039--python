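"""Measure ILM segmentation accuracy against phantom ground truth under
speckle noise.

The detector finds, per A-scan, the first depth whose median-smoothed
intensity rises more than k robust SDs above the running vitreous
baseline, then median-filters the surface laterally.  On noiseless
phantoms it is exact; here we add 5% multiplicative speckle.
"""

import numpy as np

import vitrehaze as vz

spec = vz.PhantomSpec(n_bscans=8, n_ascans=64, n_depth=128,
                      haze_level=0.01, noise_sigma=0.05)

errors, fail_fracs = [], []
for seed in range(20):
    volume, truth = vz.generate_volume(spec, seed)
    surface = vz.segment_ilm(volume)
    ok = ~surface.failed
    errors.append(np.abs(surface.depth_index[ok] - truth.ilm_depth[ok]).mean())
    fail_fracs.append(surface.failure_fraction)

print(f"phantoms: 20 volumes of {spec.n_bscans}x{spec.n_ascans} A-scans, "
      f"speckle sigma {spec.noise_sigma}")
print(f"mean absolute ILM depth error: {np.mean(errors):.3f} px "
      f"(axial spacing {spec.axial_spacing_um} um)")
print(f"failed A-scan fraction:        {np.mean(fail_fracs):.4f}")
print()
print("Sub-pixel mean error means pooled vitreous/retina means, and hence")
print("the haze score, are essentially unaffected by segmentation noise.")
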