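"""Robustness of curvature recovery to skeleton noise.

Skeletonization of real angiograms jitters centerline points at roughly the
half-voxel scale (~0.25 mm for 0.5 mm MRA voxels). Here a helix skeleton is
perturbed by 0.1 mm isotropic Gaussian noise; a smoothing fit (15 control
points for 200 samples, refinement off) recovers the true curvature, while
the jitter itself would otherwise dominate the second derivative.
"""

import numpy as np

from vesselquant import (
    FitConfig,
    Phantom,
    fit_curve,
    fitting_error,
    generate,
    geometry_profile,
)

cfg = FitConfig(n_ctrl=15, refine_max_iter=0)
kappas, errors = [], []
for seed in range(20):
    skeleton = generate(Phantom("helix", n_points=200, noise_sigma=0.1,
                                seed=seed))
    vessel = fit_curve(skeleton, cfg)
    profile = geometry_profile(vessel, 20, include_radius=False)
    kappas.append(np.nanmean(profile.curvature[1:-1]))
    errors.append(fitting_error(vessel, skeleton, 8)[1])

print("true curvature            : 0.8000 /mm")
print(f"recovered (20 replicates) : {np.mean(kappas):.4f} "
      f"+/- {np.std(kappas):.4f} /mm")
print(f"mean fit error            : {np.mean(errors):.4f} mm "
      f"(noise sigma was 0.1 mm)")
print("\nThe curvature bias stays within a few percent and the fit error")
print("sits below the injected noise scale: the smoothing fit averages the")
print("jitter instead of differentiating it.")
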