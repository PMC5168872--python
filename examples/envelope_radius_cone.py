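"""Vessel radius from the envelope-of-spheres model.

A tapering vessel is modelled as the envelope of spheres of radius r(s)
centered on the centerline. The measured wall radius is not r itself but
R = r * sqrt(1 - (dr/ds)^2): where the caliber changes, the tangency circle
sits slightly behind the sphere center and is smaller than the sphere. A
cone with r(s) = 0.5 + 0.25 s makes this visible.
"""

import numpy as np

from vesselquant import (
    Phantom,
    envelope_radius,
    fit_curve,
    fit_radius,
    generate,
    geometry_profile,
)

phantom = Phantom("cone_tube", params={"length": 20.0, "r0": 0.5,
                                       "slope": 0.25}, n_points=60)
skeleton = generate(phantom)
vessel = fit_radius(skeleton, fit_curve(skeleton))
profile = geometry_profile(vessel, n=10)

print("  s (mm)   sphere r(s)   envelope R(s)   exact R")
for u, s, R in zip(profile.params, profile.arc_positions, profile.radius):
    sample = envelope_radius(vessel, float(u))
    exact = (0.5 + 0.25 * s) * np.sqrt(1 - 0.25 ** 2)
    print(f"  {s:6.2f}   {sample.sphere_radius:9.4f}   {R:11.4f}   "
          f"{exact:9.4f}")
print("\nR is uniformly sqrt(1-0.0625) = 96.8% of the sphere radius: the")
print("5 mm-per-20 mm taper shifts each tangency circle off the sphere")
print("equator. For a constant-caliber vessel R and r coincide.")
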