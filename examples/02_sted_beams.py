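"""Shape STED depletion beams: vortex donut, pi-ring bottle, and their mix.

A charge-1 vortex mask with co-rotating circular polarization produces a
lateral donut with a true zero on the optical axis; a pi-phase ring mask
(radius 0.55 of the pupil) produces a "bottle" with a central null capped
by axial lobes.  3D-STED splits power between both with weight p.
"""

import math

from vectorpsf import psf_metrics, simulate_psf, validate

circular = {"epsilon": math.pi / 4}

donut = simulate_psf(validate({
    "beam": {"polarization": circular,
             "mask": {"kind": "vortex", "charge_q": 1}}}))
bottle = simulate_psf(validate({
    "beam": {"polarization": circular,
             "mask": {"kind": "ring", "charge_q": 1, "ring_radius_rR": 0.55}}}))
mixed = simulate_psf(validate({
    "beam": {"polarization": circular,
             "mask": {"kind": "mixed", "charge_q": 1, "ring_radius_rR": 0.55,
                      "mix_p": 0.5}}}))

for name, psf in [("donut", donut), ("bottle", bottle), ("50/50 mix", mixed)]:
    m = psf_metrics(psf)
    print(f"{name:9s}: null depth I(0)/max = {m['null_depth']:.2e}")

c = donut.grid.nx // 2
axial = bottle.intensity[c, c, :]
print(f"bottle on-axis lobes at z = {donut.grid.axis('z')[axial.argmax()]:+.0f} nm "
      f"(intensity {axial.max():.2f} vs {axial[donut.grid.nz // 2]:.3f} at center)")

# Null depths ~1e-32 are numerically exact zeros (azimuthal phase winding
# cancels every field component on axis); the bottle's center is dark only
# axially, its residual ~5% stems from the finite ring radius choice.

# Polarization matters: the same vortex with *linear* polarization leaks
# axial field into the center and spoils the zero.
linear = simulate_psf(validate({"beam": {"mask": {"kind": "vortex",
                                                  "charge_q": 1}}}))
print(f"linear-polarized donut null depth = "
      f"{psf_metrics(linear)['null_depth']:.3f}  (donut spoiled)")
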