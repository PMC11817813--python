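"""STED effective fluorescence PSF over a saturation ladder.

The fluorescence that survives depletion is I_eff = I_e * 2^(-S * I_d) with
I_d normalized to unit peak; S is the saturation factor (peak depletion
power in units of the fluorophore's saturation intensity).  Raising S
squeezes the fluorescent spot far below the diffraction limit.
"""

import math

from vectorpsf import effective_psf, psf_metrics, simulate_psf, validate

grid = {"nx": 63, "ny": 63, "nz": 1, "extent_xy": 600.0, "normalize": False}
circular = {"epsilon": math.pi / 4}

excitation = simulate_psf(validate({
    "beam": {"polarization": circular}, "grid": grid}))
depletion = simulate_psf(validate({
    "beam": {"polarization": circular,
             "mask": {"kind": "vortex", "charge_q": 1}}, "grid": grid}))

w0 = psf_metrics(excitation)["fwhm_x"]
print(f"confocal excitation FWHM: {w0:.1f} nm")
for s in [0, 1, 10, 100]:
    eff = effective_psf(excitation, depletion, s)
    w = psf_metrics(eff)["fwhm_x"]
    print(f"saturation S = {s:3d} -> effective FWHM {w:6.1f} nm "
          f"(gain x{w0 / w:.1f})")

# The width shrinks roughly as 1/sqrt(1+S), the classic STED square-root
# resolution law; at S = 100 the simulated spot is ~11x narrower than the
# confocal one while the donut's central zero keeps the peak fluorescence.
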