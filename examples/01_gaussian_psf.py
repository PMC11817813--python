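"""Focus a plain Gaussian beam and measure the focal spot.

Default conditions: NA 1.0 water-immersion objective (n = 1.33 throughout,
so the coverslip is optically invisible), 640 nm, circular polarization,
31^3 voxels over a 2 x 2 x 4 um volume, 31 x 31 angular samples.
"""

import math

from vectorpsf import psf_metrics, simulate_psf, validate

config = validate({"beam": {"polarization": {"epsilon": math.pi / 4}}})
psf = simulate_psf(config)
m = psf_metrics(psf)

print(f"lateral FWHM : {m['fwhm_x']:.1f} nm (x) / {m['fwhm_y']:.1f} nm (y)")
print(f"axial FWHM   : {m['fwhm_z']:.1f} nm")
print(f"peak voxel   : {m['argmax']} (grid center = (15, 15, 15))")

# The lateral width sits near the scalar diffraction estimate 0.51 lambda/NA
# = 326 nm, slightly enlarged by the vectorial z-field at high NA; the axial
# extent is ~3.5x the lateral one, the usual focal "cigar".
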