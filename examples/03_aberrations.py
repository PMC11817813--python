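"""Distort a donut beam with Zernike aberrations.

Coefficients are radians of wavefront phase at the pupil edge (modes
normalized to R_n^m(1) = 1).  One radian of coma or astigmatism visibly
breaks the donut symmetry and fills in its central zero -- the reason STED
microscopes need adaptive optics at depth.
"""

import math

from vectorpsf import psf_metrics, simulate_psf, validate

donut_beam = {"polarization": {"epsilon": math.pi / 4},
              "mask": {"kind": "vortex", "charge_q": 1}}

modes = {
    "none": [],
    "astigmatism (2,2)": [(2, 2, 1.0)],
    "coma (3,1)": [(3, 1, 1.0)],
    "spherical (4,0)": [(4, 0, 1.0)],
}

for label, zernike in modes.items():
    cfg = validate({"beam": {**donut_beam, "zernike": zernike}})
    m = psf_metrics(simulate_psf(cfg))
    print(f"{label:18s}: null depth = {m['null_depth']:.3e}, "
          f"peak voxel = {m['argmax']}")

# Rotationally symmetric aberrations (spherical, m = 0) leave the charge-1
# phase winding intact, so the on-axis zero survives to machine precision;
# azimuthally varying modes (astigmatism m = 2, coma m = 1) couple pupil
# field into the axis and fill the null by a few percent per radian.
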