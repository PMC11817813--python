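"""Donut/bottle mixing and the STED effective fluorescence PSF.

In 3D-STED the depletion light is split between a vortex (donut) and a
ring-mask (bottle) path with orthogonal polarizations, so the two focal
intensities add incoherently.  The fluorescence that survives depletion is
the excitation PSF suppressed exponentially by the depletion intensity:

    I_eff = I_e * exp(-ln 2 * S * I_d / max(I_d))

where S is the dimensionless saturation factor (peak depletion intensity in
units of the fluorophore's saturation intensity I_sat).  S = 1 halves the
fluorescence at the depletion peak; large S confines fluorescence to the
depletion null.
"""

from __future__ import annotations

import math

import numpy as np

from .integrator import PSFVolume

__all__ = ["mix_donut_bottle", "effective_psf"]


def _check_grids(a: PSFVolume, b: PSFVolume) -> None:
    if a.intensity.shape != b.intensity.shape:
        raise ValueError(
            f"grid mismatch: {a.intensity.shape} vs {b.intensity.shape}"
        )
    ga, gb = a.grid, b.grid
    if (ga.extent_xy, ga.extent_z) != (gb.extent_xy, gb.extent_z):
        raise ValueError("grid mismatch: physical extents differ")


def mix_donut_bottle(donut: PSFVolume, bottle: PSFVolume, p: float) -> PSFVolume:
    """Incoherent weighted sum I_tot = p * I_donut + (1 - p) * I_bottle.

    Note the convention: the weight ``p`` multiplies the **donut** term, so
    p = 1 is a pure donut and p = 0 a pure bottle.  (The opposite reading
    also circulates; ``SimulationConfig.p_convention`` flips it.)
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("mixing weight p must lie in [0, 1]")
    _check_grids(donut, bottle)
    return PSFVolume(
        grid=donut.grid,
        intensity=p * donut.intensity + (1.0 - p) * bottle.intensity,
        normalized=False,
        z_offset=donut.z_offset,
    )


def effective_psf(excitation: PSFVolume, depletion: PSFVolume,
                  saturation: float) -> PSFVolume:
    """Effective fluorescence PSF I_eff = I_e * exp(-ln2 * S * I_d / max I_d).

    The depletion volume is normalized to unit peak internally, so
    *saturation* is scale-free: at the depletion peak the fluorescence is
    suppressed by 2^-S.  Voxelwise 0 <= I_eff <= I_e, with equality exactly
    where the depletion vanishes (the donut/bottle null is preserved).
    """
    if saturation < 0:
        raise ValueError("saturation must be >= 0")
    _check_grids(excitation, depletion)
    peak = depletion.intensity.max()
    d_norm = depletion.intensity / peak if peak > 0 else depletion.intensity
    eff = excitation.intensity * np.exp(-math.log(2.0) * saturation * d_norm)
    return PSFVolume(
        grid=excitation.grid,
        intensity=eff,
        normalized=False,
        provenance=excitation.provenance,
        z_offset=excitation.z_offset,
    )
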