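"""Discretized Debye-Wolf summation of the focal field.

Each sampled pupil direction contributes one plane wave; the focal field at
voxel r = (x, y, z) is

    E(r) = -i k0 n1 / (2 pi) * sum_{m,n} Lambda(3) P0 A(theta, phi)
           exp[i k0 n1 (x sin(theta1) cos(phi) + y sin(theta1) sin(phi))]
           exp[i k0 n3 z cos(theta3)] exp[i Phi(3)] sin(theta) dtheta dphi

with all stratified-media factors (Snell chain, coverslip transmission,
polarization conversion, stratification phase) supplied by
:mod:`vectorpsf.layers`.  The prefactor's focal length is fixed to one
length unit: absolute field scale is arbitrary, only relative (or
max-normalized) intensities are meaningful.

The sum over the angular index runs in one fixed order inside a matrix
product, so results are bitwise independent of how the voxel set is
partitioned into chunks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import SimulationConfig, SimulationGrid, OpticalSystem, validate
from .layers import (
    coverslip_transmission,
    polarization_operator,
    snell_chain,
    stratification_phase,
)
from .pupil import PupilSample, assemble_pupil

__all__ = [
    "FocalField",
    "PSFVolume",
    "integrate",
    "intensity",
    "psf_metrics",
    "simulate_field",
    "simulate_psf",
]

# voxels per matmul chunk; results are chunk-independent by construction
_CHUNK_VOXELS = 8192


@dataclass
class FocalField:
    """Complex vector field on the voxel grid: ``field[c, ix, iy, iz]``
    with c = (Ex, Ey, Ez)."""

    grid: SimulationGrid
    field: np.ndarray
    wavelength: float
    provenance: Optional[dict] = None
    z_offset: float = 0.0  # nm shift of the axial window (refocus option)


@dataclass
class PSFVolume:
    """Real non-negative intensity on the voxel grid, ``intensity[ix, iy, iz]``."""

    grid: SimulationGrid
    intensity: np.ndarray
    normalized: bool = False
    provenance: Optional[dict] = None
    z_offset: float = 0.0


def integrate(pupil: PupilSample, system: OpticalSystem, wavelength: float,
              grid: SimulationGrid, z_offset: float = 0.0) -> FocalField:
    """Sum the sampled plane waves over the voxel grid.

    *z_offset* shifts the axial evaluation window (used by the axial-shift
    refocus option); coordinates stored in the result remain grid-centered.
    """
    if pupil.amplitude.shape != (pupil.theta.size, pupil.phi.size):
        raise ValueError("pupil sampling inconsistent with its angle grids")
    if pupil.amplitude.shape != (grid.n_theta, grid.n_phi):
        raise ValueError("pupil sampling inconsistent with grid (n_theta, n_phi)")

    k0 = 2.0 * math.pi / wavelength
    th = pupil.theta[:, None]
    angles = snell_chain(th, system)  # immersion-frame chain, (Nt, 1)
    cs = coverslip_transmission(angles, system, wavelength)
    lam = polarization_operator(th, pupil.phi[None, :], angles, cs)  # (Nt, Nphi, 3, 3)

    # sample-space polarization per direction
    S = np.einsum("tpij,tpj->tpi", lam, pupil.polarization0)

    # stratification phase at the objective-frame (possibly tilted) angles
    angles_obj = snell_chain(pupil.theta_obj, system)
    phi3 = stratification_phase(angles_obj, system, wavelength)

    weight = (
        pupil.amplitude
        * np.exp(1j * phi3)
        * np.sin(th)
        * pupil.d_theta
        * pupil.d_phi
    )
    V = (S * weight[..., None]).reshape(-1, 3)  # (J, 3)

    sin1 = np.broadcast_to(angles.sin1, pupil.amplitude.shape).reshape(-1)
    cos3 = np.broadcast_to(angles.cos3, pupil.amplitude.shape).reshape(-1)
    kx = k0 * system.n1 * sin1 * np.cos(np.broadcast_to(pupil.phi[None, :], pupil.amplitude.shape).reshape(-1))
    ky = k0 * system.n1 * sin1 * np.sin(np.broadcast_to(pupil.phi[None, :], pupil.amplitude.shape).reshape(-1))
    kz = k0 * system.n3 * cos3  # complex past the critical angle

    x = grid.axis("x")
    y = grid.axis("y")
    z = grid.axis("z") + z_offset

    Ax = np.exp(1j * np.outer(x, kx))  # (nx, J)
    Ay = np.exp(1j * np.outer(y, ky))  # (ny, J)
    Az = np.exp(1j * np.outer(z.astype(complex), kz))  # (nz, J)

    # F[(c, iz), j] = V[j, c] * Az[iz, j]
    F = (V.T[:, None, :] * Az[None, :, :]).reshape(3 * z.size, -1)

    nxy = x.size * y.size
    E = np.empty((3 * z.size, nxy), dtype=complex)
    for start in range(0, nxy, _CHUNK_VOXELS):
        stop = min(start + _CHUNK_VOXELS, nxy)
        ix, iy = np.unravel_index(np.arange(start, stop), (x.size, y.size))
        B = Ax[ix, :] * Ay[iy, :]  # (chunk, J)
        # fixed-order reduction over j (no BLAS blocking), so the result is
        # bitwise independent of the chunk partitioning
        E[:, start:stop] = np.einsum("cj,vj->cv", F, B, optimize=False)

    prefactor = -1j * k0 * system.n1 / (2.0 * math.pi)
    out = (prefactor * E).reshape(3, z.size, x.size, y.size)
    out = np.moveaxis(out, 1, 3)  # -> (3, nx, ny, nz)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values in focal field")
    return FocalField(grid=grid, field=out, wavelength=wavelength, z_offset=z_offset)


def intensity(field: FocalField, normalize: bool = False) -> PSFVolume:
    """I = |Ex|^2 + |Ey|^2 + |Ez|^2 per voxel; optionally max-normalized."""
    vol = np.sum(np.abs(field.field) ** 2, axis=0)
    if normalize:
        peak = vol.max()
        if peak == 0.0:
            raise ValueError("degenerate normalization: field is identically zero")
        vol = vol / peak
    return PSFVolume(
        grid=field.grid, intensity=vol, normalized=normalize,
        provenance=field.provenance, z_offset=field.z_offset,
    )


def _fwhm_1d(coords: np.ndarray, profile: np.ndarray) -> Optional[float]:
    """Full width at half max of a 1-D profile by linear interpolation of
    the half-max crossings around the profile peak; None when the profile
    does not cross half-max inside the sampled range."""
    i_max = int(np.argmax(profile))
    half = profile[i_max] / 2.0
    left = None
    for i in range(i_max, 0, -1):
        if profile[i - 1] <= half <= profile[i]:
            f = (half - profile[i - 1]) / (profile[i] - profile[i - 1])
            left = coords[i - 1] + f * (coords[i] - coords[i - 1])
            break
    right = None
    for i in range(i_max, profile.size - 1):
        if profile[i + 1] <= half <= profile[i]:
            f = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = coords[i] + f * (coords[i + 1] - coords[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def psf_metrics(psf: PSFVolume) -> dict:
    """Summary metrics of a PSF volume.

    Returns max intensity, argmax voxel, lateral FWHM along x and y and
    axial FWHM (linear interpolation through the global max), and the
    on-axis null depth I(center)/max (the donut/bottle zero quality).
    FWHMs that do not cross half-max inside the grid are None.
    """
    vol = psf.intensity
    if vol.size == 0:
        raise ValueError("empty PSF volume")
    ixm, iym, izm = np.unravel_index(int(np.argmax(vol)), vol.shape)
    x = psf.grid.axis("x")
    y = psf.grid.axis("y")
    z = psf.grid.axis("z")
    peak = float(vol[ixm, iym, izm])
    center = (vol.shape[0] // 2, vol.shape[1] // 2, vol.shape[2] // 2)
    return {
        "max": peak,
        "argmax": (int(ixm), int(iym), int(izm)),
        "fwhm_x": _fwhm_1d(x, vol[:, iym, izm]),
        "fwhm_y": _fwhm_1d(y, vol[ixm, :, izm]),
        "fwhm_z": _fwhm_1d(z, vol[ixm, iym, :]),
        "null_depth": float(vol[center] / peak) if peak > 0 else None,
    }


def _axial_refocus_offset(config: SimulationConfig) -> float:
    """Locate the axial intensity peak on a coarse on-axis scan and return
    its z (nm), used to re-center the evaluation window."""
    cfg = config.model_copy(deep=True)
    span = 4.0 * config.grid.extent_z
    scan = cfg.grid.model_copy(
        update={"nx": 1, "ny": 1, "nz": 4 * cfg.grid.nz + 1, "extent_z": span}
    )
    pupil = assemble_pupil(cfg.beam, cfg.system, scan, cfg.apodization, cfg.theta_sampling)
    fld = integrate(pupil, cfg.system, cfg.beam.wavelength, scan)
    profile = np.sum(np.abs(fld.field[:, 0, 0, :]) ** 2, axis=0)
    return float(scan.axis("z")[int(np.argmax(profile))])


def simulate_field(config: SimulationConfig,
                   custom_mask: np.ndarray | None = None) -> FocalField:
    """Assemble the pupil and integrate one focal field for *config*.

    For a ``mixed`` phase mask use :func:`simulate_psf`, which combines the
    donut and bottle intensities incoherently.
    """
    cfg = validate(config)
    if cfg.beam.mask.kind == "mixed":
        raise ValueError("mixed masks are incoherent; use simulate_psf")
    z_offset = _axial_refocus_offset(cfg) if cfg.refocus == "axial_shift" else 0.0
    pupil = assemble_pupil(
        cfg.beam, cfg.system, cfg.grid, cfg.apodization, cfg.theta_sampling,
        custom_mask=custom_mask,
    )
    fld = integrate(pupil, cfg.system, cfg.beam.wavelength, cfg.grid, z_offset)
    fld.provenance = cfg.model_dump(mode="json")
    return fld


def simulate_psf(config: SimulationConfig,
                 custom_mask: np.ndarray | None = None) -> PSFVolume:
    """Run a full simulation and return the intensity PSF.

    A ``mixed`` mask runs the vortex (donut) and ring (bottle) simulations
    separately and mixes the intensities with the configured weight; see
    :func:`vectorpsf.sted.mix_donut_bottle` for the convention.
    """
    cfg = validate(config)
    if cfg.beam.mask.kind == "mixed":
        from .sted import mix_donut_bottle

        donut_cfg = cfg.model_copy(deep=True)
        donut_cfg.beam.mask = cfg.beam.mask.model_copy(update={"kind": "vortex"})
        bottle_cfg = cfg.model_copy(deep=True)
        bottle_cfg.beam.mask = cfg.beam.mask.model_copy(update={"kind": "ring"})
        donut = intensity(simulate_field(donut_cfg), normalize=False)
        bottle = intensity(simulate_field(bottle_cfg), normalize=False)
        p = cfg.beam.mask.mix_p
        if cfg.p_convention == "p_bottle":
            p = 1.0 - p
        mixed = mix_donut_bottle(donut, bottle, p)
        if cfg.grid.normalize:
            mixed.intensity = mixed.intensity / mixed.intensity.max()
            mixed.normalized = True
        mixed.provenance = cfg.model_dump(mode="json")
        return mixed
    fld = simulate_field(cfg, custom_mask=custom_mask)
    psf = intensity(fld, normalize=cfg.grid.normalize)
    psf.provenance = cfg.model_dump(mode="json")
    return psf
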