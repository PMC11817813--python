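"""Complex vector pupil function on the angular sampling grid.

The pupil sample combines, per plane-wave direction (theta, phi):

* the Gaussian amplitude profile with the aplanatic apodization factor,
* the Zernike aberration phase exp(i Phi),
* the beam-shaping mask phase exp(i M) (vortex or pi-ring),
* the cranial-window amplitude mask CW,
* the input Jones polarization vector P0,

and, for a tilted coverslip, the rotation of the spherical wavefront: all
objective-frame quantities are evaluated at the back-rotated direction
(theta', phi'), the polar range is expanded to alpha + |gamma|, and rays
whose back-rotated direction falls outside the pupil carry zero amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import InputBeam, OpticalSystem, PhaseMaskSpec, Polarization, SimulationGrid

__all__ = [
    "PupilSample",
    "gaussian_amplitude",
    "zernike_radial",
    "zernike_phase",
    "phase_mask",
    "window_mask",
    "tilt_transform",
    "polarization_jones",
    "assemble_pupil",
    "pupil_maps",
]


@dataclass
class PupilSample:
    """Sampled pupil function.

    theta, phi        -- 1-D angle grids (radians); theta spans [0, alpha] or
                         [0, alpha+|gamma|] when tilted.
    amplitude         -- complex (n_theta, n_phi) array: Gaussian profile x
                         apodization x exp(i(Phi + M)) x window mask, zeroed
                         outside the (back-rotated) pupil.
    polarization0     -- (n_theta, n_phi, 3) complex unit Jones vectors
                         (third component 0).
    theta_obj         -- (n_theta, n_phi) objective-frame polar angle theta'
                         (equal to broadcast theta when gamma = 0); used for
                         the tilt-transformed stratification phase.
    d_theta, d_phi    -- angular steps.
    """

    theta: np.ndarray
    phi: np.ndarray
    amplitude: np.ndarray
    polarization0: np.ndarray
    theta_obj: np.ndarray
    d_theta: float
    d_phi: float


def _pupil_coords(theta, phi, alpha):
    """Cartesian pupil-plane coordinates in units of the pupil radius
    (sine condition: radial coordinate rho = sin(theta)/sin(alpha))."""
    rho = np.sin(theta) / math.sin(alpha)
    return rho * np.cos(phi), rho * np.sin(phi)


def gaussian_amplitude(theta, phi, beam: InputBeam, system: OpticalSystem,
                       apodization: str = "sqrt_cos"):
    """Gaussian pupil amplitude with aplanatic apodization.

    A(theta, phi) = A0 exp(-rho^2 / w^2) * apod(theta) with rho the
    pupil-radius-normalized radial coordinate shifted by the beam offset
    and apod = sqrt(cos theta) (energy conservation for a sine-condition
    lens) or cos(theta) when selected.  A0 is fixed to 1 (only relative
    intensities are meaningful).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    u, v = _pupil_coords(theta, phi, system.alpha)
    ox, oy = beam.offset
    rho2 = (u - ox) ** 2 + (v - oy) ** 2
    cos_t = np.cos(theta)
    if apodization == "sqrt_cos":
        apod = np.sqrt(np.clip(cos_t, 0.0, None))
    elif apodization == "cos":
        apod = np.clip(cos_t, 0.0, None)
    else:
        raise ValueError(f"unknown apodization {apodization!r}")
    return np.exp(-rho2 / beam.waist_w**2) * apod


def zernike_radial(n: int, m: int, rho):
    """Radial Zernike polynomial R_n^|m|(rho), normalized to R_n^|m|(1) = 1."""
    m = abs(m)
    if n < 0 or m > n or (n - m) % 2:
        raise ValueError(f"invalid Zernike index (n={n}, m={m})")
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for l in range((n - m) // 2 + 1):
        c = (
            (-1) ** l
            * math.factorial(n - l)
            / (
                math.factorial(l)
                * math.factorial((n + m) // 2 - l)
                * math.factorial((n - m) // 2 - l)
            )
        )
        out = out + c * rho ** (n - 2 * l)
    return out


def zernike_phase(rho, theta_c, coeffs):
    """Aberration phase Phi = sum C * R_n^|m|(rho) * G_m(theta_c), radians.

    G_m is cos(m theta_c) for m >= 0 and sin(|m| theta_c) for m < 0;
    *coeffs* is a sequence of (n, m, C) triples or ZernikeTerm objects.
    """
    rho = np.asarray(rho, dtype=float)
    theta_c = np.asarray(theta_c, dtype=float)
    phase = np.zeros(np.broadcast(rho, theta_c).shape)
    for term in coeffs:
        if hasattr(term, "n"):
            n, m, c = term.n, term.m, term.coeff
        else:
            n, m, c = term
        radial = zernike_radial(n, m, rho)
        ang = np.cos(m * theta_c) if m >= 0 else np.sin(abs(m) * theta_c)
        phase = phase + c * radial * ang
    return phase


def phase_mask(theta, phi, mask: PhaseMaskSpec, system: OpticalSystem):
    """Beam-shaping phase M(theta, phi) in radians.

    none   -> 0
    vortex -> q * azimuth about the (possibly offset) mask center
    ring   -> q*pi inside theta <= theta_R, 0 outside, with
              theta_R = arcsin((r_R / r_pup) sin alpha); an offset shifts
              the disk center in the pupil plane.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if mask.kind == "none":
        return np.zeros(np.broadcast(theta, phi).shape)
    u, v = _pupil_coords(theta, phi, system.alpha)
    ox, oy = mask.mask_offset
    u, v = u - ox, v - oy
    if mask.kind == "vortex":
        return mask.charge_q * np.arctan2(v, u)
    if mask.kind == "ring":
        # theta <= theta_R is equivalent to rho <= r_R in pupil-radius units
        inside = np.hypot(u, v) <= mask.ring_radius_rR + 1e-15
        return np.where(inside, mask.charge_q * math.pi, 0.0)
    raise ValueError(f"phase_mask does not apply to kind {mask.kind!r}")


def window_mask(theta, system: OpticalSystem):
    """Cranial-window amplitude mask: 1 for theta <= theta_c, else 0.

    With no window configured the mask is identically 1.
    """
    theta = np.asarray(theta, dtype=float)
    if system.window_theta_c is None:
        return np.ones_like(theta)
    return (theta <= system.window_theta_c + 1e-15).astype(float)


def tilt_transform(theta, phi, gamma: float, system: OpticalSystem):
    """Back-rotate ray directions for a coverslip tilted by *gamma*.

    Tilting the coverslip by gamma is equivalent to rotating the objective
    (and input beam) by -gamma; the tilt plane is fixed to x-z (rotation
    about the y axis).  Returns (theta', phi', in_pupil): the angles at
    which the untilted pupil function is evaluated, and a flag that is False
    where the back-rotated ray falls outside the pupil cap (theta' > alpha).
    """
    alpha = system.alpha
    if abs(gamma) >= math.pi / 2 - alpha:
        raise ValueError("tilt geometry violation: |gamma| must be < pi/2 - alpha")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st, ct = np.sin(theta), np.cos(theta)
    sx, sy, sz = st * np.cos(phi), st * np.sin(phi), ct
    cg, sg = math.cos(gamma), math.sin(gamma)
    # rotation of the unit ray vector about +y by -gamma
    sxp = cg * sx - sg * sz
    szp = sg * sx + cg * sz
    theta_p = np.arccos(np.clip(szp, -1.0, 1.0))
    phi_p = np.arctan2(sy, sxp)
    in_pupil = theta_p <= alpha + 1e-12
    return theta_p, phi_p, in_pupil


def polarization_jones(phi, beam: InputBeam):
    """Input Jones vector per azimuth, as a (..., 3) complex array.

    elliptical -> (cos eps, i sin eps, 0) rotated counter-clockwise by psi
                  about the optical axis (eps = +pi/4 gives left circular
                  (1, i, 0)/sqrt2, -pi/4 right circular);
    radial     -> (cos phi, sin phi, 0);
    azimuthal  -> (-sin phi, cos phi, 0).
    """
    phi = np.asarray(phi, dtype=float)
    pol: Polarization = beam.polarization
    out = np.zeros(phi.shape + (3,), dtype=complex)
    if pol.kind == "elliptical":
        ex = math.cos(pol.epsilon)
        ey = 1j * math.sin(pol.epsilon)
        c, s = math.cos(pol.psi), math.sin(pol.psi)
        out[..., 0] = c * ex - s * ey
        out[..., 1] = s * ex + c * ey
    elif pol.kind == "radial":
        out[..., 0] = np.cos(phi)
        out[..., 1] = np.sin(phi)
    elif pol.kind == "azimuthal":
        out[..., 0] = -np.sin(phi)
        out[..., 1] = np.cos(phi)
    else:
        raise ValueError(f"unknown polarization kind {pol.kind!r}")
    return out


def angular_grids(system: OpticalSystem, grid: SimulationGrid,
                  theta_sampling: str = "midpoint"):
    """Polar/azimuthal sampling per the discretization scheme.

    Left-endpoint rule: theta_1 = 0, step alpha/N_theta (the theta = 0
    sample carries sin(theta) = 0 weight); midpoint shifts samples by half a
    step for faster convergence.  The polar range extends to alpha + |gamma|
    for a tilted coverslip.
    """
    theta_max = system.alpha + abs(system.tilt_gamma)
    d_theta = theta_max / grid.n_theta
    d_phi = 2.0 * math.pi / grid.n_phi
    if theta_sampling == "left":
        theta = np.arange(grid.n_theta) * d_theta
    elif theta_sampling == "midpoint":
        theta = (np.arange(grid.n_theta) + 0.5) * d_theta
    else:
        raise ValueError(f"unknown theta_sampling {theta_sampling!r}")
    phi = np.arange(grid.n_phi) * d_phi
    return theta, phi, d_theta, d_phi


def assemble_pupil(beam: InputBeam, system: OpticalSystem, grid: SimulationGrid,
                   apodization: str = "sqrt_cos",
                   theta_sampling: str = "midpoint",
                   custom_mask: np.ndarray | None = None,
                   force_tilt_path: bool = False) -> PupilSample:
    """Build the full pupil sample A = gauss * apod * e^{i Phi} * e^{i M} * CW.

    With a tilted coverslip (gamma != 0) every objective-frame quantity
    (amplitude profile, apodization, aberration, mask, polarization) is
    evaluated at the back-rotated direction (theta', phi'), and amplitude is
    zeroed where the back-rotated ray leaves the pupil.  The window mask is
    applied in the unrotated (sample-side) frame.

    *custom_mask*, if given, is a square 2-D array of phase values (radians)
    over the pupil square [-1, 1]^2, sampled bilinearly (see toolkit).
    """
    theta, phi, d_theta, d_phi = angular_grids(system, grid, theta_sampling)
    th = theta[:, None]
    ph = phi[None, :]

    gamma = system.tilt_gamma
    if gamma != 0.0 or force_tilt_path:
        theta_e, phi_e, in_pupil = tilt_transform(th, ph, gamma, system)
    else:
        theta_e = np.broadcast_to(th, (theta.size, phi.size)).copy()
        phi_e = np.broadcast_to(ph, (theta.size, phi.size)).copy()
        in_pupil = theta_e <= system.alpha + 1e-12

    amp = gaussian_amplitude(theta_e, phi_e, beam, system, apodization)
    phase = np.zeros_like(amp)
    if beam.zernike:
        rho = np.clip(np.sin(theta_e) / math.sin(system.alpha), 0.0, 1.0)
        phase = phase + zernike_phase(rho, phi_e, beam.zernike)
    if beam.mask.kind in ("vortex", "ring"):
        phase = phase + phase_mask(theta_e, phi_e, beam.mask, system)
    if custom_mask is not None:
        phase = phase + _sample_custom_mask(custom_mask, theta_e, phi_e, system)

    amplitude = amp * np.exp(1j * phase)
    amplitude = amplitude * window_mask(th, system)  # sample-side aperture
    amplitude = np.where(in_pupil, amplitude, 0.0)

    pol0 = polarization_jones(phi_e, beam)
    return PupilSample(
        theta=theta, phi=phi, amplitude=amplitude, polarization0=pol0,
        theta_obj=theta_e, d_theta=d_theta, d_phi=d_phi,
    )


def _sample_custom_mask(mask: np.ndarray, theta, phi, system: OpticalSystem):
    """Bilinearly sample a user phase map given on the square [-1,1]^2 of
    pupil-radius units; directions outside the unit disk get zero phase."""
    mask = np.asarray(mask, dtype=float)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("custom phase mask must be a square 2-D array")
    u, v = _pupil_coords(theta, phi, system.alpha)
    n = mask.shape[0]
    # map u, v in [-1, 1] to fractional pixel indices
    fi = (v + 1.0) / 2.0 * (n - 1)
    fj = (u + 1.0) / 2.0 * (n - 1)
    inside = np.hypot(u, v) <= 1.0
    fi = np.clip(fi, 0, n - 1)
    fj = np.clip(fj, 0, n - 1)
    i0 = np.clip(np.floor(fi).astype(int), 0, n - 2)
    j0 = np.clip(np.floor(fj).astype(int), 0, n - 2)
    di, dj = fi - i0, fj - j0
    val = (
        mask[i0, j0] * (1 - di) * (1 - dj)
        + mask[i0 + 1, j0] * di * (1 - dj)
        + mask[i0, j0 + 1] * (1 - di) * dj
        + mask[i0 + 1, j0 + 1] * di * dj
    )
    return np.where(inside, val, 0.0)


def pupil_maps(beam: InputBeam, system: OpticalSystem, grid: SimulationGrid,
               n_pixels: int = 256):
    """Render back-pupil diagnostic maps on a Cartesian pixel grid.

    Returns a dict with 'intensity' (Gaussian profile |A|^2), 'phase_mask'
    (mask phase M) and 'aberrations' (Zernike phase Phi), each an
    (n_pixels, n_pixels) array over the pupil square; pixels outside the
    unit disk are NaN.  Mirrors the show-intensity / show-phase-mask /
    show-aberrations diagnostics.
    """
    ax = np.linspace(-1.0, 1.0, n_pixels)
    u, v = np.meshgrid(ax, ax)
    rho = np.hypot(u, v)
    inside = rho <= 1.0
    theta = np.arcsin(np.clip(rho, 0.0, 1.0) * math.sin(system.alpha))
    phi = np.arctan2(v, u)

    ox, oy = beam.offset
    intensity = np.exp(-2.0 * ((u - ox) ** 2 + (v - oy) ** 2) / beam.waist_w**2)
    if beam.mask.kind in ("vortex", "ring"):
        mphase = phase_mask(theta, phi, beam.mask, system)
    else:
        mphase = np.zeros_like(u)
    aberr = zernike_phase(np.clip(rho, 0.0, 1.0), phi, beam.zernike)

    nan = np.where(inside, 0.0, np.nan)
    return {
        "intensity": intensity + nan,
        "phase_mask": mphase + nan,
        "aberrations": aberr + nan,
    }
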