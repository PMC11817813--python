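"""Stratified immersion / coverslip / sample optics.

Snell angle chains (with complex continuation past critical angles),
single-interface Fresnel coefficients, the two-interface coverslip
transmission operator, the 3x3 polarization conversion matrix Lambda(3)
and the stratification (spherical-aberration) phase with its correction
collar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import OpticalSystem

__all__ = [
    "LayerAngles",
    "CoverslipOperator",
    "snell_chain",
    "fresnel_interface",
    "coverslip_transmission",
    "polarization_operator",
    "stratification_phase",
]


@dataclass
class LayerAngles:
    """Propagation angles in immersion (1), coverslip (2) and sample (3).

    Stored as complex sines and cosines so that evanescent rays (a layer
    sine exceeding 1) are represented by complex cosines with non-negative
    imaginary part (decaying waves for z > 0).
    """

    sin1: np.ndarray
    cos1: np.ndarray
    sin2: np.ndarray
    cos2: np.ndarray
    sin3: np.ndarray
    cos3: np.ndarray

    @property
    def theta1(self):
        return np.arcsin(self.sin1 + 0j)

    @property
    def theta2(self):
        return np.arcsin(self.sin2 + 0j)

    @property
    def theta3(self):
        return np.arcsin(self.sin3 + 0j)


def _complex_cos(sin_sq):
    """Principal square root of 1 - sin^2 with Im >= 0 (evanescent decay)."""
    cos = np.sqrt((1.0 + 0j) - sin_sq)
    # numpy's principal sqrt already gives Im >= 0 for negative real arguments;
    # enforce it explicitly for safety against -0.0 imaginary parts
    return np.where(cos.imag < 0, -cos, cos)


def snell_chain(theta1, system: OpticalSystem) -> LayerAngles:
    """Angle chain n1 sin(theta1) = n2 sin(theta2) = n3 sin(theta3).

    theta1 is the (real) incidence angle in the immersion medium; layer
    sines follow from Snell's law and cosines are complex-continued past
    total internal reflection.
    """
    theta1 = np.asarray(theta1, dtype=float)
    s1 = np.sin(theta1)
    c1 = np.cos(theta1).astype(complex)
    s2 = system.n1 * s1 / system.n2
    s3 = system.n1 * s1 / system.n3
    return LayerAngles(
        sin1=s1, cos1=c1,
        sin2=s2, cos2=_complex_cos(np.asarray(s2, dtype=complex) ** 2),
        sin3=s3, cos3=_complex_cos(np.asarray(s3, dtype=complex) ** 2),
    )


def fresnel_interface(n_in, cos_in, n_out, cos_out):
    """Single-interface Fresnel amplitude coefficients (ts, tp, rs, rp).

    Conventions (field amplitudes, complex cosines allowed):
      ts = 2 n_i c_i / (n_i c_i + n_o c_o)
      tp = 2 n_i c_i / (n_o c_i + n_i c_o)
      rs = (n_i c_i - n_o c_o) / (n_i c_i + n_o c_o)
      rp = (n_o c_i - n_i c_o) / (n_o c_i + n_i c_o)
    """
    a = n_in * cos_in
    b = n_out * cos_out
    c = n_out * cos_in
    d = n_in * cos_out
    ts = 2.0 * a / (a + b)
    tp = 2.0 * a / (c + d)
    rs = (a - b) / (a + b)
    rp = (c - d) / (c + d)
    return ts, tp, rs, rp


@dataclass
class CoverslipOperator:
    """Effective two-interface coverslip transmission per polarization."""

    Tp: np.ndarray
    Ts: np.ndarray


def coverslip_transmission(angles: LayerAngles, system: OpticalSystem,
                           wavelength: float) -> CoverslipOperator:
    """Airy summation of multiple reflections inside the coverslip:

        T = t(1) t(2) e^{i beta} / (1 + r(1) r(2) e^{2 i beta}),
        beta = k2 t cos(theta2),  k2 = 2 pi n2 / lambda,

    per polarization, with t(j), r(j) the Fresnel coefficients at the
    immersion/coverslip and coverslip/sample interfaces.  For matched
    indices this reduces to the pure propagation phase e^{i beta}.
    """
    n1, n2, n3 = system.n1, system.n2, system.n3
    ts1, tp1, rs1, rp1 = fresnel_interface(n1, angles.cos1, n2, angles.cos2)
    ts2, tp2, rs2, rp2 = fresnel_interface(n2, angles.cos2, n3, angles.cos3)
    k2 = 2.0 * math.pi * n2 / wavelength
    beta = k2 * system.thickness_t * angles.cos2
    ph = np.exp(1j * beta)
    Ts = ts1 * ts2 * ph / (1.0 + rs1 * rs2 * ph**2)
    Tp = tp1 * tp2 * ph / (1.0 + rp1 * rp2 * ph**2)
    return CoverslipOperator(Tp=Tp, Ts=Ts)


def _rot_phi(phi):
    """R_phi: rotation about the optical axis mapping (x, y) into the
    meridional (p, s) frame of a ray at azimuth phi."""
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    zero = np.zeros_like(c)
    one = np.ones_like(c)
    return np.stack(
        [
            np.stack([c, s, zero], axis=-1),
            np.stack([-s, c, zero], axis=-1),
            np.stack([zero, zero, one], axis=-1),
        ],
        axis=-2,
    ).astype(complex)


def _lens_operator(cos_t, sin_t):
    """L_theta: meridional bending of the field by the objective."""
    zero = np.zeros_like(cos_t)
    one = np.ones_like(cos_t)
    return np.stack(
        [
            np.stack([cos_t, zero, sin_t], axis=-1),
            np.stack([zero, one, zero], axis=-1),
            np.stack([-sin_t, zero, cos_t], axis=-1),
        ],
        axis=-2,
    )


def _layer_rotation(cos_t, sin_t):
    """P(l): meridional coordinate rotation in layer l (inverse of L)."""
    zero = np.zeros_like(cos_t)
    one = np.ones_like(cos_t)
    return np.stack(
        [
            np.stack([cos_t, zero, -sin_t], axis=-1),
            np.stack([zero, one, zero], axis=-1),
            np.stack([sin_t, zero, cos_t], axis=-1),
        ],
        axis=-2,
    )


def polarization_operator(theta, phi, angles: LayerAngles,
                          cs: CoverslipOperator) -> np.ndarray:
    """3x3 polarization conversion Lambda(3) from the back pupil into the
    sample medium:

        Lambda(3) = R_phi^-1 [P(3)]^-1 I(2) P(1) L_theta1 R_phi

    with I(2) = diag(Tp, Ts, Tp) carrying the coverslip transmission (and
    the s/p apodization difference).  Broadcasts over leading axes; returns
    an array of shape (..., 3, 3).  Applied to the input Jones vector P0 it
    yields the sample-space polarization P(3).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = np.broadcast(theta, phi).shape
    theta = np.broadcast_to(theta, shape)
    phi = np.broadcast_to(phi, shape)

    c1 = np.broadcast_to(angles.cos1, shape).astype(complex)
    s1 = np.broadcast_to(angles.sin1, shape).astype(complex)
    c3 = np.broadcast_to(angles.cos3, shape).astype(complex)
    s3 = np.broadcast_to(angles.sin3, shape).astype(complex)
    Tp = np.broadcast_to(cs.Tp, shape)
    Ts = np.broadcast_to(cs.Ts, shape)

    Rf = _rot_phi(phi)
    Rf_inv = np.swapaxes(Rf, -1, -2)  # rotation: inverse = transpose
    L1 = _lens_operator(c1, s1)
    P1 = _layer_rotation(c1, s1)
    P3_inv = _lens_operator(c3, s3)  # [P(3)]^-1 with the same sign convention

    I2 = np.zeros(shape + (3, 3), dtype=complex)
    I2[..., 0, 0] = Tp
    I2[..., 1, 1] = Ts
    I2[..., 2, 2] = Tp

    return Rf_inv @ P3_inv @ I2 @ P1 @ L1 @ Rf


def stratification_phase(angles: LayerAngles, system: OpticalSystem,
                         wavelength: float):
    """Spherical-aberration phase of the stratified path (radians):

        Phi(3) = k0 [ n3 d cos(theta3) - n1 (t + d) cos(theta1) ]

    independent of azimuth.  With the correction collar active the same
    expression evaluated at d = collar_depth is subtracted, so the residual
    vanishes identically when collar_depth equals the focusing depth.
    The coverslip's own propagation phase k2 t cos(theta2) lives in the
    coverslip transmission operator, not here; for matched indices the sum
    of both is zero and the focus stays at the geometrical focus.
    """
    k0 = 2.0 * math.pi / wavelength
    t, d = system.thickness_t, system.depth_d

    def phase_at(depth):
        return k0 * (system.n3 * depth * angles.cos3
                     - system.n1 * (t + depth) * angles.cos1)

    phi = phase_at(d)
    if system.collar_active:
        phi = phi - phase_at(float(system.collar_depth))
    return phi
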