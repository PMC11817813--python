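"""Independent brute-force reference implementations used as oracles.

Everything here is written from the physics directly -- scalar cmath,
explicit 3x3 list matrices, five nested loops -- and deliberately shares no
code with the vectorpsf package.
"""

import cmath
import math


def mat_mul(a, b):
    return [[sum(a[i][k] * b[k][j] for k in range(3)) for j in range(3)]
            for i in range(3)]


def mat_vec(a, v):
    return [sum(a[i][k] * v[k] for k in range(3)) for i in range(3)]


def rot_phi(phi):
    c, s = math.cos(phi), math.sin(phi)
    return [[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]]


def rot_phi_inv(phi):
    c, s = math.cos(phi), math.sin(phi)
    return [[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]


def lens_op(cos_t, sin_t):
    return [[cos_t, 0.0, sin_t], [0.0, 1.0, 0.0], [-sin_t, 0.0, cos_t]]


def layer_rot(cos_t, sin_t):
    return [[cos_t, 0.0, -sin_t], [0.0, 1.0, 0.0], [sin_t, 0.0, cos_t]]


def complex_cos_from_sin(s):
    c = cmath.sqrt(1.0 - s * s)
    if c.imag < 0:
        c = -c
    return c


def fresnel(n_i, c_i, n_o, c_o):
    ts = 2.0 * n_i * c_i / (n_i * c_i + n_o * c_o)
    tp = 2.0 * n_i * c_i / (n_o * c_i + n_i * c_o)
    rs = (n_i * c_i - n_o * c_o) / (n_i * c_i + n_o * c_o)
    rp = (n_o * c_i - n_i * c_o) / (n_o * c_i + n_i * c_o)
    return ts, tp, rs, rp


def slab_transfer_matrix_t(n1, n2, n3, cos1, cos2, cos3, k2t_cos2, pol):
    """Two-interface slab transmission via 2x2 transfer matrices."""
    if pol == "s":
        t1, _, r1, _ = fresnel(n1, cos1, n2, cos2)
        t2, _, r2, _ = fresnel(n2, cos2, n3, cos3)
    else:
        _, t1, _, r1 = fresnel(n1, cos1, n2, cos2)
        _, t2, _, r2 = fresnel(n2, cos2, n3, cos3)
    e_m = cmath.exp(-1j * k2t_cos2)
    e_p = cmath.exp(1j * k2t_cos2)
    # D_j = (1/t_j) [[1, r_j], [r_j, 1]], P = diag(e^-i beta, e^+i beta)
    m00 = (1.0 * e_m * 1.0 + r1 * e_p * r2) / (t1 * t2)
    return 1.0 / m00


def naive_focal_field(xs, ys, zs, *, na, n1, n2, n3, t, d, lam,
                      n_theta, n_phi, epsilon=0.0, psi=0.0, waist=1.0,
                      offset=(0.0, 0.0), vortex_q=None, zernike=(),
                      sampling="midpoint", apod="sqrt_cos"):
    """Direct five-nested-loop Debye-Wolf summation.

    zernike entries are (mode_name, coeff) with hand-expanded polynomials.
    Returns E[c][ix][iy][iz] as nested lists of complex.
    """
    alpha = math.asin(na / n1)
    d_theta = alpha / n_theta
    d_phi = 2.0 * math.pi / n_phi
    k0 = 2.0 * math.pi / lam
    pol_in = [math.cos(psi) * math.cos(epsilon) - math.sin(psi) * 1j * math.sin(epsilon),
              math.sin(psi) * math.cos(epsilon) + math.cos(psi) * 1j * math.sin(epsilon),
              0.0]

    E = [[[[0j, 0j, 0j] for _ in zs] for _ in ys] for _ in xs]
    for m in range(n_theta):
        theta = (m + 0.5) * d_theta if sampling == "midpoint" else m * d_theta
        s1 = math.sin(theta)
        c1 = math.cos(theta)
        s2 = n1 * s1 / n2
        s3 = n1 * s1 / n3
        c2 = complex_cos_from_sin(s2)
        c3 = complex_cos_from_sin(s3)
        ts1, tp1, rs1, rp1 = fresnel(n1, c1, n2, c2)
        ts2, tp2, rs2, rp2 = fresnel(n2, c2, n3, c3)
        beta = 2.0 * math.pi * n2 / lam * t * c2
        eb = cmath.exp(1j * beta)
        Ts = ts1 * ts2 * eb / (1.0 + rs1 * rs2 * eb * eb)
        Tp = tp1 * tp2 * eb / (1.0 + rp1 * rp2 * eb * eb)
        strat = k0 * (n3 * d * c3 - n1 * (t + d) * c1)
        rho = s1 / math.sin(alpha)
        apod_f = math.sqrt(c1) if apod == "sqrt_cos" else c1
        for n in range(n_phi):
            phi = n * d_phi
            u = rho * math.cos(phi) - offset[0]
            v = rho * math.sin(phi) - offset[1]
            amp = math.exp(-(u * u + v * v) / waist**2) * apod_f
            phase = 0.0
            if vortex_q is not None:
                phase += vortex_q * phi
            for mode, coeff in zernike:
                if mode == "defocus":  # (2, 0)
                    phase += coeff * (2.0 * rho * rho - 1.0)
                elif mode == "coma_x":  # (3, 1)
                    phase += coeff * (3.0 * rho**3 - 2.0 * rho) * math.cos(phi)
                elif mode == "astig_oblique":  # (2, -2)
                    phase += coeff * rho * rho * math.sin(2.0 * phi)
                else:
                    raise ValueError(mode)
            a0 = amp * cmath.exp(1j * phase)

            lam3 = mat_mul(
                rot_phi_inv(phi),
                mat_mul(
                    lens_op(c3, s3),  # [P(3)]^-1
                    mat_mul(
                        [[Tp, 0, 0], [0, Ts, 0], [0, 0, Tp]],
                        mat_mul(layer_rot(c1, s1),
                                mat_mul(lens_op(c1, s1), rot_phi(phi))),
                    ),
                ),
            )
            vec = mat_vec(lam3, pol_in)
            w = a0 * cmath.exp(1j * strat) * s1 * d_theta * d_phi
            kx = k0 * n1 * s1 * math.cos(phi)
            ky = k0 * n1 * s1 * math.sin(phi)
            kz = k0 * n3 * c3
            for ix, x in enumerate(xs):
                for iy, y in enumerate(ys):
                    lateral = cmath.exp(1j * (kx * x + ky * y))
                    for iz, z in enumerate(zs):
                        ph = w * lateral * cmath.exp(1j * kz * z)
                        vox = E[ix][iy][iz]
                        vox[0] += vec[0] * ph
                        vox[1] += vec[1] * ph
                        vox[2] += vec[2] * ph
    pref = -1j * k0 * n1 / (2.0 * math.pi)
    for ix in range(len(xs)):
        for iy in range(len(ys)):
            for iz in range(len(zs)):
                E[ix][iy][iz] = [pref * c for c in E[ix][iy][iz]]
    return E


def naive_convolve_same(sample, kernel):
    """Zero-padded direct-sum 3-D convolution cropped to the sample shape,
    matching scipy's mode='same' centering."""
    import numpy as np

    sx, sy, sz = sample.shape
    kx, ky, kz = kernel.shape
    out = np.zeros((sx, sy, sz))
    ox, oy, oz = (kx - 1) // 2, (ky - 1) // 2, (kz - 1) // 2
    for i in range(sx):
        for j in range(sy):
            for k in range(sz):
                acc = 0.0
                for a in range(kx):
                    for b in range(ky):
                        for c in range(kz):
                            ii, jj, kk = i - a + ox, j - b + oy, k - c + oz
                            if 0 <= ii < sx and 0 <= jj < sy and 0 <= kk < sz:
                                acc += sample[ii, jj, kk] * kernel[a, b, c]
                out[i, j, k] = acc
    return out
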