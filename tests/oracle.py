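"""Independent brute-force oracle: 4x4 Hilbert-space density-matrix
integrator.

Builds the Hamiltonian directly from Pauli matrices and integrates the
master equation with an adaptive Runge-Kutta solver (no Liouville-space
superoperator, no matrix exponential), so it shares nothing with the
production engine beyond the operator definitions.  Relaxation applies
the same phenomenological model -- per-operator decay plus longitudinal
cross relaxation and recovery -- expressed through projections of the
density matrix onto the product-operator basis.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

_IX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_IY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_IZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_E2 = np.eye(2, dtype=complex)


def _op(h, n, scale=1.0):
    return scale * np.kron(h, n)


_BASIS = [
    _op(_E2, _E2, 0.5),
    _op(_IX, _E2), _op(_IY, _E2), _op(_IZ, _E2),
    _op(_E2, _IX), _op(_E2, _IY), _op(_E2, _IZ),
    _op(_IX, _IZ, 2), _op(_IY, _IZ, 2), _op(_IZ, _IX, 2), _op(_IZ, _IY, 2),
    _op(_IX, _IX, 2), _op(_IX, _IY, 2), _op(_IY, _IX, 2), _op(_IY, _IY, 2),
    _op(_IZ, _IZ, 2),
]


def hamiltonian(system, fields=()):
    """Rotating-frame Hamiltonian in angular-frequency units."""
    h = 2 * np.pi * system.offset_H * _op(_IZ, _E2)
    h = h + 2 * np.pi * system.offset_N * _op(_E2, _IZ)
    h = h + 2 * np.pi * system.J_NH * _op(_IZ, _IZ)
    for f in fields:
        w1 = 2 * np.pi * f.amplitude
        ph = np.deg2rad(f.phase)
        axis = np.cos(ph) * _IX + np.sin(ph) * _IY
        carrier = 2 * np.pi * f.carrier_offset * _IZ
        if f.channel == "H":
            h = h + np.kron(w1 * axis + carrier, _E2)
        else:
            h = h + np.kron(_E2, w1 * axis + carrier)
    return h


def _rates(system):
    r = np.zeros(16)
    r[[1, 2]] = system.R2_H
    r[3] = system.R1_H
    r[[4, 5]] = system.R2_N
    r[6] = system.R1_N
    r[[7, 8]] = system.R2_H + system.R1_N
    r[[9, 10]] = system.R1_H + system.R2_N
    r[[11, 12, 13, 14]] = system.R2_H + system.R2_N
    r[15] = system.R1_H + system.R1_N
    return r


def integrate(system, rho0, segments, include_recovery=True,
              rtol=1e-12, atol=1e-13):
    """Integrate d rho/dt = -i[H, rho] + relaxation over (fields, t) legs.

    ``rho0`` is a 4x4 density operator (e.g. from basis coefficients);
    returns the final 4x4 matrix.
    """
    rates = _rates(system)
    sig = np.sign(system.gamma_ratio) * system.sigma_HN
    hz_eq, nz_eq = 1.0, 1.0 / abs(system.gamma_ratio)

    def relaxation(rho):
        coeff = np.array([np.trace(b @ rho).real for b in _BASIS])
        out = np.zeros((4, 4), dtype=complex)
        for i, b in enumerate(_BASIS):
            out -= rates[i] * coeff[i] * b
        # Solomon coupling and (optional) return to thermal equilibrium
        dh = coeff[3] - (hz_eq if include_recovery else 0.0)
        dn = coeff[6] - (nz_eq if include_recovery else 0.0)
        if include_recovery:
            out += rates[3] * hz_eq * _BASIS[3]
            out += rates[6] * nz_eq * _BASIS[6]
        out -= sig * dn * _BASIS[3]
        out -= sig * dh * _BASIS[6]
        return out

    rho = np.asarray(rho0, dtype=complex)
    for fields, t in segments:
        if t == 0:
            continue
        h = hamiltonian(system, fields)

        def rhs(_, y):
            r = y.reshape(4, 4)
            d = -1j * (h @ r - r @ h) + relaxation(r)
            return d.ravel()

        sol = solve_ivp(rhs, (0.0, t), rho.ravel(), method="DOP853",
                        rtol=rtol, atol=atol)
        rho = sol.y[:, -1].reshape(4, 4)
    return rho


def coefficients(rho):
    """Project a 4x4 density operator onto the 16 product operators."""
    return np.array([np.trace(b @ rho).real for b in _BASIS])


def matrix_from_coefficients(coeffs):
    rho = np.zeros((4, 4), dtype=complex)
    for c, b in zip(coeffs, _BASIS):
        rho = rho + c * b
    return rho
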