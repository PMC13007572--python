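"""Product-operator basis for the two-spin-1/2 (amide 1H-15N) system.

The 16 Hermitian operators {E/2, Hx..Hz, Nx..Nz, 2HiNj} are orthonormal
under the Hilbert-Schmidt inner product Tr(A B) on the 4-dimensional
Hilbert space, so density operators are represented by real coefficient
vectors and every superoperator by a real 16x16 matrix.
"""
from __future__ import annotations

import numpy as np

# Single-spin operators (hbar = 1).
_IX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_IY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_E = np.eye(2, dtype=complex)

#: Basis labels, in the fixed canonical order used throughout the package.
LABELS: tuple[str, ...] = (
    "E/2", "Hx", "Hy", "Hz", "Nx", "Ny", "Nz",
    "2HxNz", "2HyNz", "2HzNx", "2HzNy",
    "2HxNx", "2HxNy", "2HyNx", "2HyNy", "2HzNz",
)

INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}

N_OPS = 16


def _kron(h: np.ndarray, n: np.ndarray, scale: float = 1.0) -> np.ndarray:
    return scale * np.kron(h, n)


#: The basis as 4x4 matrices (1H factor first in the Kronecker product).
MATRICES: tuple[np.ndarray, ...] = (
    _kron(_E, _E, 0.5),
    _kron(_IX, _E), _kron(_IY, _E), _kron(_IZ, _E),
    _kron(_E, _IX), _kron(_E, _IY), _kron(_E, _IZ),
    _kron(_IX, _IZ, 2.0), _kron(_IY, _IZ, 2.0),
    _kron(_IZ, _IX, 2.0), _kron(_IZ, _IY, 2.0),
    _kron(_IX, _IX, 2.0), _kron(_IX, _IY, 2.0),
    _kron(_IY, _IX, 2.0), _kron(_IY, _IY, 2.0),
    _kron(_IZ, _IZ, 2.0),
)

# Indices of operators with non-zero coherence order on each channel.
TRANSVERSE_H: tuple[int, ...] = (1, 2, 7, 8, 11, 12, 13, 14)
TRANSVERSE_N: tuple[int, ...] = (4, 5, 9, 10, 11, 12, 13, 14)
LONGITUDINAL: tuple[int, ...] = (0, 3, 6, 15)


def coefficients_to_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Assemble the 4x4 density operator from basis coefficients."""
    rho = np.zeros((4, 4), dtype=complex)
    for c, op in zip(coeffs, MATRICES):
        rho += c * op
    return rho


def matrix_to_coefficients(rho: np.ndarray) -> np.ndarray:
    """Project a 4x4 operator onto the basis (real parts of Tr(B_i rho))."""
    return np.array([np.trace(op @ rho).real for op in MATRICES])


def commutator_superoperator(hamiltonian: np.ndarray) -> np.ndarray:
    """Real 16x16 matrix of rho -> -i[H, rho] in the basis.

    H must be Hermitian (angular-frequency units); the result is then
    real and antisymmetric, generating a rotation of the coefficient
    vector.
    """
    gen = np.empty((N_OPS, N_OPS))
    for j, bj in enumerate(MATRICES):
        com = -1j * (hamiltonian @ bj - bj @ hamiltonian)
        for i, bi in enumerate(MATRICES):
            gen[i, j] = np.trace(bi @ com).real
    return gen


def single_spin_hamiltonian(channel: str, x: float, y: float, z: float) -> np.ndarray:
    """Hamiltonian x*Ix + y*Iy + z*Iz on one channel (angular units)."""
    op = x * _IX + y * _IY + z * _IZ
    if channel == "H":
        return np.kron(op, _E)
    if channel == "N":
        return np.kron(_E, op)
    raise ValueError(f"unknown channel {channel!r}")


def j_coupling_hamiltonian(j_hz: float) -> np.ndarray:
    """Weak (secular) scalar coupling 2*pi*J Hz*Nz for heteronuclei."""
    return 2.0 * np.pi * j_hz * np.kron(_IZ, _IZ)
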