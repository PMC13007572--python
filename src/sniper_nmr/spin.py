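"""Two-spin Liouville-space engine for selective amide 1H-15N experiments.

The density operator of a weakly coupled 1H-15N pair is expanded in the
16 product operators (see :mod:`sniper_nmr.basis`); its dynamics under
offsets, the one-bond scalar coupling, rf irradiation, phenomenological
relaxation and (optionally) first-order chemical exchange between several
chemical states is a linear inhomogeneous system

    d s / dt = G s + b,

propagated exactly over piecewise-constant segments by the matrix
exponential of the augmented generator.  The affine part ``b`` drives the
longitudinal terms back to thermal equilibrium, which is what the
steady-state heteronuclear nOe measurement relies on.

Magnetizations are expressed per channel in units of that channel's own
equilibrium polarization sign, so both ``Hz`` and ``Nz`` are positive at
equilibrium; with a negative gyromagnetic ratio for 15N the Solomon
cross-relaxation coupling then carries a factor ``sign(gamma_ratio)``
(see docs/methods.md).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import basis

__all__ = [
    "SpinSystem", "ExchangeModel", "RfField", "StateVector", "Generator",
    "equilibrium_state", "liouvillian", "evolve", "apply_ideal_pulse",
    "purge_transverse",
]

#: Signed gyromagnetic ratio gamma_H / gamma_N for 1H / 15N.
DEFAULT_GAMMA_RATIO = -9.87


class PhysicalityWarning(UserWarning):
    """A parameter set is outside the usual physically meaningful range."""


@dataclass
class SpinSystem:
    """Amide 1H-15N spin pair: offsets, coupling and relaxation rates.

    Parameters
    ----------
    offset_H, offset_N : float
        Rotating-frame offsets of the two spins from their carriers, Hz.
    J_NH : float
        One-bond scalar coupling, Hz (~92 Hz for backbone amides).
    R1_H, R2_H, R1_N, R2_N : float
        Longitudinal / transverse auto-relaxation rates, 1/s.
    sigma_HN : float
        Longitudinal 1H-15N cross-relaxation rate, 1/s (may be negative).
    gamma_ratio : float
        Signed gyromagnetic ratio gamma_H / gamma_N.
    """

    offset_H: float = 0.0
    offset_N: float = 0.0
    J_NH: float = 92.0
    R1_H: float = 0.0
    R2_H: float = 0.0
    R1_N: float = 0.0
    R2_N: float = 0.0
    sigma_HN: float = 0.0
    gamma_ratio: float = DEFAULT_GAMMA_RATIO

    def __post_init__(self) -> None:
        for name in ("R1_H", "R2_H", "R1_N", "R2_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma_ratio == 0:
            raise ValueError("gamma_ratio must be non-zero")
        if self.R2_H < self.R1_H / 2 or self.R2_N < self.R1_N / 2:
            warnings.warn("R2 < R1/2 is unphysical for dipolar/CSA relaxation",
                          PhysicalityWarning, stacklevel=2)
        bound = np.sqrt(self.R1_H * self.R1_N)
        if abs(self.sigma_HN) > bound + 1e-12:
            warnings.warn("|sigma_HN| exceeds sqrt(R1_H*R1_N)",
                          PhysicalityWarning, stacklevel=2)

    def replace(self, **kwargs) -> "SpinSystem":
        """Return a copy with the given fields overridden."""
        params = {k: getattr(self, k) for k in (
            "offset_H", "offset_N", "J_NH", "R1_H", "R2_H", "R1_N", "R2_N",
            "sigma_HN", "gamma_ratio")}
        params.update(kwargs)
        return SpinSystem(**params)


@dataclass
class ExchangeModel:
    """First-order chemical exchange between chemical states.

    ``states`` holds per-state ``(offset_N, offset_H, population)``;
    ``rate_matrix`` K (1/s) acts on the population vector, dP/dt = K P,
    with columns summing to zero.  Detailed balance with the stated
    populations is required so the populations are the kinetic steady
    state.
    """

    states: list[tuple[float, float, float]]
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        k = len(self.states)
        if self.rate_matrix.shape != (k, k):
            raise ValueError("rate_matrix shape must match number of states")
        pops = self.populations
        if np.any(pops <= 0) or abs(pops.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be positive and sum to 1")
        if np.max(np.abs(self.rate_matrix.sum(axis=0))) > 1e-9 * max(
                1.0, np.max(np.abs(self.rate_matrix))):
            raise ValueError("rate_matrix columns must sum to zero")
        for i in range(k):
            for j in range(i + 1, k):
                if abs(self.rate_matrix[i, j] * pops[j]
                       - self.rate_matrix[j, i] * pops[i]) > 1e-9 * max(
                           1.0, np.max(np.abs(self.rate_matrix))):
                    raise ValueError("rate_matrix violates detailed balance")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def populations(self) -> np.ndarray:
        return np.array([s[2] for s in self.states])

    @classmethod
    def two_site(cls, offset_N_a: float, offset_N_b: float, k_ex: float,
                 p_a: float = 0.5, offset_H_a: float = 0.0,
                 offset_H_b: float = 0.0) -> "ExchangeModel":
        """Symmetrically parameterized two-site exchange.

        ``k_ex = k_ab + k_ba`` is the total exchange rate; individual
        rates follow from the populations (k_ab = k_ex * p_b, etc.).
        """
        p_b = 1.0 - p_a
        k_ab, k_ba = k_ex * p_b, k_ex * p_a
        rates = np.array([[-k_ab, k_ba], [k_ab, -k_ba]])
        return cls(states=[(offset_N_a, offset_H_a, p_a),
                           (offset_N_b, offset_H_b, p_b)],
                   rate_matrix=rates)


@dataclass
class RfField:
    """A continuous rf irradiation on one channel.

    ``amplitude`` is the nutation frequency omega_1/2pi in Hz, ``phase``
    in degrees (0 = x, 90 = y), ``carrier_offset`` shifts the irradiation
    frequency from the channel carrier (Hz).
    """

    channel: str
    amplitude: float
    phase: float = 0.0
    carrier_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in ("H", "N"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.amplitude < 0:
            raise ValueError("rf amplitude must be >= 0")


class StateVector:
    """Real coefficients over the product-operator basis.

    With ``n_states > 1`` (chemical exchange) the 16-coefficient block is
    replicated per chemical state; block ``k`` starts at ``16 * k``.
    """

    def __init__(self, coefficients: np.ndarray, n_states: int = 1):
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.size != basis.N_OPS * n_states:
            raise ValueError("coefficient length must be 16 * n_states")
        self.coefficients = coefficients.copy()
        self.n_states = n_states

    @classmethod
    def zero(cls, n_states: int = 1) -> "StateVector":
        return cls(np.zeros(basis.N_OPS * n_states), n_states)

    @classmethod
    def from_operators(cls, n_states: int = 1, **ops: float) -> "StateVector":
        s = cls.zero(n_states)
        for name, value in ops.items():
            for k in range(n_states):
                s.coefficients[16 * k + basis.INDEX[name]] = value
        return s

    def copy(self) -> "StateVector":
        return StateVector(self.coefficients, self.n_states)

    def __getitem__(self, label: str) -> float:
        """Coefficient of an operator, summed over chemical states."""
        i = basis.INDEX[label]
        return float(sum(self.coefficients[16 * k + i]
                         for k in range(self.n_states)))

    def state_block(self, k: int) -> np.ndarray:
        return self.coefficients[16 * k:16 * (k + 1)]

    def non_identity_norm(self) -> float:
        mask = np.ones(self.coefficients.size, dtype=bool)
        mask[::16] = False
        return float(np.linalg.norm(self.coefficients[mask]))


@dataclass
class Generator:
    """Piecewise-constant generator: ds/dt = matrix @ s + affine."""

    matrix: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]
    n_states: int = 1
    _aug_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.zeros(self.matrix.shape[0])

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def propagator(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(P, c) with s(t) = P s(0) + c, from the augmented exponential."""
        key = float(t)
        if key not in self._aug_cache:
            n = self.dim
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = self.matrix
            aug[:n, n] = self.affine
            full = expm(aug * t)
            self._aug_cache[key] = (full[:n, :n], full[:n, n])
        return self._aug_cache[key]


def equilibrium_state(system: SpinSystem,
                      exchange: ExchangeModel | None = None) -> StateVector:
    """Thermal equilibrium: Hz = 1 and Nz = 1/|gamma_ratio| by convention.

    With chemical exchange each state's block is weighted by its
    population.
    """
    nz = 1.0 / abs(system.gamma_ratio)
    if exchange is None:
        return StateVector.from_operators(Hz=1.0, Nz=nz)
    s = StateVector.zero(exchange.n_states)
    for k, (_, _, pop) in enumerate(exchange.states):
        s.coefficients[16 * k + basis.INDEX["Hz"]] = pop
        s.coefficients[16 * k + basis.INDEX["Nz"]] = pop * nz
    return s


def _single_state_generator(system: SpinSystem, fields: list[RfField],
                            offset_H: float, offset_N: float,
                            include_relaxation: bool = True) -> np.ndarray:
    h = basis.single_spin_hamiltonian("H", 0.0, 0.0, 2 * np.pi * offset_H)
    h += basis.single_spin_hamiltonian("N", 0.0, 0.0, 2 * np.pi * offset_N)
    h += basis.j_coupling_hamiltonian(system.J_NH)
    for f in fields:
        w1 = 2 * np.pi * f.amplitude
        ph = np.deg2rad(f.phase)
        h += basis.single_spin_hamiltonian(
            f.channel, w1 * np.cos(ph), w1 * np.sin(ph),
            2 * np.pi * f.carrier_offset)
    gen = basis.commutator_superoperator(h)
    if include_relaxation:
        gen += _relaxation_matrix(system)
    return gen


def _relaxation_matrix(system: SpinSystem) -> np.ndarray:
    rates = np.zeros(basis.N_OPS)
    r1h, r2h, r1n, r2n = system.R1_H, system.R2_H, system.R1_N, system.R2_N
    rates[[1, 2]] = r2h
    rates[3] = r1h
    rates[[4, 5]] = r2n
    rates[6] = r1n
    rates[[7, 8]] = r2h + r1n      # 2HxNz, 2HyNz
    rates[[9, 10]] = r1h + r2n     # 2HzNx, 2HzNy
    rates[[11, 12, 13, 14]] = r2h + r2n
    rates[15] = r1h + r1n
    rel = -np.diag(rates)
    # Solomon cross relaxation Hz <-> Nz; sign(gamma_ratio) accounts for
    # expressing each channel's Mz in units of its own equilibrium sign.
    sig = np.sign(system.gamma_ratio) * system.sigma_HN
    rel[3, 6] -= sig
    rel[6, 3] -= sig
    return rel


def liouvillian(system: SpinSystem, fields: list[RfField] | None = None,
                exchange: ExchangeModel | None = None,
                include_recovery: bool = True,
                include_relaxation: bool = True) -> Generator:
    """Assemble the full generator for a constant irradiation segment.

    The coherent part (offsets, J coupling, rf) is antisymmetric and
    norm-conserving; relaxation adds the phenomenological diagonal decay
    plus the longitudinal cross-relaxation coupling; exchange couples the
    chemical-state blocks identically for every basis operator.  With
    ``include_recovery`` the affine term returns Hz/Nz to their thermal
    values, making equilibrium a fixed point of free evolution.
    """
    fields = fields or []
    if exchange is None:
        g = _single_state_generator(system, fields, system.offset_H,
                                    system.offset_N, include_relaxation)
        n_states = 1
    else:
        k = exchange.n_states
        g = np.zeros((16 * k, 16 * k))
        for i, (off_n, off_h, _) in enumerate(exchange.states):
            g[16 * i:16 * (i + 1), 16 * i:16 * (i + 1)] = \
                _single_state_generator(system, fields, off_h, off_n,
                                        include_relaxation)
        g += np.kron(exchange.rate_matrix, np.eye(basis.N_OPS))
        n_states = k
    affine = np.zeros(g.shape[0])
    if include_recovery and include_relaxation:
        s_eq = equilibrium_state(system, exchange)
        rel = _relaxation_matrix(system)
        for k in range(n_states):
            affine[16 * k:16 * (k + 1)] = -rel @ s_eq.coefficients[
                16 * k:16 * (k + 1)]
    return Generator(matrix=g, affine=affine, n_states=n_states)


def evolve(state: StateVector, generator: Generator, t: float) -> StateVector:
    """Propagate a state for time t (s) under a constant generator."""
    if t < 0:
        raise ValueError("evolution time must be >= 0")
    if generator.dim != state.coefficients.size:
        raise ValueError("generator and state dimensions differ")
    p, c = generator.propagator(t)
    return StateVector(p @ state.coefficients + c, state.n_states)


def _rotation_superoperator(channel: str, flip_deg: float,
                            phase_deg: float) -> np.ndarray:
    ph = np.deg2rad(phase_deg)
    h = basis.single_spin_hamiltonian(channel, np.cos(ph), np.sin(ph), 0.0)
    return expm(basis.commutator_superoperator(h) * np.deg2rad(flip_deg))


def apply_ideal_pulse(state: StateVector, channel: str, flip: float,
                      phase: float = 0.0) -> StateVector:
    """Instantaneous hard pulse: right-handed rotation on one channel.

    A 90-degree pulse of phase x takes Mz to -My.
    """
    rot = _rotation_superoperator(channel, flip, phase)
    if state.n_states > 1:
        rot = np.kron(np.eye(state.n_states), rot)
    return StateVector(rot @ state.coefficients, state.n_states)


def purge_transverse(state: StateVector, channel: str = "both") -> StateVector:
    """Idealized purge gradient: zero all coherences on the channel(s).

    Longitudinal terms (Hz, Nz, 2HzNz) and the identity are untouched.
    """
    if channel == "both":
        idx = sorted(set(basis.TRANSVERSE_H) | set(basis.TRANSVERSE_N))
    elif channel == "H":
        idx = list(basis.TRANSVERSE_H)
    elif channel == "N":
        idx = list(basis.TRANSVERSE_N)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    out = state.copy()
    for k in range(state.n_states):
        out.coefficients[[16 * k + i for i in idx]] = 0.0
    return out
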