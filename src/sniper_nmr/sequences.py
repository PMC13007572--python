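"""Selective 1D amide relaxation experiments assembled from building blocks.

Each experiment follows the same skeleton: equilibrium 1H polarization is
converted to in-phase 15N by a matched selective transfer (simultaneous
Hartmann-Hahn irradiation or consecutive single-field periods), stored
longitudinally, sharpened by a chemical-shift-selective filter whose
first 90 may be a long shaped pulse, relaxation-encoded (longitudinal
delay, constant-time spin-lock, proton saturation or exchange mixing),
and read out as in-phase transverse 1H after a back transfer.  Gradients
are idealized as projections onto the longitudinal subspace; detection
is the in-phase transverse amplitude at acquisition start (no lineshape
is needed for relaxation quantification).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .analysis import Profile
from .shapes import Shape, shape_propagator
from .spin import (
    ExchangeModel, RfField, SpinSystem, StateVector, apply_ideal_pulse,
    equilibrium_state, evolve, liouvillian, purge_transverse,
)

__all__ = [
    "SequenceTiming", "SpinLockParams", "DecayCurve",
    "haha_transfer", "rsfpt_transfer", "optimal_transfer_duration",
    "cssf_filter", "run_r1_experiment", "run_r1rho_experiment",
    "run_noe_experiment", "run_zz_exchange", "response_profile",
    "sniper_signal", "transfer_signal",
]


class TimingWarning(UserWarning):
    """A delay lies outside its usual operating range."""


@dataclass
class SequenceTiming:
    """Delays of the selective experiments (all seconds).

    ``zeta`` is the selective-filter delay (0-5 ms), ``delta`` the
    refocusing delay of the consecutive-transfer variant (5-40 ms);
    ``transfer_duration`` of ``None`` means use the numerically found
    optimum for the matched transfer.
    """

    zeta: float = 0.002
    delta: float = 0.010
    transfer_duration: float | None = None
    ct_relax_time: float = 0.25
    relax_delays: list[float] | None = None
    noe_saturation_time: float = 4.0

    def __post_init__(self) -> None:
        for name in ("zeta", "delta", "ct_relax_time",
                     "noe_saturation_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transfer_duration is not None and self.transfer_duration < 0:
            raise ValueError("transfer_duration must be >= 0")
        if self.zeta > 0.005:
            warnings.warn("zeta above 5 ms is outside the usual range",
                          TimingWarning, stacklevel=2)
        if not 0.005 <= self.delta <= 0.040:
            warnings.warn("delta outside the usual 5-40 ms range",
                          TimingWarning, stacklevel=2)
        if self.relax_delays is not None:
            self.relax_delays = [float(t) for t in self.relax_delays]
            if any(t < 0 for t in self.relax_delays):
                raise ValueError("relaxation delays must be >= 0")


@dataclass
class SpinLockParams:
    """On- or off-resonance 15N spin lock (amplitude and offset in Hz)."""

    amplitude: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("spin-lock amplitude must be > 0")

    @property
    def theta(self) -> float:
        """Tilt of the effective field from z, degrees (90 on-resonance)."""
        return float(np.degrees(np.arctan2(self.amplitude, self.offset)))


@dataclass
class DecayCurve:
    """Relaxation-delay series with intensities (arbitrary units)."""

    delays: np.ndarray
    intensities: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size < 2:
            raise ValueError("a decay curve needs at least 2 points")
        if self.delays.size != self.intensities.size:
            raise ValueError("delays and intensities lengths differ")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")


# ---------------------------------------------------------------------------
# Transfer elements

def haha_transfer(system: SpinSystem, amplitude: float, duration: float,
                  exchange: ExchangeModel | None = None) -> float:
    """Simultaneous matched-irradiation in-phase transfer efficiency.

    Starts from in-phase 1H along the lock axis, applies equal-amplitude
    x-phase irradiation on both channels, and returns the in-phase 15N
    fraction.  Maximal on-resonance transfer needs omega_1 = J_NH/2 and a
    duration near 3/(pi J); use :func:`optimal_transfer_duration`.
    """
    if duration <= 0:
        raise ValueError("transfer duration must be > 0")
    s = _transfer_start(exchange)
    s = _apply_haha(s, system, amplitude, duration, exchange)
    return s["Nx"]


def rsfpt_transfer(system: SpinSystem, amplitude: float,
                   timing: SequenceTiming | None = None,
                   exchange: ExchangeModel | None = None) -> float:
    """Consecutive single-field matched-transfer efficiency.

    A 1H-only matched lock converts in-phase 1H into two-spin
    longitudinal order (complete at tau = 1/(J sqrt 2) when
    omega_1 = J_NH/2), which survives a purge and the refocusing delay,
    and a 15N-only lock then converts it to in-phase 15N.
    """
    timing = timing or SequenceTiming()
    s = _transfer_start(exchange)
    s = _apply_rsfpt(s, system, amplitude, timing, exchange)
    return s["Nx"]


def _transfer_start(exchange: ExchangeModel | None) -> StateVector:
    if exchange is None:
        return StateVector.from_operators(Hx=1.0)
    s = StateVector.zero(exchange.n_states)
    for k, (_, _, pop) in enumerate(exchange.states):
        s.coefficients[16 * k + 1] = pop
    return s


def _apply_haha(state, system, amplitude, duration, exchange=None):
    gen = liouvillian(system, [RfField("H", amplitude),
                               RfField("N", amplitude)], exchange)
    return evolve(state, gen, duration)


def _apply_rsfpt(state, system, amplitude, timing, exchange=None):
    tau = (timing.transfer_duration / 2.0 if timing.transfer_duration
           else 1.0 / (system.J_NH * np.sqrt(2.0)))
    gen_h = liouvillian(system, [RfField("H", amplitude)], exchange)
    gen_n = liouvillian(system, [RfField("N", amplitude)], exchange)
    s = evolve(state, gen_h, tau)
    s = purge_transverse(s, "both")
    s = evolve(s, liouvillian(system, [], exchange), timing.delta)
    return evolve(s, gen_n, tau)


def optimal_transfer_duration(system: SpinSystem, amplitude: float,
                              kind: str = "haha") -> float:
    """Duration maximizing the on-resonance in-phase transfer."""
    sys0 = system.replace(offset_H=0.0, offset_N=0.0)
    if kind == "rsfpt":
        return 2.0 / (sys0.J_NH * np.sqrt(2.0))

    def neg_eff(t):
        return -haha_transfer(sys0, amplitude, t)

    res = minimize_scalar(neg_eff, bounds=(0.2 / sys0.J_NH, 2.0 / sys0.J_NH),
                          method="bounded",
                          options={"xatol": 1e-6 / sys0.J_NH})
    return float(res.x)


# ---------------------------------------------------------------------------
# Chemical-shift-selective filter

def _apply_cssf(state, system, excitation, zeta,
                decoupling_amplitude=2000.0, exchange=None):
    """90y-equivalent excitation, zeta precession under CW decoupling,
    hard 90-y back-rotation, purge.  Passes cos(2 pi dnu zeta) of Nz for
    ideal pulses."""
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if excitation is None or excitation == "ideal":
        s = apply_ideal_pulse(state, "N", 90.0, 90.0)
    elif isinstance(excitation, Shape):
        s = _apply_shape(state, system, excitation,
                         decoupling_amplitude, exchange)
    else:
        raise TypeError("excitation must be 'ideal', None or a Shape")
    fields = ([RfField("H", decoupling_amplitude)]
              if decoupling_amplitude > 0 else [])
    gen = liouvillian(system, fields, exchange)
    s = evolve(s, gen, zeta)
    s = apply_ideal_pulse(s, "N", 90.0, -90.0)
    return purge_transverse(s, "both")


def _apply_shape(state, system, shape, decoupling_amplitude, exchange=None):
    """Shaped 15N pulse (excitation along +x) during 1H CW decoupling."""
    if exchange is None:
        p, c = shape_propagator(system, shape, phase_offset=90.0,
                                decoupling_amplitude=decoupling_amplitude)
        return StateVector(p @ state.coefficients + c, 1)
    s = state
    for frac, ph in shape.slices:
        fields = [RfField("N", shape.peak_amplitude * frac, ph + 90.0)]
        if decoupling_amplitude > 0:
            fields.append(RfField("H", decoupling_amplitude))
        gen = liouvillian(system, fields, exchange)
        s = evolve(s, gen, shape.dt)
    return s


def cssf_filter(system: SpinSystem, excitation, zeta: float,
                decoupling_amplitude: float = 2000.0) -> float:
    """Longitudinal 15N fraction surviving the selective filter.

    Applies excitation (hard 90 or shaped pulse), a zeta free-precession
    period under proton CW decoupling, the hard back-rotation and an
    idealized purge to a pure Nz state; returns the retained Nz.  With
    ideal pulses and no relaxation this is cos(2 pi offset_N zeta), so
    resonances 1/(4 zeta) Hz off the carrier are removed.
    """
    s = StateVector.from_operators(Nz=1.0)
    s = _apply_cssf(s, system, excitation, zeta, decoupling_amplitude)
    return s["Nz"]


# ---------------------------------------------------------------------------
# Full experiments

def _prepare_selected_nz(system, shape, timing, transfer="haha",
                         amplitude=None, decoupling_amplitude=2000.0,
                         exchange=None):
    """Equilibrium -> selective transfer -> store -> selective filter.

    Returns the state after the filter's purge (signal on Nz) and the
    transfer parameters used, so the readout can mirror them.
    """
    amplitude = system.J_NH / 2.0 if amplitude is None else amplitude
    duration = timing.transfer_duration or optimal_transfer_duration(
        system, amplitude)
    s = equilibrium_state(system, exchange)
    s = apply_ideal_pulse(s, "H", 90.0, 90.0)        # Hz -> Hx
    if transfer == "haha":
        s = _apply_haha(s, system, amplitude, duration, exchange)
    elif transfer == "rsfpt":
        s = _apply_rsfpt(s, system, amplitude, timing, exchange)
    else:
        raise ValueError("transfer must be 'haha' or 'rsfpt'")
    s = apply_ideal_pulse(s, "N", 90.0, -90.0)       # Nx -> Nz
    s = purge_transverse(s, "both")
    s = _apply_cssf(s, system, shape, timing.zeta,
                    decoupling_amplitude, exchange)
    return s, amplitude, duration


def _readout_h_signal(state, system, amplitude, duration, transfer="haha",
                      timing=None):
    """Nz -> in-phase transverse 1H amplitude at acquisition start."""
    s = apply_ideal_pulse(state, "N", 90.0, 90.0)    # Nz -> Nx
    if transfer == "haha":
        s = _apply_haha(s, system, amplitude, duration)
    else:
        s = _apply_rsfpt_reverse(s, system, amplitude,
                                 timing or SequenceTiming())
    return s["Hx"]


def _apply_rsfpt_reverse(state, system, amplitude, timing):
    tau = (timing.transfer_duration / 2.0 if timing.transfer_duration
           else 1.0 / (system.J_NH * np.sqrt(2.0)))
    gen_n = liouvillian(system, [RfField("N", amplitude)])
    gen_h = liouvillian(system, [RfField("H", amplitude)])
    s = evolve(state, gen_n, tau)
    s = purge_transverse(s, "both")
    s = evolve(s, liouvillian(system, []), timing.delta)
    return evolve(s, gen_h, tau)


def run_r1_experiment(system: SpinSystem, shape, timing: SequenceTiming,
                      transfer: str = "haha", amplitude: float | None = None,
                      decoupling_amplitude: float = 2000.0) -> DecayCurve:
    """Longitudinal 15N relaxation decay of the selected resonance.

    The relaxation delay acts on stored Nz with cross-relaxation and
    recovery suppressed, emulating the proton-inversion scheme used to
    isolate the pure R1_N decay; for an isolated on-resonance residue the
    fitted mono-exponential rate therefore recovers R1_N.
    """
    if not timing.relax_delays:
        raise ValueError("relax_delays must be non-empty")
    sel, amp, dur = _prepare_selected_nz(
        system, shape, timing, transfer, amplitude, decoupling_amplitude)
    relax_sys = system.replace(sigma_HN=0.0)
    gen = liouvillian(relax_sys, [], include_recovery=False)
    intensities = []
    for t in timing.relax_delays:
        s = evolve(sel, gen, t)
        s = purge_transverse(s, "both")
        intensities.append(_readout_h_signal(s, system, amp, dur,
                                             transfer, timing))
    return DecayCurve(np.asarray(timing.relax_delays),
                      np.asarray(intensities))


def run_r1rho_experiment(system: SpinSystem, shape, timing: SequenceTiming,
                         sl: SpinLockParams, transfer: str = "haha",
                         amplitude: float | None = None,
                         decoupling_amplitude: float = 2000.0,
                         align: bool = True) -> DecayCurve:
    """Constant-time rotating-frame relaxation decay under a 15N lock.

    The stored Nz is tilted onto the effective-field axis, locked for the
    variable time, tilted back and read out.  The constant-time window is
    completed by a far off-resonance temperature-compensation lock placed
    before the selection step; it has no effect on the spins, so the
    fitted decay rate is R1rho = R1 cos^2(theta) + R2 sin^2(theta)
    directly (R2_N for an on-resonance lock).
    """
    if not timing.relax_delays:
        raise ValueError("relax_delays must be non-empty")
    if max(timing.relax_delays) > timing.ct_relax_time + 1e-12:
        raise ValueError("relaxation delays exceed the constant-time window")
    sel, amp, dur = _prepare_selected_nz(
        system, shape, timing, transfer, amplitude, decoupling_amplitude)
    theta = sl.theta
    lock_sys = system.replace(offset_N=sl.offset, sigma_HN=0.0)
    gen = liouvillian(lock_sys, [RfField("N", sl.amplitude)],
                      include_recovery=False)
    intensities = []
    for t in timing.relax_delays:
        s = apply_ideal_pulse(sel, "N", theta if align else 90.0, 90.0)
        s = evolve(s, gen, t)
        s = apply_ideal_pulse(s, "N", -(theta if align else 90.0), 90.0)
        s = purge_transverse(s, "both")
        intensities.append(_readout_h_signal(s, system, amp, dur,
                                             transfer, timing))
    return DecayCurve(np.asarray(timing.relax_delays),
                      np.asarray(intensities))


def run_noe_experiment(system: SpinSystem, shape, timing: SequenceTiming,
                       transfer: str = "haha",
                       amplitude: float | None = None) -> float:
    """Steady-state heteronuclear nOe ratio (saturated / unsaturated).

    Proton saturation is modeled by clamping Hz to zero while the
    longitudinal system evolves with thermal recovery; at steady state
    the ratio equals 1 + gamma_ratio * sigma_HN / R1_N.
    """
    if system.R1_N > 0 and timing.noe_saturation_time < 5.0 / system.R1_N:
        warnings.warn("saturation shorter than 5/R1_N: steady state may "
                      "not be reached", TimingWarning, stacklevel=2)
    gen = liouvillian(system, [], include_recovery=True)
    sat_matrix = gen.matrix.copy()
    sat_matrix[3, :] = 0.0                      # clamp dHz/dt
    sat_affine = gen.affine.copy()
    sat_affine[3] = 0.0
    from .spin import Generator
    sat_gen = Generator(matrix=sat_matrix, affine=sat_affine)

    eq = equilibrium_state(system)
    s_sat = eq.copy()
    s_sat.coefficients[3] = 0.0
    s_sat = evolve(s_sat, sat_gen, timing.noe_saturation_time)
    s_ref = evolve(eq, gen, timing.noe_saturation_time)

    def readout(s):
        return apply_ideal_pulse(s, "N", 90.0, 90.0)["Nx"]

    ref = readout(s_ref)
    if ref == 0:
        raise ValueError("no reference 15N signal")
    return readout(s_sat) / ref


def run_zz_exchange(system: SpinSystem, exchange: ExchangeModel, shape,
                    mixing_times, timing: SequenceTiming | None = None,
                    transfer: str = "haha", amplitude: float | None = None,
                    ideal_preparation: bool = False,
                    prepare: str = "carrier") -> np.ndarray:
    """State-resolved longitudinal intensities versus exchange mixing time.

    The selective experiment prepares Nz in the chemical state at the
    carrier; during the mixing time the longitudinal block evolves under
    exchange and R1 (recovery suppressed, as in the difference scheme),
    and each state's Nz is reported, giving auto- and cross-state
    build-up curves.  Returns an (n_states, n_mixing) array, or with
    ``prepare='all'`` the full (n_states, n_states, n_mixing) auto/cross
    matrix (detected, prepared, mixing) obtained by moving the selection
    carrier onto each state in turn.  ``ideal_preparation`` skips the
    transfer/filter and starts from unit Nz in the prepared state.
    """
    if prepare == "all":
        mixing_times = np.asarray(mixing_times, dtype=float)
        out = np.empty((exchange.n_states, exchange.n_states,
                        mixing_times.size))
        for j, (off_n, off_h, _) in enumerate(exchange.states):
            shifted = ExchangeModel(
                states=[(on - off_n, oh - off_h, p)
                        for on, oh, p in exchange.states],
                rate_matrix=exchange.rate_matrix)
            out[:, j, :] = run_zz_exchange(
                system, shifted, shape, mixing_times, timing, transfer,
                amplitude, ideal_preparation, prepare="carrier")
        return out
    if prepare != "carrier":
        raise ValueError("prepare must be 'carrier' or 'all'")
    mixing_times = np.asarray(mixing_times, dtype=float)
    if mixing_times.size == 0:
        raise ValueError("mixing_times must be non-empty")
    timing = timing or SequenceTiming()
    offsets = np.array([st[0] for st in exchange.states])
    target = int(np.argmin(np.abs(offsets)))
    dnu = np.abs(offsets - offsets[target])
    dnu = dnu[dnu > 0]
    k_max = float(np.max(np.abs(exchange.rate_matrix)))
    if dnu.size and 2 * np.pi * dnu.min() < 10.0 * k_max:
        warnings.warn("exchange is not slow relative to the state "
                      "frequency separation", TimingWarning, stacklevel=2)
    if ideal_preparation:
        sel = StateVector.zero(exchange.n_states)
        sel.coefficients[16 * target + 6] = 1.0
    else:
        sel, _, _ = _prepare_selected_nz(system, shape, timing, transfer,
                                         amplitude, exchange=exchange)
        sel = purge_transverse(sel, "both")
    mix_sys = system.replace(sigma_HN=0.0)
    gen = liouvillian(mix_sys, [], exchange, include_recovery=False)
    out = np.empty((exchange.n_states, mixing_times.size))
    for m, t in enumerate(mixing_times):
        s = evolve(sel, gen, t)
        for k in range(exchange.n_states):
            out[k, m] = s.coefficients[16 * k + 6]
    return out


# ---------------------------------------------------------------------------
# Offset-response profiles

def transfer_signal(amplitude: float, duration: float | None = None,
                    transfer: str = "haha"):
    """Experiment callable: in-phase transfer efficiency of a system."""
    cache: dict = {}

    def experiment(system: SpinSystem) -> float:
        if duration is None and "duration" not in cache:
            cache["duration"] = optimal_transfer_duration(
                system, amplitude, transfer)
        dur = duration or cache["duration"]
        if transfer == "haha":
            return haha_transfer(system, amplitude, dur)
        timing = SequenceTiming(transfer_duration=dur)
        return rsfpt_transfer(system, amplitude, timing)

    return experiment


def sniper_signal(shape, timing: SequenceTiming | None = None,
                  transfer: str = "haha", amplitude: float | None = None,
                  decoupling_amplitude: float = 2000.0):
    """Experiment callable: zero-delay signal of the full selective
    experiment (transfer + shaped filter + readout)."""
    timing = timing or SequenceTiming()
    cache: dict = {}

    def experiment(system: SpinSystem) -> float:
        amp = system.J_NH / 2.0 if amplitude is None else amplitude
        if timing.transfer_duration is None and "duration" not in cache:
            # the transfer duration is set once, at the on-resonance optimum
            cache["duration"] = optimal_transfer_duration(system, amp,
                                                          transfer)
        fixed = timing if timing.transfer_duration is not None else \
            SequenceTiming(zeta=timing.zeta, delta=timing.delta,
                           transfer_duration=cache["duration"],
                           ct_relax_time=timing.ct_relax_time,
                           relax_delays=timing.relax_delays,
                           noe_saturation_time=timing.noe_saturation_time)
        sel, amp, dur = _prepare_selected_nz(
            system, shape, fixed, transfer, amp, decoupling_amplitude)
        return _readout_h_signal(sel, system, amp, dur, transfer, fixed)

    return experiment


def response_profile(experiment, system_template: SpinSystem,
                     offset_grid, sweep: str = "N") -> Profile:
    """Map an experiment's response versus the target resonance offset.

    The template system's swept offset (15N by default) is moved across
    the grid while the rf carriers stay fixed, and the scalar response is
    normalized to the on-resonance value.
    """
    offset_grid = np.asarray(offset_grid, dtype=float)
    if offset_grid.size == 0:
        raise ValueError("offset grid must not be empty")
    if np.any(np.diff(offset_grid) < 0):
        raise ValueError("offset grid must be sorted")

    def at(off):
        if sweep == "N":
            return experiment(system_template.replace(offset_N=off))
        if sweep == "H":
            return experiment(system_template.replace(offset_H=off))
        raise ValueError("sweep must be 'N' or 'H'")

    resp = np.array([at(off) for off in offset_grid])
    ref = at(0.0)
    if ref == 0:
        raise ValueError("zero on-resonance response; cannot normalize")
    resp = resp / ref
    prof = Profile(offsets=offset_grid, response=np.abs(resp))
    prof.scale = abs(ref)
    return prof
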