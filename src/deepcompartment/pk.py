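"""Two-compartment pharmacokinetic model with dose events.

The model tracks drug *amounts* in a central and a peripheral compartment,

    dA1/dt = In(t) + k21*A2 - (k10 + k12)*A1
    dA2/dt = k12*A1 - k21*A2

with rate constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 formed from the four
pharmacokinetic parameters: clearance CL (L/h), central volume V1 (L),
inter-compartmental clearance Q (L/h) and peripheral volume V2 (L).  Doses
enter the central compartment either as instantaneous boluses (state jump
A1 += amount) or as constant-rate infusions.  The reported quantity is the
central *concentration* C1(t) = A1(t)/V1, converted from IU/L to IU/dL.

Amount-space integration is algebraically equivalent to carrying both states
pre-divided by V1 and avoids rescaling the peripheral state; the central
concentration is identical either way.

Two solution paths are provided:

* :func:`solve_profile` — numeric integration (scipy, LSODA) with a hard
  restart at every event time, so boluses are exact discontinuities.
* :func:`analytic_profile` / :func:`analytic_bolus_solution` — the closed-form
  biexponential solution of the linear system, valid for arbitrary bolus and
  constant-rate-infusion regimens via superposition.  This path accepts
  complex-valued parameters, which :func:`concentration_and_gradient` exploits
  for complex-step derivatives (the differentiable path used in training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import InvalidParameterError

logger = logging.getLogger(__name__)

#: Conversion from IU/L to IU/dL (concentrations are reported in IU/dL).
IU_PER_L_TO_IU_PER_DL = 0.1

PARAM_ORDER = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters of the two-compartment model.

    CL and Q may be zero only in limiting/oracle cases (e.g. mass-conservation
    checks); V1 and V2 must be strictly positive to form the rate constants.
    """

    CL: float  # clearance, L/h
    V1: float  # central volume, L
    Q: float   # inter-compartmental clearance, L/h
    V2: float  # peripheral volume, L

    def __post_init__(self) -> None:
        for name in ("V1", "V2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )
        for name in ("CL", "Q"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"{name} must be non-negative and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.Q, self.V2], dtype=float)


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants (1/h) of the two-compartment system."""

    k10: float
    k12: float
    k21: float


def rate_constants(pk: PKParameters) -> RateConstants:
    """Form (k10, k12, k21) = (CL/V1, Q/V1, Q/V2)."""
    return RateConstants(k10=pk.CL / pk.V1, k12=pk.Q / pk.V1, k21=pk.Q / pk.V2)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: bolus if duration == 0, else an infusion of
    constant rate amount/duration over [time, time + duration]."""

    time: float      # h
    amount: float    # IU
    duration: float = 0.0  # h

    @property
    def rate(self) -> float:
        return self.amount / self.duration if self.duration > 0 else np.inf


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered sequence of dose events (the intervention schedule)."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise InvalidParameterError("dose event times must be non-negative")
        if sorted(times) != times:
            raise InvalidParameterError("dose events must be sorted by time")
        if any(e.amount < 0 for e in self.events):
            raise InvalidParameterError("dose amounts must be non-negative")
        if any(e.duration < 0 for e in self.events):
            raise InvalidParameterError("dose durations must be non-negative")

    @classmethod
    def bolus(cls, amount: float, time: float = 0.0) -> "DoseRegimen":
        return cls(events=(DoseEvent(time=time, amount=amount),))

    @classmethod
    def from_events(cls, events: Sequence[tuple]) -> "DoseRegimen":
        return cls(events=tuple(DoseEvent(*e) for e in events))


@dataclass
class ConcentrationCurve:
    """A concentration–time profile (times in h, values in IU/dL)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidParameterError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("concentration values must be finite")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="time_h,concentration_iu_dl",
            comments="",
        )


# ---------------------------------------------------------------------------
# Closed-form solution machinery (complex-step safe)
# ---------------------------------------------------------------------------


def _modes(cl, v1, q, v2):
    """Eigen-decomposition pieces of the 2x2 rate matrix.

    Returns (alpha, beta, k21) with alpha >= beta the two exponential rates.
    For real parameters the discriminant (k10-k21)^2 + k12^2 + 2 k12 (k10+k21)
    is non-negative, so the rates are real.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    root = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return alpha, beta, k21


def _one_m_exp_div(lam, tau):
    """(1 - exp(-lam*tau)) / lam, with the lam -> 0 limit tau handled by series."""
    x = lam * tau
    small = np.abs(x) < 1e-6
    lam_safe = np.where(np.abs(lam) == 0, 1.0, lam)
    direct = (1.0 - np.exp(-x)) / lam_safe
    series = tau * (1.0 - x / 2.0 + x * x / 6.0)
    return np.where(small, series, direct)


def _unit_bolus_conc(cl, v1, q, v2, tau):
    """Central concentration (IU/L per IU dosed) tau hours after a unit bolus.

    Standard biexponential: C(tau) = [(alpha-k21) e^{-alpha tau}
    + (k21-beta) e^{-beta tau}] / ((alpha-beta) V1); the degenerate
    (critically damped) alpha == beta branch uses the analytic limit.
    """
    alpha, beta, k21 = _modes(cl, v1, q, v2)
    gap = alpha - beta
    scale = np.abs(alpha) + np.abs(beta)
    degenerate = np.abs(gap) <= 1e-9 * np.where(scale == 0, 1.0, scale)
    gap_safe = np.where(degenerate, 1.0, gap)
    general = (
        (alpha - k21) * np.exp(-alpha * tau) + (k21 - beta) * np.exp(-beta * tau)
    ) / gap_safe
    limit = np.exp(-alpha * tau) * (1.0 + (k21 - alpha) * tau)
    out = np.where(degenerate, limit, general) / v1
    return np.where(np.real(tau) < 0, 0.0, out)


def _unit_bolus_integral(cl, v1, q, v2, tau):
    """Integral of :func:`_unit_bolus_conc` from 0 to tau (infusion kernel)."""
    alpha, beta, k21 = _modes(cl, v1, q, v2)
    gap = alpha - beta
    scale = np.abs(alpha) + np.abs(beta)
    degenerate = np.abs(gap) <= 1e-9 * np.where(scale == 0, 1.0, scale)
    gap_safe = np.where(degenerate, 1.0, gap)
    tau_c = np.maximum(np.real(tau), 0.0) if not np.iscomplexobj(tau) else tau
    general = (
        (alpha - k21) * _one_m_exp_div(alpha, tau_c)
        + (k21 - beta) * _one_m_exp_div(beta, tau_c)
    ) / gap_safe
    # alpha == beta limit: int e^{-a s} (1 + (k21-a) s) ds
    phi1 = _one_m_exp_div(alpha, tau_c)
    alpha_safe = np.where(np.abs(alpha) == 0, 1.0, alpha)
    phi2 = (phi1 - tau_c * np.exp(-alpha * tau_c)) / alpha_safe
    limit = phi1 + (k21 - alpha) * phi2
    out = np.where(degenerate, limit, general) / v1
    return np.where(np.real(tau) < 0, 0.0, out)


def conc_events(cl, v1, q, v2, ev_times, ev_amounts, ev_durations, t):
    """Central concentration (IU/dL) under a bolus/infusion event schedule.

    All arguments broadcast; the event axis is the last axis of ``ev_*`` and is
    summed over (superposition of the linear system's responses).  Parameters
    may be complex (for complex-step differentiation); times are real.
    """
    cl, v1, q, v2 = (np.asarray(a)[..., None] for a in (cl, v1, q, v2))
    t = np.asarray(t)[..., None]
    ev_times = np.asarray(ev_times, dtype=float)
    ev_amounts = np.asarray(ev_amounts, dtype=float)
    ev_durations = np.asarray(ev_durations, dtype=float)

    tau = t - ev_times
    is_inf = ev_durations > 0
    bolus_part = np.where(
        is_inf, 0.0, ev_amounts * _unit_bolus_conc(cl, v1, q, v2, np.maximum(tau, 0.0))
    )
    bolus_part = np.where(tau < 0, 0.0, bolus_part)

    dur_safe = np.where(is_inf, ev_durations, 1.0)
    rate = np.where(is_inf, ev_amounts / dur_safe, 0.0)
    tau1 = np.clip(tau, 0.0, None)
    tau2 = np.clip(tau - ev_durations, 0.0, None)
    inf_part = rate * (
        _unit_bolus_integral(cl, v1, q, v2, tau1)
        - _unit_bolus_integral(cl, v1, q, v2, tau2)
    )
    total = (bolus_part + inf_part).sum(axis=-1)
    return total * IU_PER_L_TO_IU_PER_DL


def _regimen_arrays(regimen: DoseRegimen):
    if not regimen.events:
        z = np.zeros(1)
        return z, z, z
    ev = regimen.events
    return (
        np.array([e.time for e in ev], dtype=float),
        np.array([e.amount for e in ev], dtype=float),
        np.array([e.duration for e in ev], dtype=float),
    )


def analytic_profile(
    pk: PKParameters, regimen: DoseRegimen, times
) -> ConcentrationCurve:
    """Closed-form concentration profile under an arbitrary event schedule."""
    times = np.asarray(times, dtype=float)
    ev_t, ev_a, ev_d = _regimen_arrays(regimen)
    values = conc_events(pk.CL, pk.V1, pk.Q, pk.V2, ev_t, ev_a, ev_d, times)
    return ConcentrationCurve(times=times, values=np.real(values))


def analytic_bolus_solution(pk: PKParameters, dose: float, t) -> np.ndarray:
    """Closed-form central concentration (IU/dL) after a single bolus at t=0.

    At t=0 this equals dose/V1/10; for dose=0 it is identically zero.
    Repeated eigenvalues are handled by the critically damped branch.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    out = dose * _unit_bolus_conc(pk.CL, pk.V1, pk.Q, pk.V2, t) * IU_PER_L_TO_IU_PER_DL
    return np.real(out)


def concentration_and_gradient(theta: np.ndarray, ev_times, ev_amounts,
                               ev_durations, t):
    """Concentration and its Jacobian w.r.t. (CL, V1, Q, V2) by complex step.

    ``theta`` has shape (..., 4) aligned with the time array ``t``.  Returns
    ``(c, jac)`` with ``jac`` of shape (4,) + c.shape.  The complex-step
    derivative Im f(x + ih)/h is exact to machine precision for the analytic
    solution (no subtractive cancellation).
    """
    theta = np.asarray(theta, dtype=float)
    cl, v1, q, v2 = (theta[..., j] for j in range(4))
    c = np.real(conc_events(cl, v1, q, v2, ev_times, ev_amounts, ev_durations, t))
    h = 1e-30
    jac = np.empty((4,) + c.shape)
    for j in range(4):
        pert = [np.asarray(theta[..., k], dtype=complex) for k in range(4)]
        pert[j] = pert[j] + 1j * h
        cj = conc_events(*pert, ev_times, ev_amounts, ev_durations, t)
        jac[j] = np.imag(cj) / h
    return c, jac


# ---------------------------------------------------------------------------
# Numeric solver
# ---------------------------------------------------------------------------


def solve_profile(
    pk: PKParameters,
    regimen: DoseRegimen,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    return_amounts: bool = False,
):
    """Numerically integrate the dosed two-compartment system.

    Integrates amounts (A1, A2) from t=0 with LSODA, restarting at every event
    boundary so boluses are exact state discontinuities (A1 += amount) and
    infusion on/off switches are not smoothed over.  Returns the central
    concentration A1/V1 in IU/dL on the requested grid; a requested time that
    coincides with a bolus reports the post-bolus state.

    Events beyond the last requested time are ignored with a logged warning.
    With ``return_amounts=True`` also returns the (n, 2) amount matrix (used
    by mass-balance checks).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise InvalidParameterError("times must be a non-empty 1-D grid")
    if np.any(times < 0):
        raise InvalidParameterError("times must be non-negative")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise InvalidParameterError("time grid must be sorted strictly ascending")

    horizon = times[-1]
    events = []
    for e in regimen.events:
        if e.time > horizon:
            logger.warning(
                "dose event at t=%.4g h lies beyond the integration horizon "
                "%.4g h and is ignored", e.time, horizon,
            )
            continue
        events.append(e)

    k = rate_constants(pk)

    boundaries = {0.0, horizon}
    for e in events:
        boundaries.add(e.time)
        if e.duration > 0 and e.time + e.duration < horizon:
            boundaries.add(e.time + e.duration)
    bounds = np.array(sorted(boundaries))

    out = np.empty((times.size, 2))
    state = np.zeros(2)

    def rhs_factory(inflow):
        def rhs(_t, a):
            return (
                inflow + k.k21 * a[1] - (k.k10 + k.k12) * a[0],
                k.k12 * a[0] - k.k21 * a[1],
            )
        return rhs

    for i, a in enumerate(bounds):
        for e in events:
            if e.time == a and e.duration == 0:
                state = state + np.array([e.amount, 0.0])
        at_a = np.flatnonzero(times == a)
        out[at_a] = state
        if i + 1 == bounds.size:
            break
        b = bounds[i + 1]
        inflow = sum(
            e.rate for e in events
            if e.duration > 0 and e.time <= a and a < e.time + e.duration
        )
        mask = (times > a) & (times < b)
        sol = solve_ivp(
            rhs_factory(inflow),
            (a, b),
            state,
            method="LSODA",
            t_eval=np.concatenate([times[mask], [b]]),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        vals = sol.y.T
        out[np.flatnonzero(mask)] = vals[:-1]
        state = vals[-1]

    conc = out[:, 0] / pk.V1 * IU_PER_L_TO_IU_PER_DL
    curve = ConcentrationCurve(times=times, values=conc)
    if return_amounts:
        return curve, out
    return curve
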