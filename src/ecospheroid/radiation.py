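"""Linear-quadratic radiation kill coupled to Lotka-Volterra regrowth.

A single radiation fraction of dose d (Gy) reduces each population
instantaneously by its linear-quadratic surviving fraction

    SF(d) = exp(-alpha d - beta d^2),

with population-specific sensitivity constants alpha (Gy^-1) and beta
(Gy^-2).  In-silico regrowth experiments grow a mixed spheroid until its
total volume reaches a trigger, irradiate, and follow the total volume
until it re-crosses an endpoint; the regrowth time is the interval from
irradiation to that re-crossing.  Crossing times are located by
root-finding on the dense ODE solution, so they are independent of any
output grid.  Scanning the interaction coefficients (lambda_P, lambda_RR)
over a grid yields a regrowth-time landscape over interaction space.

Growth-delay utilities compare measured (or simulated) irradiated growth
curves against untreated baselines at a volume endpoint defined as a
multiple of the volume at irradiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import EstimationError, InvalidParameterError
from .growth import GrowthCurve, LVParams, lv_rhs

__all__ = [
    "LQParams",
    "RadiationProtocol",
    "RegrowthResult",
    "GrowthDelayResult",
    "surviving_fraction",
    "apply_radiation",
    "regrowth_time",
    "regrowth_landscape",
    "irradiated_trajectory",
    "growth_delay",
    "perturb_lq",
]

_BLOWUP_VOLUME = 1e7


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic sensitivity: alpha in Gy^-1, beta in Gy^-2."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (math.isfinite(self.alpha) and self.alpha >= 0):
            raise InvalidParameterError("alpha must be finite and >= 0")
        if not (math.isfinite(self.beta) and self.beta >= 0):
            raise InvalidParameterError("beta must be finite and >= 0")


@dataclass(frozen=True)
class RadiationProtocol:
    """Single-fraction in-silico irradiation schedule.

    The spheroid is irradiated with ``dose`` Gy when its total volume first
    reaches ``trigger_volume`` (mm^3) and followed until it re-crosses
    ``endpoint_volume`` (mm^3) or until ``max_follow_up`` days have elapsed
    in the phase being monitored (censoring horizon).
    """

    dose: float
    trigger_volume: float
    endpoint_volume: float
    max_follow_up: float = 300.0

    def __post_init__(self):
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise InvalidParameterError("dose must be finite and >= 0")
        for name in ("trigger_volume", "endpoint_volume", "max_follow_up"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0")


@dataclass(frozen=True)
class RegrowthResult:
    """Outcome of one in-silico irradiation/regrowth experiment."""

    lambda_P: float
    lambda_RR: float
    time_to_trigger: float
    regrowth_time: float
    censored: bool
    post_kill_state: tuple[float, float]
    reason: str = ""


@dataclass(frozen=True)
class GrowthDelayResult:
    """Radiation-induced growth delay at a volume-multiple endpoint."""

    endpoint_multiplier: float
    time_irradiated: float
    time_untreated_baseline: float
    delay: float
    censored: bool


def surviving_fraction(lq: LQParams, dose: float) -> float:
    """LQ surviving fraction exp(-alpha d - beta d^2); 1 at zero dose."""
    if not (math.isfinite(dose) and dose >= 0):
        raise InvalidParameterError("dose must be finite and >= 0")
    return math.exp(-lq.alpha * dose - lq.beta * dose * dose)


def apply_radiation(state: tuple[float, float], dose: float,
                    lq_P: LQParams, lq_RR: LQParams) -> tuple[float, float]:
    """Scale each population by its surviving fraction, instantaneously."""
    v_p, v_rr = state
    if v_p < 0 or v_rr < 0:
        raise InvalidParameterError("volumes must be >= 0")
    return (v_p * surviving_fraction(lq_P, dose),
            v_rr * surviving_fraction(lq_RR, dose))


def _integrate_until(p: LVParams, y0: Sequence[float], threshold: float,
                     horizon: float, rtol: float, atol: float):
    """Integrate LV dynamics until the total volume first rises through
    ``threshold``; returns (crossing_time_or_None, state_at_end)."""

    def rhs(t, y):
        return lv_rhs(p, y[0], y[1])

    def crossing(t, y):
        return (y[0] + y[1]) - threshold

    crossing.terminal = True
    crossing.direction = 1

    def blowup(t, y):
        return (y[0] + y[1]) - _BLOWUP_VOLUME

    blowup.terminal = True
    blowup.direction = 1

    if y0[0] + y0[1] >= threshold:
        return 0.0, (float(y0[0]), float(y0[1]))

    sol = solve_ivp(rhs, (0.0, horizon), list(y0), rtol=rtol, atol=atol,
                    method="RK45", events=(crossing, blowup),
                    dense_output=True)
    if sol.t_events[1].size:  # diverged
        raise EstimationError(
            "LV dynamics diverged before reaching the threshold"
        )
    if sol.t_events[0].size:
        t_cross = float(sol.t_events[0][0])
        y = sol.sol(t_cross)
        return t_cross, (float(y[0]), float(y[1]))
    y = sol.y[:, -1]
    return None, (float(y[0]), float(y[1]))


def regrowth_time(p: LVParams, protocol: RadiationProtocol,
                  lq_P: LQParams, lq_RR: LQParams,
                  rtol: float = 1e-8, atol: float = 1e-10) -> RegrowthResult:
    """Simulate grow -> irradiate -> regrow for one parameter set.

    The spheroid grows from (V_P0, V_RR0) until the total volume reaches
    ``protocol.trigger_volume``; the LQ kill is applied instantaneously;
    growth resumes until the total re-crosses ``protocol.endpoint_volume``.
    Either phase not completing within ``protocol.max_follow_up`` days
    yields a censored result with a reason.
    """
    try:
        t_trig, state = _integrate_until(
            p, (p.V_P0, p.V_RR0), protocol.trigger_volume,
            protocol.max_follow_up, rtol, atol)
    except EstimationError:
        return RegrowthResult(p.lambda_P, p.lambda_RR, math.nan, math.nan,
                              True, (math.nan, math.nan), reason="divergence")
    if t_trig is None:
        return RegrowthResult(p.lambda_P, p.lambda_RR, math.nan, math.nan,
                              True, (math.nan, math.nan),
                              reason="trigger_not_reached")

    killed = apply_radiation(state, protocol.dose, lq_P, lq_RR)
    p_post = replace(p, V_P0=max(killed[0], 1e-300),
                     V_RR0=max(killed[1], 1e-300))
    try:
        t_regrow, _ = _integrate_until(
            p_post, killed, protocol.endpoint_volume,
            protocol.max_follow_up, rtol, atol)
    except EstimationError:
        return RegrowthResult(p.lambda_P, p.lambda_RR, t_trig, math.nan,
                              True, killed, reason="divergence")
    if t_regrow is None:
        return RegrowthResult(p.lambda_P, p.lambda_RR, t_trig, math.nan,
                              True, killed, reason="endpoint_not_reached")
    return RegrowthResult(p.lambda_P, p.lambda_RR, t_trig, t_regrow,
                          False, killed)


def regrowth_landscape(base: LVParams,
                       lambda_grid: Iterable[tuple[float, float]],
                       protocol: RadiationProtocol,
                       lq_P: LQParams, lq_RR: LQParams,
                       rtol: float = 1e-8,
                       atol: float = 1e-10) -> list[RegrowthResult]:
    """Regrowth time at every (lambda_P, lambda_RR) grid point.

    Points are independent and evaluated deterministically; per-point
    divergence (strong mutualism) is recorded as a censored result, never
    raised.
    """
    results = []
    for lam_p, lam_rr in lambda_grid:
        params = replace(base, lambda_P=float(lam_p), lambda_RR=float(lam_rr))
        results.append(regrowth_time(params, protocol, lq_P, lq_RR,
                                     rtol=rtol, atol=atol))
    return results


def irradiated_trajectory(p: LVParams, protocol: RadiationProtocol,
                          lq_P: LQParams, lq_RR: LQParams,
                          t_eval: Sequence[float],
                          rtol: float = 1e-8, atol: float = 1e-10):
    """Piecewise (pre-kill, post-kill) trajectory sampled at ``t_eval``.

    Returns ``(PairTrajectory, time_of_irradiation)``.  With zero dose the
    trajectory is exactly the unirradiated LV solution.  Raises
    :class:`EstimationError` if the trigger volume is never reached within
    the follow-up horizon.
    """
    from .growth import PairTrajectory, simulate_lv

    t_eval = np.asarray(t_eval, dtype=float)
    if protocol.dose == 0.0:
        grid = t_eval if t_eval[0] == 0.0 else np.concatenate(([0.0], t_eval))
        traj = simulate_lv(p, grid, rtol=rtol, atol=atol)
        t_trig, _ = _integrate_until(p, (p.V_P0, p.V_RR0),
                                     protocol.trigger_volume,
                                     protocol.max_follow_up, rtol, atol)
        if t_trig is None:
            raise EstimationError("trigger volume not reached in follow-up")
        keep = np.isin(traj.times, t_eval)
        return (PairTrajectory(traj.times[keep], traj.V_P[keep],
                               traj.V_RR[keep]), t_trig)

    t_trig, state = _integrate_until(p, (p.V_P0, p.V_RR0),
                                     protocol.trigger_volume,
                                     protocol.max_follow_up, rtol, atol)
    if t_trig is None:
        raise EstimationError("trigger volume not reached in follow-up")
    killed = apply_radiation(state, protocol.dose, lq_P, lq_RR)

    def rhs_pre(t, y):
        return lv_rhs(p, y[0], y[1])

    pre = solve_ivp(rhs_pre, (0.0, max(t_trig, t_eval[-1], 1e-9)),
                    [p.V_P0, p.V_RR0], rtol=rtol, atol=atol,
                    method="RK45", dense_output=True)
    post_span = max(t_eval[-1] - t_trig, 0.0)
    post = None
    if post_span > 0:
        post = solve_ivp(rhs_pre, (0.0, post_span), list(killed),
                         rtol=rtol, atol=atol, method="RK45",
                         dense_output=True)

    v_p = np.empty_like(t_eval)
    v_rr = np.empty_like(t_eval)
    for i, t in enumerate(t_eval):
        if t <= t_trig or post is None:
            y = pre.sol(min(t, t_trig))
        else:
            y = post.sol(t - t_trig)
        v_p[i], v_rr[i] = y
    return PairTrajectory(t_eval, v_p, v_rr), t_trig


def _crossing_time(curve: GrowthCurve, endpoint: float) -> float | None:
    """First up-crossing of ``endpoint`` by monotone interpolation on log
    volume; ``None`` if the curve never reaches it."""
    v = curve.volumes
    t = curve.times
    if v[0] >= endpoint:
        return float(t[0])
    above = np.nonzero(v >= endpoint)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    # interpolate in (log V, t) between the bracketing samples
    lv0, lv1 = math.log(v[i - 1]), math.log(v[i])
    frac = (math.log(endpoint) - lv0) / (lv1 - lv0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def growth_delay(irradiated: GrowthCurve,
                 untreated_baseline: Sequence[GrowthCurve],
                 multiplier: float,
                 irradiation_time: float | None = None) -> GrowthDelayResult:
    """Growth delay of an irradiated curve relative to untreated baselines.

    The endpoint is ``multiplier`` times the irradiated spheroid's volume
    at ``irradiation_time`` (default: its first observation).  Crossing
    times are found by monotone log-linear interpolation, never
    extrapolation: a baseline that does not reach the endpoint raises
    :class:`EstimationError`; an irradiated curve that does not is
    censored at its last observation.
    """
    if multiplier <= 1:
        raise InvalidParameterError("multiplier must be > 1")
    if not untreated_baseline:
        raise EstimationError("at least one untreated baseline is required")
    if irradiation_time is None:
        irradiation_time = float(irradiated.times[0])
    start_volume = float(np.interp(irradiation_time, irradiated.times,
                                   irradiated.volumes))
    if start_volume <= 0:
        raise EstimationError("starting volume at irradiation must be > 0")
    endpoint = multiplier * start_volume

    baseline_times = []
    for curve in untreated_baseline:
        t_cross = _crossing_time(curve, endpoint)
        if t_cross is None:
            raise EstimationError(
                f"baseline curve {curve.label!r} never reaches the endpoint "
                f"{endpoint:.4g} mm^3 (extrapolation refused)"
            )
        baseline_times.append(t_cross)
    t_baseline = float(np.mean(baseline_times))

    t_irr = _crossing_time(irradiated, endpoint)
    if t_irr is None:
        return GrowthDelayResult(multiplier, float(irradiated.times[-1]),
                                 t_baseline, math.nan, censored=True)
    return GrowthDelayResult(multiplier, t_irr, t_baseline,
                             t_irr - t_baseline, censored=False)


def perturb_lq(lq: LQParams, lq_sd: LQParams,
               rng: np.random.Generator) -> LQParams:
    """Resample LQ constants from independent normals truncated at 0.

    Off by default everywhere; intended for optional uncertainty
    propagation of the clonogenic-fit standard deviations.
    """
    alpha = max(0.0, rng.normal(lq.alpha, lq_sd.alpha))
    beta = max(0.0, rng.normal(lq.beta, lq_sd.beta))
    return LQParams(alpha=alpha, beta=beta)
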