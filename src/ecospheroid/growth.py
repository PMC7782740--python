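"""Deterministic growth dynamics for homogeneous and mixed tumour spheroids.

Two population models are implemented.  Homogeneous spheroids follow
logistic growth,

    dV/dt = r V (1 - V/K),          V(0) = V0,

with growth rate ``r`` (day^-1) and carrying capacity ``K`` (mm^3), whose
closed-form solution is

    V(t) = V0 K e^{rt} / (K + V0 (e^{rt} - 1)).

Mixed spheroids containing a parental (P, radiosensitive) and a
radioresistant (RR) population follow a two-species Lotka-Volterra
competition-type model,

    dV_P/dt  = r_P  V_P  (1 - V_P/K_P  - lambda_RR V_RR/K_P),
    dV_RR/dt = r_RR V_RR (1 - V_RR/K_RR - lambda_P  V_P/K_RR),

where ``lambda_P`` is the effect the parental population exerts on the
radioresistant one and ``lambda_RR`` the converse.  The signs of the two
coupling coefficients classify the ecological interaction: both positive is
competition, both negative mutualism, and opposite signs antagonism.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DivergenceError, InvalidParameterError

__all__ = [
    "GrowthCurve",
    "LogisticParams",
    "LVParams",
    "PairTrajectory",
    "InteractionClass",
    "logistic_solution",
    "logistic_rhs",
    "lv_rhs",
    "simulate_lv",
    "classify_interaction",
    "lv_coexistence_equilibrium",
]

# Total volume (mm^3) beyond which an LV trajectory is declared divergent.
_BLOWUP_VOLUME = 1e7


@dataclass(frozen=True)
class GrowthCurve:
    """Time-stamped volume series for one spheroid.

    Parameters
    ----------
    times : array-like
        Observation times in days; strictly increasing, non-negative.
    volumes : array-like
        Spheroid volumes in mm^3; finite and non-negative.
    label : str
        Free-text spheroid identifier.
    group : str
        Experimental group (e.g. cell line / seeding ratio).
    """

    times: np.ndarray
    volumes: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidParameterError(
                "times and volumes must be 1-D arrays of equal length"
            )
        if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise InvalidParameterError("times must be finite and >= 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidParameterError("volumes must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)

    def __len__(self) -> int:
        return self.times.size


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (math.isfinite(value) and value > 0):
            raise InvalidParameterError(
                f"{name} must be finite and > 0, got {value!r}"
            )


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters: rate r (day^-1), capacity K (mm^3),
    initial volume V0 (mm^3); all strictly positive."""

    r: float
    K: float
    V0: float

    def __post_init__(self):
        _require_positive(r=self.r, K=self.K, V0=self.V0)


@dataclass(frozen=True)
class LVParams:
    """Two-population Lotka-Volterra parameters.

    Growth rates ``r_P``/``r_RR`` (day^-1), carrying capacities
    ``K_P``/``K_RR`` (mm^3) and initial volumes ``V_P0``/``V_RR0`` (mm^3)
    are strictly positive; the interaction coefficients ``lambda_P`` (effect
    of parental on radioresistant) and ``lambda_RR`` (effect of
    radioresistant on parental) are finite and sign-unconstrained.
    """

    r_P: float
    r_RR: float
    K_P: float
    K_RR: float
    lambda_P: float
    lambda_RR: float
    V_P0: float
    V_RR0: float

    def __post_init__(self):
        _require_positive(r_P=self.r_P, r_RR=self.r_RR, K_P=self.K_P,
                          K_RR=self.K_RR, V_P0=self.V_P0, V_RR0=self.V_RR0)
        _require_finite(lambda_P=self.lambda_P, lambda_RR=self.lambda_RR)

    @property
    def parental(self) -> LogisticParams:
        """Logistic parameters of the parental population in isolation."""
        return LogisticParams(r=self.r_P, K=self.K_P, V0=self.V_P0)

    @property
    def radioresistant(self) -> LogisticParams:
        """Logistic parameters of the RR population in isolation."""
        return LogisticParams(r=self.r_RR, K=self.K_RR, V0=self.V_RR0)


@dataclass(frozen=True)
class PairTrajectory:
    """Simulated per-population volume paths of a mixed spheroid."""

    times: np.ndarray
    V_P: np.ndarray
    V_RR: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "V_P", np.asarray(self.V_P, dtype=float))
        object.__setattr__(self, "V_RR", np.asarray(self.V_RR, dtype=float))

    @property
    def total(self) -> np.ndarray:
        """Total volume V_P + V_RR at each time."""
        return self.V_P + self.V_RR

    @property
    def fraction_parental(self) -> np.ndarray:
        """Parental proportion V_P/(V_P+V_RR); NaN where the total is 0."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.V_P / tot, np.nan)


class InteractionClass(enum.Enum):
    """Ecological interaction type determined by the coupling signs."""

    COMPETITION = "competition"
    MUTUALISM = "mutualism"
    ANTAGONISM_P_HARMED = "antagonism_P_harmed"
    ANTAGONISM_RR_HARMED = "antagonism_RR_harmed"
    NEUTRAL = "neutral"


def logistic_solution(p: LogisticParams, t):
    """Closed-form logistic volume V(t) in mm^3.

    Evaluated as K / (1 + (K/V0 - 1) e^{-rt}), which is algebraically
    identical to the textbook V0 K e^{rt} / (K + V0(e^{rt}-1)) form but
    does not overflow for large r*t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    out = p.K / (1.0 + (p.K / p.V0 - 1.0) * np.exp(-p.r * t))
    return out if out.ndim else float(out)


def logistic_rhs(p: LogisticParams, V):
    """Logistic growth rate dV/dt = r V (1 - V/K) in mm^3/day."""
    V = np.asarray(V, dtype=float)
    out = p.r * V * (1.0 - V / p.K)
    return out if out.ndim else float(out)


def lv_rhs(p: LVParams, V_P: float, V_RR: float) -> tuple[float, float]:
    """Lotka-Volterra right-hand side (dV_P/dt, dV_RR/dt) in mm^3/day.

    Uses the standard multiplicative r*V prefactor, so each equation
    reduces exactly to the logistic law when the other population is absent
    and volumes started non-negative stay non-negative.
    """
    dP = p.r_P * V_P * (1.0 - V_P / p.K_P - p.lambda_RR * V_RR / p.K_P)
    dRR = p.r_RR * V_RR * (1.0 - V_RR / p.K_RR - p.lambda_P * V_P / p.K_RR)
    return dP, dRR


def lv_coexistence_equilibrium(p: LVParams) -> tuple[float, float] | None:
    """Interior equilibrium solving V_P + lambda_RR V_RR = K_P,
    V_RR + lambda_P V_P = K_RR; ``None`` if the system is singular."""
    det = 1.0 - p.lambda_P * p.lambda_RR
    if det == 0.0:
        return None
    v_p = (p.K_P - p.lambda_RR * p.K_RR) / det
    v_rr = (p.K_RR - p.lambda_P * p.K_P) / det
    return v_p, v_rr


def simulate_lv(p: LVParams, t_grid: Sequence[float],
                rtol: float = 1e-8, atol: float = 1e-10) -> PairTrajectory:
    """Integrate the Lotka-Volterra model over ``t_grid``.

    ``t_grid`` must be strictly increasing and start at 0.  Integration
    uses an adaptive explicit Runge-Kutta scheme; a blow-up under strong
    mutualism raises :class:`DivergenceError` carrying the last valid time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise InvalidParameterError("t_grid must have at least two points")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError(
            "t_grid must be strictly increasing and start at 0"
        )

    def rhs(t, y):
        return lv_rhs(p, y[0], y[1])

    def blowup(t, y):
        return (y[0] + y[1]) - _BLOWUP_VOLUME

    blowup.terminal = True
    blowup.direction = 1

    sol = solve_ivp(rhs, (0.0, t_grid[-1]), [p.V_P0, p.V_RR0],
                    t_eval=t_grid, rtol=rtol, atol=atol, method="RK45",
                    events=blowup)
    if sol.status == 1 or not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise DivergenceError(
            f"LV integration diverged (lambda_P={p.lambda_P}, "
            f"lambda_RR={p.lambda_RR}); last valid time {last:.3f} d",
            last_valid_time=float(last),
        )
    return PairTrajectory(times=sol.t, V_P=sol.y[0], V_RR=sol.y[1])


def classify_interaction(lambda_P: float, lambda_RR: float) -> InteractionClass:
    """Classify the ecological interaction from the signs of the couplings.

    Both positive -> competition; both negative -> mutualism; opposite
    signs -> antagonism, named for the harmed population (a positive
    lambda_P suppresses RR, a positive lambda_RR suppresses P).  A zero on
    an axis contributes neutrally; both zero is neutral.
    """
    _require_finite(lambda_P=lambda_P, lambda_RR=lambda_RR)
    if lambda_P > 0 and lambda_RR > 0:
        return InteractionClass.COMPETITION
    if lambda_P < 0 and lambda_RR < 0:
        return InteractionClass.MUTUALISM
    if lambda_P > 0 and lambda_RR < 0:
        # parental suppresses RR, RR boosts parental: RR is harmed
        return InteractionClass.ANTAGONISM_RR_HARMED
    if lambda_P < 0 and lambda_RR > 0:
        return InteractionClass.ANTAGONISM_P_HARMED
    return InteractionClass.NEUTRAL
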