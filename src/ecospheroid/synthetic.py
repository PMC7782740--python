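"""Synthetic spheroid experiments with realistic noise structure.

Generators emulate the measurement design of the wet-lab study: spheroid
volumes measured roughly daily out to day 15-20 with multiplicative error
proportional to size (5-20% coefficient of variation), and population
proportions measured at a few sparse timepoints (flow-cytometry style,
days 5/10/15) with roughly absolute error on the fraction.  Mixed
spheroids are seeded 1:1 or 9:1.  Every generator is a pure function of
(parameters, design, noise seed), so any dataset can be regenerated
exactly from its provenance record.

Noise law: volumes are multiplied by exp(sigma Z) with
sigma = sqrt(log(1 + cv^2)) (log-scale-unbiased, empirical CV equal to
``cv``); fractions receive additive Gaussian noise with sd = cv/2, clipped
to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .errors import DivergenceError, InvalidParameterError
from .fitting import ProportionObservation
from .growth import GrowthCurve, LogisticParams, LVParams, logistic_solution, \
    simulate_lv
from .radiation import LQParams, RadiationProtocol, irradiated_trajectory

__all__ = [
    "NoiseModel",
    "SamplingDesign",
    "IrradiatedDataset",
    "gen_homogeneous",
    "gen_mixed",
    "gen_irradiated",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative-Gaussian measurement noise with a fixed seed."""

    cv: float
    seed: int
    kind: str = "multiplicative-gaussian"

    def __post_init__(self):
        if not (math.isfinite(self.cv) and self.cv >= 0):
            raise InvalidParameterError("cv must be finite and >= 0")
        if self.kind != "multiplicative-gaussian":
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")

    def volume_factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        """Draw multiplicative factors, clipped below at 1e-6."""
        if self.cv == 0:
            return np.ones(shape)
        sigma = math.sqrt(math.log1p(self.cv ** 2))
        return np.maximum(np.exp(sigma * rng.standard_normal(shape)), 1e-6)

    def fraction_noise(self, rng: np.random.Generator, shape) -> np.ndarray:
        """Additive Gaussian perturbation for proportions (sd = cv/2)."""
        if self.cv == 0:
            return np.zeros(shape)
        return rng.normal(0.0, self.cv / 2.0, shape)


def _default_volume_times() -> np.ndarray:
    return np.arange(0.0, 16.0)


def _default_proportion_times() -> np.ndarray:
    return np.array([5.0, 10.0, 15.0])


@dataclass(frozen=True)
class SamplingDesign:
    """When volumes/proportions are measured and how many replicates.

    Defaults mirror the wet-lab design: 12 spheroids per group monitored
    daily to day 15, and proportions measured at days 5/10/15 in four
    replicate flow-cytometry experiments.
    """

    volume_times: np.ndarray = field(default_factory=_default_volume_times)
    proportion_times: np.ndarray = field(
        default_factory=_default_proportion_times)
    n_spheroids: int = 12
    n_proportion_replicates: int = 4

    def __post_init__(self):
        vt = np.asarray(self.volume_times, dtype=float)
        pt = np.asarray(self.proportion_times, dtype=float)
        if vt.size < 1 or np.any(np.diff(vt) <= 0) or np.any(vt < 0):
            raise InvalidParameterError(
                "volume_times must be strictly increasing and >= 0")
        if pt.size and (np.any(np.diff(pt) <= 0) or np.any(pt < 0)):
            raise InvalidParameterError(
                "proportion_times must be strictly increasing and >= 0")
        if self.n_spheroids < 1 or self.n_proportion_replicates < 1:
            raise InvalidParameterError(
                "n_spheroids and n_proportion_replicates must be >= 1")
        object.__setattr__(self, "volume_times", vt)
        object.__setattr__(self, "proportion_times", pt)


@dataclass(frozen=True)
class IrradiatedDataset:
    """Irradiated growth curves plus the irradiation-time metadata."""

    curves: list[GrowthCurve]
    time_of_irradiation: float
    protocol: RadiationProtocol


def gen_homogeneous(p: LogisticParams, design: SamplingDesign,
                    noise: NoiseModel, group: str = "homogeneous"
                    ) -> list[GrowthCurve]:
    """Noisy logistic growth curves for ``design.n_spheroids`` spheroids."""
    rng = np.random.default_rng(noise.seed)
    true = logistic_solution(p, design.volume_times)
    factors = noise.volume_factors(
        rng, (design.n_spheroids, design.volume_times.size))
    return [
        GrowthCurve(design.volume_times, true * factors[i],
                    label=f"s{i:03d}", group=group)
        for i in range(design.n_spheroids)
    ]


def gen_mixed(p: LVParams, design: SamplingDesign, noise: NoiseModel,
              group: str = "mixed"
              ) -> tuple[list[GrowthCurve], list[ProportionObservation]]:
    """Noisy mixed-spheroid totals plus sparse proportion observations.

    Totals are the LV solution with multiplicative noise; proportions are
    the noiseless trajectory fractions perturbed additively and clipped to
    [0, 1].  Divergent dynamics raise :class:`DivergenceError` naming the
    interaction coefficients.
    """
    rng = np.random.default_rng(noise.seed)
    grid = np.union1d(design.volume_times, design.proportion_times)
    if grid[0] != 0.0:
        grid = np.concatenate(([0.0], grid))
    try:
        traj = simulate_lv(p, grid)
    except DivergenceError as err:
        raise DivergenceError(
            f"cannot generate mixed data: dynamics diverge for "
            f"lambda_P={p.lambda_P}, lambda_RR={p.lambda_RR}",
            last_valid_time=err.last_valid_time,
        ) from err

    vol_idx = np.searchsorted(grid, design.volume_times)
    prop_idx = np.searchsorted(grid, design.proportion_times)
    true_total = traj.total[vol_idx]
    true_frac = traj.fraction_parental[prop_idx]

    factors = noise.volume_factors(
        rng, (design.n_spheroids, design.volume_times.size))
    curves = [
        GrowthCurve(design.volume_times, true_total * factors[i],
                    label=f"s{i:03d}", group=group)
        for i in range(design.n_spheroids)
    ]
    n_rep = design.n_proportion_replicates
    eps = noise.fraction_noise(rng, (n_rep, design.proportion_times.size))
    fractions = np.clip(true_frac[None, :] + eps, 0.0, 1.0)
    proportions = [
        ProportionObservation(time=float(t), fraction_P=float(fractions[k, i]),
                              group=group)
        for i, t in enumerate(design.proportion_times)
        for k in range(n_rep)
    ]
    return curves, proportions


def gen_irradiated(p: LVParams, protocol: RadiationProtocol,
                   lq_P: LQParams, lq_RR: LQParams,
                   design: SamplingDesign, noise: NoiseModel,
                   group: str = "irradiated") -> IrradiatedDataset:
    """Noisy totals from a grow -> irradiate -> regrow trajectory.

    The sampling grid and noise draws match :func:`gen_mixed`, so a zero
    dose reproduces the unirradiated curves exactly under the same seed.
    """
    rng = np.random.default_rng(noise.seed)
    traj, t_irr = irradiated_trajectory(p, protocol, lq_P, lq_RR,
                                        design.volume_times)
    factors = noise.volume_factors(
        rng, (design.n_spheroids, design.volume_times.size))
    curves = [
        GrowthCurve(design.volume_times, traj.total * factors[i],
                    label=f"s{i:03d}", group=group)
        for i in range(design.n_spheroids)
    ]
    return IrradiatedDataset(curves=curves, time_of_irradiation=t_irr,
                             protocol=protocol)
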