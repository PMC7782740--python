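"""Numeric defaults for the prostate-spheroid system.

All quantities that parameterise the default workflows live here so that a
single file documents the whole numerical setup: per-line logistic growth
parameters estimated from homogeneous PC3/DU145 spheroids, linear-quadratic
radiosensitivity constants from PC3 clonogenic assays, the default
irradiation protocol, and the default interaction-parameter grid for
regrowth landscapes.

Volumes are in mm^3, times in days, rates in day^-1, doses in Gy.
"""

from __future__ import annotations

from .growth import LogisticParams, LVParams
from .radiation import LQParams, RadiationProtocol

# Logistic fits to homogeneous spheroids (mean estimates; 95% CIs in the
# source data are not carried here).  P = parental (radiosensitive),
# RR = radioresistant.
PC3_PARENTAL = LogisticParams(r=0.293, K=0.843, V0=0.040)
PC3_RADIORESISTANT = LogisticParams(r=0.363, K=2.217, V0=0.036)
DU145_PARENTAL = LogisticParams(r=0.306, K=0.724, V0=0.030)
DU145_RADIORESISTANT = LogisticParams(r=0.210, K=1.388, V0=0.046)

LOGISTIC_PRESETS: dict[str, LogisticParams] = {
    "pc3_parental": PC3_PARENTAL,
    "pc3_rr": PC3_RADIORESISTANT,
    "du145_parental": DU145_PARENTAL,
    "du145_rr": DU145_RADIORESISTANT,
}

# In-silico 1:1 seeding volume for mixed-spheroid simulations: total seed
# volume equal to the sum of the two PC3 V0 estimates, split equally.
SEED_1TO1_V0 = 0.038


def pc3_mixed_params(lambda_P: float = 0.0, lambda_RR: float = 0.0,
                     V_P0: float = SEED_1TO1_V0,
                     V_RR0: float = SEED_1TO1_V0) -> LVParams:
    """Lotka-Volterra parameter set for mixed PC3 spheroids.

    Growth rates and carrying capacities are the homogeneous-spheroid
    estimates, held fixed; the interaction coefficients are free.
    """
    return LVParams(
        r_P=PC3_PARENTAL.r, r_RR=PC3_RADIORESISTANT.r,
        K_P=PC3_PARENTAL.K, K_RR=PC3_RADIORESISTANT.K,
        lambda_P=lambda_P, lambda_RR=lambda_RR,
        V_P0=V_P0, V_RR0=V_RR0,
    )


def du145_mixed_params(lambda_P: float = 0.0, lambda_RR: float = 0.0,
                       V_P0: float = SEED_1TO1_V0,
                       V_RR0: float = SEED_1TO1_V0) -> LVParams:
    """Lotka-Volterra parameter set for mixed DU145 spheroids."""
    return LVParams(
        r_P=DU145_PARENTAL.r, r_RR=DU145_RADIORESISTANT.r,
        K_P=DU145_PARENTAL.K, K_RR=DU145_RADIORESISTANT.K,
        lambda_P=lambda_P, lambda_RR=lambda_RR,
        V_P0=V_P0, V_RR0=V_RR0,
    )


# Linear-quadratic radiosensitivity from PC3 clonogenic survival curves
# (mean +/- SD of the fits: parental alpha 0.44+/-0.07, beta 0.04+/-0.01;
# radioresistant alpha 0.35+/-0.06, beta 0.03+/-0.01).
LQ_PC3_PARENTAL = LQParams(alpha=0.44, beta=0.04)
LQ_PC3_RADIORESISTANT = LQParams(alpha=0.35, beta=0.03)
LQ_SD_PC3_PARENTAL = LQParams(alpha=0.07, beta=0.01)
LQ_SD_PC3_RADIORESISTANT = LQParams(alpha=0.06, beta=0.01)

# Default in-silico irradiation protocol: grow to 0.9 mm^3 total volume,
# deliver a single 6 Gy fraction, follow regrowth back to 0.9 mm^3.
DEFAULT_PROTOCOL = RadiationProtocol(
    dose=6.0, trigger_volume=0.9, endpoint_volume=0.9, max_follow_up=300.0
)

# Default interaction-parameter grid for regrowth landscapes.
LANDSCAPE_LAMBDA_MIN = -0.75
LANDSCAPE_LAMBDA_MAX = 0.75
LANDSCAPE_LAMBDA_STEP = 0.05
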