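"""Published coefficient tables and count tables from the living-space trial.

These are *inputs* to worked examples and desk reproductions: the fitted
lactation-curve parameters, the mixed-model coefficient tables for the milk
residual, milk-solids and rumination models, the Cox model estimates, and the
service-outcome / progesterone-profile contingency tables. Values are stored
exactly as printed (hence finite precision; totals recomputed from them carry
rounding error, see docs/methods.md).
"""

from __future__ import annotations

from .lactation import GroupDimFixedEffects, MilkBotParams

#: Pooled lactation-curve fit (all cows, 7-day rolling volume).
MILKBOT_FIT = MilkBotParams(scale=60.19, ramp=30.2, offset=-4.33, decay=0.001782)

#: Suggested starting values for the curve fit.
MILKBOT_INIT = MilkBotParams(scale=49.0, ramp=27.0, offset=4.0, decay=0.00206)

#: Milk-volume residual model (outcome: daily milk-yield residual, litres).
#: Reference group: primiparous control space.
MILK_RESIDUAL_FIXED_EFFECTS = GroupDimFixedEffects(
    intercept=-10.31,
    dim_slope=0.03,
    group_offsets={
        "primiparous-high": 2.64,
        "multiparous-high": 16.01,
        "multiparous-control": 17.96,
    },
    group_dim_interactions={
        # printed as "0.00 (-0.01 to -0.00)"; magnitude below printed precision
        "primiparous-high": 0.00,
        "multiparous-high": -0.04,
        "multiparous-control": -0.05,
    },
)

#: Variance components of the milk-residual model.
MILK_RESIDUAL_COW_VARIANCE = 64.23
MILK_RESIDUAL_RESID_VARIANCE = 16.37

#: Rumination model (outcome: daily rumination time, minutes).
RUMINATION_FIXED_EFFECTS = GroupDimFixedEffects(
    intercept=462.9,
    dim_slope=-0.039,
    group_offsets={
        "primiparous-high": 13.05,
        "multiparous-control": 16.08,
        "multiparous-high": 32.26,
    },
    group_dim_interactions={
        "primiparous-high": -0.10,
        "multiparous-control": -0.18,
        "multiparous-high": -0.17,
    },
)

#: Milk-solids model (outcome: daily total milk solids, kg); high space is the
#: reference, so the control group adds the interaction column.
SOLIDS_INTERCEPT = 3.26
SOLIDS_CONTROL_OFFSET = 0.31
SOLIDS_DIM_POLY = (0.012, -1.5e-4, 5.9e-7, -8e-10)  # DIM^1..DIM^4
SOLIDS_CONTROL_DIM_POLY = (-0.017, 1.7e-4, -6.5e-7, 8e-10)
SOLIDS_COW_VARIANCE = 0.33
SOLIDS_RESID_VARIANCE = 0.26

#: Cox proportional-hazards estimates (hazard ratios vs primiparous control).
COX_HAZARD_RATIOS = {
    "primiparous-high": 0.48,
    "multiparous-high": 0.58,
    "multiparous-control": 0.84,
}

#: Services and conceptions by trial group (rows: high, control;
#: columns: conceived, not conceived). 120 vs 99 services, 29 vs 37 pregnancies.
SERVICE_OUTCOME_TABLE = [[29, 120 - 29], [37, 99 - 37]]

#: Progesterone profile counts by trial group (rows: high, control;
#: columns: Normal, Abnormal, DOV).
P4_PROFILE_TABLE = [[8, 12, 19], [11, 11, 17]]
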