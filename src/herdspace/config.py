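"""Herd-simulation configuration and ground-truth parameter blocks.

The truth blocks define the generating process for every synthetic input
table; their defaults are the study conditions (published fitted parameters
and effect sizes where printed, documented realistic values otherwise) so
that downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError
from .lactation import GroupDimFixedEffects, MilkBotParams


@dataclass(frozen=True)
class LactationTruth:
    """Generating parameters for daily milk volume and rumination."""

    milkbot: MilkBotParams = MilkBotParams(60.19, 30.2, -4.33, 0.001782)
    fixed: GroupDimFixedEffects = GroupDimFixedEffects(
        intercept=-10.31, dim_slope=0.03,
        group_offsets={"primiparous-high": 2.64, "multiparous-high": 16.01,
                       "multiparous-control": 17.96},
        group_dim_interactions={"primiparous-high": -0.005,
                                "multiparous-high": -0.04,
                                "multiparous-control": -0.05},
    )
    cow_variance: float = 64.23
    residual_variance: float = 16.37
    rumination_fixed: GroupDimFixedEffects = GroupDimFixedEffects(
        intercept=462.9, dim_slope=-0.039,
        group_offsets={"primiparous-high": 13.05, "multiparous-control": 16.08,
                       "multiparous-high": 32.26},
        group_dim_interactions={"primiparous-high": -0.10,
                                "multiparous-control": -0.18,
                                "multiparous-high": -0.17},
    )
    # rumination variance components are not published; realistic sensor
    # spread: between-cow SD 30 min/d, day-to-day SD 55 min/d
    rumination_cow_variance: float = 900.0
    rumination_residual_variance: float = 3025.0


@dataclass(frozen=True)
class ReproductionTruth:
    """Discrete-time conception process on the oestrous-cycle grid.

    Conception at each service is Bernoulli with the group probability
    ``1 - (1 - base)^scale``, i.e. hazard scaling on the per-cycle grid.
    Base per-service conception probability is the control group's observed
    37/99; the high-space hazard scale is the published 0.58.
    """

    voluntary_wait_days: float = 42.0
    cycle_mean: float = 21.0
    cycle_sd: float = 2.0
    cycle_min: float = 18.0
    cycle_max: float = 26.0
    detection_sensitivity: float = 0.9
    base_conception_prob: float = 37.0 / 99.0
    hazard_scale: dict = field(default_factory=lambda: {"control": 1.0,
                                                        "high": 0.58})


@dataclass(frozen=True)
class ProgesteroneTruth:
    """Template-based milk progesterone trajectories with assay noise."""

    class_mix: dict = field(default_factory=lambda: {
        "Normal": 0.25, "DOV": 0.45, "Abnormal": 0.30})
    subtype_mix: dict = field(default_factory=lambda: {
        "cessation": 1 / 3, "prolonged_luteal": 1 / 3, "short_luteal": 1 / 3})
    baseline_ng_ml: float = 1.0
    plateau_low: float = 8.0
    plateau_high: float = 14.0
    assay_cv: float = 0.132
    truncation_ng_ml: float = 20.0
    first_dim: int = 14
    last_dim: int = 84


@dataclass(frozen=True)
class BehaviourTruth:
    """Daily zone-occupancy schedules (hours) per trial group."""

    schedules: dict = field(default_factory=lambda: {
        "high": {"cubicles": 12.43, "other": 7.10, "feed_face": 3.0,
                 "robot": 0.6, "water": 0.4, "brush": 0.2, "loafing": 0.27},
        "control": {"cubicles": 11.42, "other": 8.17, "feed_face": 3.5,
                    "robot": 0.6, "water": 0.2, "brush": 0.11},
    })
    lying_sd_hours: float = 1.5
    fix_interval_s: float = 9.0
    position_sd_m: float = 0.255     # +-50 cm at 95% confidence
    dropout_rate: float = 0.0

    def __post_init__(self):
        for grp, sched in self.schedules.items():
            if sum(sched.values()) > 24.0 + 1e-9:
                raise ConfigurationError(
                    f"zone schedule for {grp!r} exceeds 24 h/day")


@dataclass(frozen=True)
class MetaboliteTruth:
    """Lognormal-ish metabolite levels with a target high-flag prevalence."""

    bhb_median: float = 0.55
    bhb_sigma: float = 0.30
    nefa_median: float = 0.40
    nefa_sigma: float = 0.35
    bhb_high_prevalence: float = 0.08
    nefa_high_prevalence: float = 0.08


@dataclass(frozen=True)
class HerdTruth:
    lactation: LactationTruth = field(default_factory=LactationTruth)
    reproduction: ReproductionTruth = field(default_factory=ReproductionTruth)
    progesterone: ProgesteroneTruth = field(default_factory=ProgesteroneTruth)
    behaviour: BehaviourTruth = field(default_factory=BehaviourTruth)
    metabolites: MetaboliteTruth = field(default_factory=MetaboliteTruth)


#: Parity composition at trial commencement (20/9/4/0/2 of 35 pairs).
DEFAULT_PARITY_MIX = {1: 20 / 35, 2: 9 / 35, 3: 4 / 35, 5: 2 / 35}


@dataclass(frozen=True)
class HerdConfig:
    """Configuration of a simulated trial herd.

    n_pairs matched cow pairs (one cow per treatment group), a parity mix,
    trial length in days and a seed driving every generator stream.
    """

    n_pairs: int = 35
    parity_mix: dict = field(default_factory=lambda: dict(DEFAULT_PARITY_MIX))
    trial_days: int = 364
    seed: int = 0
    pregnant_pair_fraction: float = 0.3
    max_entry_dim: int = 180
    truth: HerdTruth = field(default_factory=HerdTruth)

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.trial_days < 1:
            raise ConfigurationError("trial_days must be >= 1")
        total = sum(self.parity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"parity_mix proportions must sum to 1, got {total}")
        if any(p < 1 for p in self.parity_mix):
            raise ConfigurationError("parities must be >= 1")


def load_herd_config(path) -> HerdConfig:
    """Read a flat-key YAML herd configuration (missing keys -> defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("n_pairs", "trial_days", "seed", "pregnant_pair_fraction",
                "max_entry_dim"):
        if key in raw:
            kwargs[key] = raw[key]
    if "parity_mix" in raw:
        kwargs["parity_mix"] = {int(k): float(v)
                                for k, v in raw["parity_mix"].items()}
    return HerdConfig(**kwargs)


def dump_herd_config(config: HerdConfig, path) -> None:
    data = asdict(config)
    data.pop("truth")   # truth blocks are code-level defaults, not file keys
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
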