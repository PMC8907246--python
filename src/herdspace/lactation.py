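"""Two-step lactation modelling: non-linear curve plus residual mixed models.

Step one fits a four-parameter lactation curve (MilkBot form: scale, ramp,
offset, decay) to the herd's pooled milk-volume series by Levenberg-Marquardt
least squares.  Step two models the per-cow-day residuals from that curve with
a linear mixed model in days in milk (DIM) and parity-by-treatment group, with
a random intercept per cow-lactation.  The same mixed-model machinery serves
the daily-rumination outcome.  305-day totals and window means are produced
from the fixed-effect structure with random effects at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import DomainError, FitError

#: The four parity-by-treatment groups; the first is the model reference.
PARITY_GROUPS = (
    "primiparous-control",
    "primiparous-high",
    "multiparous-control",
    "multiparous-high",
)
REFERENCE_GROUP = "primiparous-control"


@dataclass(frozen=True)
class MilkBotParams:
    """Lactation-curve parameters.

    scale : asymptotic scale of the curve (L/day)
    ramp : rise time constant of early lactation (days)
    offset : horizontal shift of the ramp (days, may be negative)
    decay : exponential rate of late-lactation decline (1/day)
    """

    scale: float
    ramp: float
    offset: float
    decay: float

    def __post_init__(self):
        if self.scale <= 0:
            raise DomainError(f"scale must be > 0, got {self.scale}")
        if self.ramp == 0:
            raise DomainError("ramp must be non-zero")
        if self.ramp < 0:
            raise DomainError(f"ramp must be > 0, got {self.ramp}")
        if self.decay < 0:
            raise DomainError(f"decay must be >= 0, got {self.decay}")

    def as_array(self) -> np.ndarray:
        return np.array([self.scale, self.ramp, self.offset, self.decay])


def milkbot_predict(params: MilkBotParams, dim):
    """Daily milk volume (L) at days-in-milk ``dim`` under the curve.

    ``scale * (1 - exp((offset - dim)/ramp)/2) * exp(-decay * dim)``.
    Vectorised over ``dim``; may go negative for extreme parameters (the
    simulator clamps at zero, the fitting code does not).
    """
    dim = np.asarray(dim, dtype=float)
    out = (
        params.scale
        * (1.0 - np.exp((params.offset - dim) / params.ramp) / 2.0)
        * np.exp(-params.decay * dim)
    )
    return float(out) if out.ndim == 0 else out


def add_rolling_volume(milk: pd.DataFrame, window: int = 7, min_days: int = 4,
                       volume_col: str = "volume_l") -> pd.DataFrame:
    """Attach the trailing rolling-mean volume (``rolling7_l``) per cow.

    Trailing window of ``window`` days aligned to the current DIM, requiring at
    least ``min_days`` observed days; earlier days get NaN.
    """
    milk = milk.sort_values(["cow_lactation_id", "dim"]).copy()
    milk["rolling7_l"] = (
        milk.groupby("cow_lactation_id")[volume_col]
        .transform(lambda s: s.rolling(window, min_periods=min_days).mean())
    )
    return milk


@dataclass(frozen=True)
class MilkBotFit:
    params: MilkBotParams
    se: np.ndarray
    t_values: np.ndarray
    n_obs: int
    sse: float
    converged: bool


def fit_milkbot(milk: pd.DataFrame, init: MilkBotParams | None = None,
                source: str = "rolling", max_iter: int = 1000) -> MilkBotFit:
    """Fit the lactation curve to pooled cow-day volumes.

    Parameters
    ----------
    milk : table with ``dim`` and either ``rolling7_l`` (source="rolling",
        the default analysis series) or ``volume_l`` (source="daily").
    init : starting values; defaults to the conventional (49, 27, 4, 0.00206).
    source : which series to fit, "rolling" or "daily".

    Uses Levenberg-Marquardt least squares; standard errors come from the
    Gauss-Newton covariance at the optimum, t-values are estimate/SE.
    """
    if init is None:
        init = MilkBotParams(49.0, 27.0, 4.0, 0.00206)
    col = {"rolling": "rolling7_l", "daily": "volume_l"}[source]
    data = milk[["dim", col]].dropna()
    dim = data["dim"].to_numpy(dtype=float)
    vol = data[col].to_numpy(dtype=float)
    if np.unique(dim).size < 4:
        raise FitError("need at least 4 distinct dim values to fit 4 parameters")

    def resid(theta):
        a, b, c, d = theta
        return a * (1.0 - np.exp((c - dim) / b) / 2.0) * np.exp(-d * dim) - vol

    res = least_squares(resid, init.as_array(), method="lm",
                        ftol=1e-8, xtol=1e-8, max_nfev=max_iter * 5)
    if not res.success:
        raise FitError("lactation-curve fit did not converge",
                       last_iterate=res.x)
    dof = max(dim.size - 4, 1)
    sse = float(2.0 * res.cost)
    sigma2 = sse / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    params = MilkBotParams(*res.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = res.x / se
    return MilkBotFit(params=params, se=se, t_values=tvals,
                      n_obs=dim.size, sse=sse, converged=True)


def compute_lactation_residuals(milk: pd.DataFrame, params: MilkBotParams,
                                volume_col: str = "volume_l") -> pd.Series:
    """Observed volume minus curve prediction, per cow-day (aligned index)."""
    return milk[volume_col] - milkbot_predict(params, milk["dim"].to_numpy())


@dataclass(frozen=True)
class GroupDimFixedEffects:
    """Fixed-effect structure of the group-by-DIM models.

    ``prediction(group, dim) = intercept + offset[group]
    + (dim_slope + interaction[group]) * dim`` with the reference group
    contributing zero offset and interaction.
    """

    intercept: float
    dim_slope: float
    group_offsets: Mapping[str, float] = field(default_factory=dict)
    group_dim_interactions: Mapping[str, float] = field(default_factory=dict)
    extra_offsets: Mapping[str, float] = field(default_factory=dict)

    def predict(self, group: str, dim, extra: str | None = None):
        off = self.group_offsets.get(group, 0.0)
        inter = self.group_dim_interactions.get(group, 0.0)
        dim = np.asarray(dim, dtype=float)
        out = self.intercept + off + (self.dim_slope + inter) * dim
        if extra is not None:
            out = out + self.extra_offsets.get(extra, 0.0)
        return float(out) if out.ndim == 0 else out


def intraclass_correlation(between_variance: float, residual_variance: float) -> float:
    """Share of variance attributable to the grouping factor."""
    if between_variance < 0 or residual_variance < 0:
        raise DomainError("variance components must be non-negative")
    return between_variance / (between_variance + residual_variance)


@dataclass(frozen=True)
class GroupDimMixedFit:
    """A fitted random-intercept model of an outcome on group and DIM."""

    fixed: GroupDimFixedEffects
    table: pd.DataFrame          # estimate, se, ci_low, ci_high, p per term
    cow_variance: float
    residual_variance: float
    n_obs: int
    n_groups: int
    reference: str = REFERENCE_GROUP
    converged: bool = True

    @property
    def icc(self) -> float:
        return intraclass_correlation(self.cow_variance, self.residual_variance)

    @classmethod
    def from_coefficients(cls, fixed: GroupDimFixedEffects,
                          cow_variance: float = np.nan,
                          residual_variance: float = np.nan) -> "GroupDimMixedFit":
        """Wrap an externally reported coefficient set (e.g. a printed table)."""
        return cls(fixed=fixed, table=pd.DataFrame(), cow_variance=cow_variance,
                   residual_variance=residual_variance, n_obs=0, n_groups=0)


def _group_dim_design(groups: pd.Series, dim: np.ndarray, reference: str,
                      levels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(dim.size), dim]
    names = ["intercept", "dim"]
    for lev in levels:
        if lev == reference:
            continue
        ind = (groups == lev).to_numpy(dtype=float)
        cols.append(ind)
        names.append(f"group[{lev}]")
        cols.append(ind * dim)
        names.append(f"group[{lev}]:dim")
    return np.column_stack(cols), names


def _mixedlm_table(result, names: Iterable[str]) -> pd.DataFrame:
    names = list(names)
    k = len(names)
    ci = np.asarray(result.conf_int())[:k]
    return pd.DataFrame(
        {
            "estimate": np.asarray(result.fe_params)[:k],
            "se": np.asarray(result.bse_fe)[:k],
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": np.asarray(result.pvalues)[:k],
        },
        index=names,
    )


def fit_group_by_dim_mixed_model(data: pd.DataFrame, outcome: str,
                                 group_col: str = "parity_group",
                                 dim_col: str = "dim",
                                 id_col: str = "cow_lactation_id",
                                 reference: str = REFERENCE_GROUP,
                                 reml: bool = True) -> GroupDimMixedFit:
    """Random-intercept model: outcome ~ DIM + group + group:DIM + (1 | cow).

    Serves both the milk-residual outcome and the rumination-minutes outcome.
    REML by default (variance components); a zero cow variance is reported
    with a warning, not raised.
    """
    levels = [g for g in PARITY_GROUPS if g in set(data[group_col])]
    if reference not in levels:
        levels = [reference] + levels
    dim = data[dim_col].to_numpy(dtype=float)
    exog, names = _group_dim_design(data[group_col], dim, reference, levels)
    model = sm.MixedLM(data[outcome].to_numpy(dtype=float), exog,
                       groups=data[id_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    cow_var = float(np.asarray(result.cov_re)[0, 0])
    resid_var = float(result.scale)
    if cow_var <= 0:
        warnings.warn("singular fit: cow-intercept variance estimated at zero",
                      stacklevel=2)
    est = dict(zip(names, result.fe_params))
    fixed = GroupDimFixedEffects(
        intercept=est["intercept"],
        dim_slope=est["dim"],
        group_offsets={g: est.get(f"group[{g}]", 0.0) for g in levels
                       if g != reference},
        group_dim_interactions={g: est.get(f"group[{g}]:dim", 0.0)
                                for g in levels if g != reference},
    )
    return GroupDimMixedFit(
        fixed=fixed, table=_mixedlm_table(result, names),
        cow_variance=cow_var, residual_variance=resid_var,
        n_obs=int(data.shape[0]), n_groups=int(data[id_col].nunique()),
        reference=reference, converged=bool(result.converged),
    )


def predict_305d_yield(params: MilkBotParams,
                       fit: GroupDimMixedFit | GroupDimFixedEffects,
                       group: str) -> float:
    """Total predicted 305-day milk volume (L) for a parity-treatment group.

    Sum over DIM 1..305 of the curve prediction plus the residual-model
    fixed-effect prediction, random effects at zero.
    """
    fixed = fit.fixed if isinstance(fit, GroupDimMixedFit) else fit
    dims = np.arange(1, 306)
    return float(np.sum(milkbot_predict(params, dims) + fixed.predict(group, dims)))


def predict_mean_rumination(fit: GroupDimMixedFit | GroupDimFixedEffects,
                            group: str,
                            dim_range: tuple[int, int] = (1, 100)) -> float:
    """Mean fixed-effect rumination prediction (min/day) over an inclusive
    integer DIM range."""
    lo, hi = dim_range
    if hi < lo:
        raise DomainError(f"empty dim range {dim_range}")
    fixed = fit.fixed if isinstance(fit, GroupDimMixedFit) else fit
    dims = np.arange(lo, hi + 1)
    return float(np.mean(fixed.predict(group, dims)))
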