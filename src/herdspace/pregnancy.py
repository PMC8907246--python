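"""Milk-reproduction interplay: days-pregnant effects on yield and the
service-outcome logistic model.

Days pregnant (DP) is recoded into seven ordinal categories; the milk-residual
mixed model augmented with DP-category fixed effects separates how much of a
305-day yield difference between groups is attributable to differing
conception dates versus other treatment effects.  A mixed-effects logistic
model tests whether the 7-day rolling milk volume before a service predicts
its conception outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .errors import DomainError, FitError, SeparationError
from .lactation import (
    PARITY_GROUPS,
    REFERENCE_GROUP,
    GroupDimFixedEffects,
    GroupDimMixedFit,
    MilkBotParams,
    _group_dim_design,
    _mixedlm_table,
    milkbot_predict,
)

#: Upper bounds of days-pregnant categories 1..5; 6 is open-ended, 0 means
#: not (yet) pregnant.
DP_BOUNDS = (50, 100, 150, 200, 250)


def encode_days_pregnant(dim, conception_dim=None):
    """Ordinal days-pregnant code 0-6 for a cow-day.

    DP = dim - conception_dim when conceived and positive, else 0 (code 0).
    Codes: 1 (1-50), 2 (51-100), 3 (101-150), 4 (151-200), 5 (201-250),
    6 (250+).  Total over all inputs; vectorised.
    """
    dim = np.asarray(dim, dtype=float)
    if conception_dim is None:
        conc = np.full_like(dim, np.nan)
    else:
        conc = np.asarray(conception_dim, dtype=float)
    dp = np.where(np.isnan(conc), 0.0, dim - conc)
    dp = np.clip(dp, 0.0, None)
    code = np.digitize(dp, [0.5] + [b + 0.5 for b in DP_BOUNDS])
    code = np.where(dp <= 0, 0, code)
    return int(code) if code.ndim == 0 else code.astype(int)


def fit_dp_adjusted_model(data: pd.DataFrame, outcome: str = "milk_residual",
                          group_col: str = "parity_group", dim_col: str = "dim",
                          dp_col: str = "dp_code",
                          id_col: str = "cow_lactation_id",
                          reference: str = REFERENCE_GROUP,
                          reml: bool = True) -> GroupDimMixedFit:
    """Milk-residual mixed model augmented with DP-category fixed effects.

    DP code 0 (non-pregnant) is the reference; categories absent from the data
    are omitted with a warning.  DP effects land in
    ``fit.fixed.extra_offsets`` under keys ``"dp1"``..``"dp6"``.
    """
    levels = [g for g in PARITY_GROUPS if g in set(data[group_col])]
    dim = data[dim_col].to_numpy(dtype=float)
    exog, names = _group_dim_design(data[group_col], dim, reference, levels)
    dp = data[dp_col].to_numpy()
    present = sorted(c for c in np.unique(dp) if c != 0)
    missing = [c for c in range(1, 7) if c not in present]
    if missing:
        warnings.warn(f"DP categories absent from data, coefficients omitted: "
                      f"{missing}", stacklevel=2)
    dp_cols = [(dp == c).astype(float) for c in present]
    if dp_cols:
        exog = np.column_stack([exog] + dp_cols)
        names = names + [f"dp{c}" for c in present]
    model = sm.MixedLM(data[outcome].to_numpy(dtype=float), exog,
                       groups=data[id_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    est = dict(zip(names, result.fe_params))
    fixed = GroupDimFixedEffects(
        intercept=est["intercept"],
        dim_slope=est["dim"],
        group_offsets={g: est.get(f"group[{g}]", 0.0) for g in levels
                       if g != reference},
        group_dim_interactions={g: est.get(f"group[{g}]:dim", 0.0)
                                for g in levels if g != reference},
        extra_offsets={f"dp{c}": est[f"dp{c}"] for c in present},
    )
    return GroupDimMixedFit(
        fixed=fixed, table=_mixedlm_table(result, names),
        cow_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        n_obs=int(data.shape[0]), n_groups=int(data[id_col].nunique()),
        reference=reference, converged=bool(result.converged),
    )


def predict_305d_yield_dp(params: MilkBotParams, fit: GroupDimMixedFit,
                          group: str, conception_dim: float | None) -> float:
    """305-day yield for a group conceiving at ``conception_dim`` (None =
    never), using the DP-augmented fixed effects."""
    dims = np.arange(1, 306)
    base = milkbot_predict(params, dims) + fit.fixed.predict(group, dims)
    codes = encode_days_pregnant(dims, np.full(dims.size, conception_dim)
                                 if conception_dim is not None else None)
    dp_eff = np.array([fit.fixed.extra_offsets.get(f"dp{c}", 0.0)
                       for c in codes])
    return float(np.sum(base + dp_eff))


def decompose_yield_difference(fit: GroupDimMixedFit, params: MilkBotParams,
                               group_a: str, group_b: str,
                               conception_a: float | None,
                               conception_b: float | None,
                               common_conception: float | None = None,
                               ) -> tuple[float, float]:
    """Split a 305-day yield difference (group_a minus group_b) into the part
    attributable to differing conception dates and the remainder.

    Both groups are re-predicted at a common conception date (default: group
    b's); the attributable component is the difference-of-differences, the
    residual the rest of the total difference.
    """
    if common_conception is None:
        common_conception = conception_b
    total = (predict_305d_yield_dp(params, fit, group_a, conception_a)
             - predict_305d_yield_dp(params, fit, group_b, conception_b))
    at_common = (predict_305d_yield_dp(params, fit, group_a, common_conception)
                 - predict_305d_yield_dp(params, fit, group_b, common_conception))
    attributable = total - at_common
    return attributable, total - attributable


@dataclass(frozen=True)
class ServiceOutcomeFit:
    """Mixed logistic fit of conception-at-service (posterior summaries)."""

    table: pd.DataFrame          # estimate, se, odds_ratio per term
    cow_re_sd: float
    n_services: int
    n_cows: int

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.table.loc[term, "estimate"]))


def fit_service_outcome_model(services: pd.DataFrame,
                              outcome: str = "conceived",
                              milk_col: str = "rolling7_l",
                              dim_col: str = "dim", group_col: str = "group",
                              id_col: str = "cow_lactation_id",
                              reference: str = "high") -> ServiceOutcomeFit:
    """Probability of conception at a service from prior 7-day rolling milk
    volume, ln(DIM) and trial group, with a cow random intercept.

    Fitted by variational Bayes (logistic GLMM); posterior means/SDs are
    reported as estimates/SEs, odds ratios as exp(estimate).
    """
    y = services[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("outcome has no variation: every service "
                              f"{'conceived' if y[0] else 'failed'}")
    if (services[dim_col] <= 0).any():
        raise DomainError("dim must be positive for ln(DIM)")
    # continuous covariates are standardised for the variational solver and
    # coefficients back-transformed to the raw scale afterwards
    milk = services[milk_col].to_numpy(dtype=float)
    ln_dim = np.log(services[dim_col].to_numpy(dtype=float))
    centers = np.array([0.0, milk.mean(), ln_dim.mean(), 0.0])
    scales = np.array([1.0, max(milk.std(), 1e-12),
                       max(ln_dim.std(), 1e-12), 1.0])
    exog = np.column_stack([
        np.ones(y.size),
        (milk - centers[1]) / scales[1],
        (ln_dim - centers[2]) / scales[2],
        (services[group_col] != reference).to_numpy(dtype=float),
    ])
    names = ["intercept", "rolling7_l", "ln_dim", f"group[not {reference}]"]
    cows = pd.Categorical(services[id_col])
    vc = sparse.csr_matrix(
        (np.ones(y.size), (np.arange(y.size), cows.codes)),
        shape=(y.size, len(cows.categories)),
    )
    model = BinomialBayesMixedGLM(y, exog, vc, ident=np.zeros(vc.shape[1],
                                                              dtype=int),
                                  fep_names=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # Laplace (MAP) fit: posterior SDs track the sampling SEs much
            # more closely than the variational approximation's
            result = model.fit_map()
        except Exception:
            try:
                result = model.fit_vb()
            except Exception as exc:   # pragma: no cover - solver failure
                raise FitError(f"service-outcome GLMM failed: {exc}") from exc
    est = result.fe_mean / scales
    se = result.fe_sd / scales
    est[0] -= np.sum(est[1:3] * centers[1:3])
    table = pd.DataFrame(
        {"estimate": est, "se": se, "odds_ratio": np.exp(est)},
        index=names,
    )
    return ServiceOutcomeFit(table=table,
                             cow_re_sd=float(np.exp(result.vcp_mean[0])),
                             n_services=int(y.size),
                             n_cows=int(len(cows.categories)))
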