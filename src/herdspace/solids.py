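"""Milk-constituent (fat + protein mass) modelling.

Monthly milk-recording constituent percentages are converted to a daily solids
mass and modelled with a quartic-in-DIM mixed model with a treatment-group
main effect and group-by-DIM^k interactions, random intercept per
cow-lactation.  305-day solids totals come from the fixed-effect curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, FitError
from .lactation import intraclass_correlation

#: Milk density (kg/L) used to convert percent solids to mass.
MILK_DENSITY = 1.03

POLY_DEGREE = 4
#: DIM is divided by this before raising to powers, purely for conditioning;
#: reported coefficients are back-transformed to the raw-DIM scale.
_DIM_SCALE = 100.0


def daily_solids_mass(fat_pct, protein_pct, volume_l):
    """Daily fat+protein mass (kg): ((fat% + protein%)/100) * density * volume.

    Vectorised.  Records where both percentages are zero are missing assays
    and must be excluded upstream (see ``exclude_zero_constituents``).
    """
    fat = np.asarray(fat_pct, dtype=float)
    prot = np.asarray(protein_pct, dtype=float)
    vol = np.asarray(volume_l, dtype=float)
    if (fat < 0).any() or (prot < 0).any() or (vol < 0).any():
        raise DomainError("percentages and volumes must be non-negative")
    out = (fat + prot) / 100.0 * MILK_DENSITY * vol
    return float(out) if out.ndim == 0 else out


def exclude_zero_constituents(recording: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records where fat and protein are both zero (failed assays).

    Returns the filtered table and the number of rows removed.
    """
    bad = (recording["fat_pct"] == 0) & (recording["protein_pct"] == 0)
    return recording.loc[~bad].copy(), int(bad.sum())


@dataclass(frozen=True)
class PolyGroupMixedFit:
    """Quartic group-by-DIM mixed fit (treatment reference: high space)."""

    intercept: float
    group_offset: float                 # non-reference group main effect
    dim_poly: tuple                     # coefficients of DIM^1..4
    group_dim_poly: tuple               # non-reference interactions DIM^1..4
    cow_variance: float
    residual_variance: float
    table: pd.DataFrame
    n_obs: int = 0
    n_groups: int = 0
    reference: str = "high"

    @property
    def icc(self) -> float:
        return intraclass_correlation(self.cow_variance, self.residual_variance)

    @classmethod
    def from_coefficients(cls, intercept, group_offset, dim_poly, group_dim_poly,
                          cow_variance=np.nan, residual_variance=np.nan,
                          reference="high"):
        return cls(intercept=float(intercept), group_offset=float(group_offset),
                   dim_poly=tuple(dim_poly), group_dim_poly=tuple(group_dim_poly),
                   cow_variance=cow_variance, residual_variance=residual_variance,
                   table=pd.DataFrame(), reference=reference)

    def predict(self, group: str, dim):
        dim = np.asarray(dim, dtype=float)
        powers = np.stack([dim ** k for k in range(1, POLY_DEGREE + 1)])
        out = self.intercept + np.asarray(self.dim_poly) @ powers
        if group != self.reference:
            out = out + self.group_offset + np.asarray(self.group_dim_poly) @ powers
        return float(out) if out.ndim == 0 else out


def fit_polynomial_group_mixed_model(data: pd.DataFrame, outcome: str = "solids_kg",
                                     group_col: str = "group",
                                     dim_col: str = "dim",
                                     id_col: str = "cow_lactation_id",
                                     reference: str = "high",
                                     reml: bool = True) -> PolyGroupMixedFit:
    """Fit solids ~ group + DIM^1..4 + group:DIM^1..4 + (1 | cow-lactation)."""
    if data[dim_col].nunique() < POLY_DEGREE + 2:
        raise FitError("need at least 6 distinct dim values for a quartic "
                       "plus intercept and group effect")
    u = data[dim_col].to_numpy(dtype=float) / _DIM_SCALE
    other = (data[group_col] != reference).to_numpy(dtype=float)
    cols = [np.ones(u.size), other]
    names = ["intercept", "group"]
    for k in range(1, POLY_DEGREE + 1):
        cols.append(u ** k)
        names.append(f"dim^{k}")
    for k in range(1, POLY_DEGREE + 1):
        cols.append(other * u ** k)
        names.append(f"group:dim^{k}")
    exog = np.column_stack(cols)
    endog = data[outcome].to_numpy(dtype=float)
    model = sm.MixedLM(endog, exog, groups=data[id_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            # deterministic outcome (zero residual variance): the mixed fit
            # degenerates to ordinary least squares
            result = sm.OLS(endog, exog).fit()
            result.fe_params = result.params
            result.bse_fe = result.bse
            result.cov_re = np.zeros((1, 1))
            result.scale = float(result.mse_resid)
            result.converged = True
    est = dict(zip(names, result.fe_params))
    scale_back = np.array([_DIM_SCALE ** -k for k in range(1, POLY_DEGREE + 1)])
    kfe = len(names)
    ci = np.asarray(result.conf_int())[:kfe]
    rescale = np.ones(kfe)
    for i, nm in enumerate(names):
        if "dim^" in nm:
            k = int(nm.split("^")[1])
            rescale[i] = _DIM_SCALE ** -k
    table = pd.DataFrame(
        {
            "estimate": np.asarray(result.fe_params)[:kfe] * rescale,
            "se": np.asarray(result.bse_fe)[:kfe] * rescale,
            "ci_low": ci[:, 0] * rescale,
            "ci_high": ci[:, 1] * rescale,
            "p": np.asarray(result.pvalues)[:kfe],
        },
        index=names,
    )
    return PolyGroupMixedFit(
        intercept=est["intercept"],
        group_offset=est["group"],
        dim_poly=tuple(est[f"dim^{k}"] * scale_back[k - 1]
                       for k in range(1, POLY_DEGREE + 1)),
        group_dim_poly=tuple(est[f"group:dim^{k}"] * scale_back[k - 1]
                             for k in range(1, POLY_DEGREE + 1)),
        cow_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        table=table,
        n_obs=int(data.shape[0]), n_groups=int(data[id_col].nunique()),
        reference=reference,
    )


def predict_305d_solids(fit: PolyGroupMixedFit, group: str) -> float:
    """Total predicted solids mass (kg) over DIM 1..305, random effects at 0."""
    dims = np.arange(1, 306)
    return float(np.sum(fit.predict(group, dims)))
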