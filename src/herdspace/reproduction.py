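"""Reproduction analysis: time-to-conception survival, inter-service
intervals, milk-progesterone profile classification, commencement of luteal
activity, contingency comparisons and energy-balance flagging.

Time to conception is measured in days from calving; cows that never conceive
are right-censored at trial exit or trial end.  Progesterone profiles sampled
thrice weekly between 14 and 84 days in milk are classified by rule into
Normal, delayed ovulation (DOV) or Abnormal (cessation of cyclicity,
prolonged luteal activity, or short luteal phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy.stats import chi2_contingency

from .errors import (ClassificationError, DegenerateTableError, DomainError,
                     FitError)
from .lactation import REFERENCE_GROUP

#: First-rise threshold (ng/ml) for the delayed-ovulation rule.
P4_RISE_THRESHOLD = 3.0
#: Luteal-phase membership threshold (ng/ml).
P4_LUTEAL_THRESHOLD = 5.0
#: Delayed ovulation: first rise after this many days in milk.
DOV_DAY_LIMIT = 45
#: Cessation of cyclicity: a sub-luteal run longer than this (days).
CESSATION_LOW_DAYS = 12
#: Prolonged luteal activity: a luteal run longer than this without AI (days).
PROLONGED_LUTEAL_DAYS = 21
#: Short luteal phase: a non-first luteal run shorter than this (days).
SHORT_LUTEAL_DAYS = 10
#: Last progesterone sampling day; CLA censoring time.
P4_LAST_DIM = 84

#: Inter-service interval blocks (inclusive bounds); the final block is open.
ISI_BLOCKS = ((1, 17), (18, 26), (27, 35), (36, 52))
ISI_LABELS = ("1-17", "18-26", "27-35", "36-52", "52+")

BHB_HIGH = 1.2    # mmol/l, inclusive
NEFA_HIGH = 0.8   # mmol/l, inclusive


# ---------------------------------------------------------------- survival

def build_tte_dataset(roster: pd.DataFrame, conceptions: pd.DataFrame,
                      trial_days: int | None = None) -> pd.DataFrame:
    """Right-censored time-to-conception records for eligible cow pairs.

    Only pairs where *both* cows were non-pregnant at entry are eligible;
    pairs with a pregnant-at-entry cow are excluded whole.  Event time is the
    conception DIM; censoring time is days from calving to trial exit (or
    trial end).

    ``conceptions`` needs columns cow_lactation_id, conception_dim (NaN when
    open).
    """
    pregnant_pairs = set(roster.loc[roster["pregnant_at_entry"], "pair_id"])
    eligible = roster.loc[~roster["pair_id"].isin(pregnant_pairs)].copy()
    merged = eligible.merge(conceptions[["cow_lactation_id", "conception_dim"]],
                            on="cow_lactation_id", how="left")
    event = merged["conception_dim"].notna()
    censor_dim = merged["entry_dim"] + (merged["exit_day"]
                                        if "exit_day" in merged else trial_days)
    time = np.where(event, merged["conception_dim"], censor_dim)
    out = pd.DataFrame({
        "cow_lactation_id": merged["cow_lactation_id"],
        "group": merged["group"],
        "parity_group": merged["parity_group"],
        "time": time.astype(float),
        "event": event.astype(int),
    })
    if (out["time"] <= 0).any():
        raise DomainError("non-positive time-to-event encountered")
    return out


@dataclass
class KMEstimate:
    curves: dict                 # group -> survival DataFrame (index time)
    medians: dict                # group -> median or inf (not reached)
    risk_table: pd.DataFrame     # at-risk counts at 0/100/200/300 days

    def median(self, group):
        return self.medians[group]


def km_estimate(tte: pd.DataFrame, by: str = "group",
                risk_times=(0, 100, 200, 300)) -> KMEstimate:
    """Product-limit survival curves per group with medians and a risk table.

    Median is the first time at which S(t) <= 0.5; ``inf`` when not reached.
    """
    if tte["event"].sum() < 1:
        warnings.warn("no events: survival is flat, medians not reached",
                      stacklevel=2)
    curves, medians, risk = {}, {}, {}
    for grp, sub in tte.groupby(by):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(grp))
        curves[grp] = kmf.survival_function_
        medians[grp] = float(kmf.median_survival_time_)
        risk[grp] = [int((sub["time"] >= t).sum()) for t in risk_times]
    return KMEstimate(curves=curves, medians=medians,
                      risk_table=pd.DataFrame(risk, index=list(risk_times)).T)


@dataclass
class CoxFit:
    table: pd.DataFrame          # coef, se, HR, CI, p per covariate
    ph_test: pd.DataFrame        # Schoenfeld-residual PH test per covariate
    fitter: CoxPHFitter = field(repr=False)

    def hazard_ratio(self, term: str) -> float:
        return float(np.exp(self.table.loc[term, "coef"]))


def fit_cox_ph(tte: pd.DataFrame, covariate: str = "parity_group",
               reference: str = REFERENCE_GROUP) -> CoxFit:
    """Cox proportional-hazards fit with dummy-coded group covariates.

    Efron tie handling; a Schoenfeld-residual proportional-hazards test is
    attached.  Covariates with no variation are dropped with a warning.
    """
    levels = [l for l in pd.unique(tte[covariate]) if l != reference]
    if not levels:
        raise FitError("single-arm input: nothing to contrast")
    df = tte[["time", "event"]].copy()
    kept = []
    for lev in levels:
        col = (tte[covariate] == lev).astype(float)
        if col.nunique() < 2:
            warnings.warn(f"covariate level {lev!r} has no variation; dropped",
                          stacklevel=2)
            continue
        df[str(lev)] = col.to_numpy()
        kept.append(str(lev))
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "se": summ["se(coef)"],
        "hr": summ["exp(coef)"],
        "hr_ci_low": summ["exp(coef) lower 95%"],
        "hr_ci_high": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })
    ph = proportional_hazard_test(cph, df, time_transform="rank").summary
    return CoxFit(table=table, ph_test=ph, fitter=cph)


# ---------------------------------------------------------------- intervals

def categorize_isi(interval_days: int) -> str:
    """Inter-service interval block; 18-26 days marks a normal oestrous cycle.

    The printed 36-52 and 52+ blocks share the value 52; 52 belongs to 36-52
    and 52+ starts at 53.
    """
    if interval_days <= 0:
        raise DomainError(f"interval must be >= 1, got {interval_days}")
    for (lo, hi), label in zip(ISI_BLOCKS, ISI_LABELS):
        if lo <= interval_days <= hi:
            return label
    return ISI_LABELS[-1]


def inter_service_intervals(services: pd.DataFrame) -> pd.DataFrame:
    """Consecutive service-to-service intervals per cow, with ISI blocks."""
    rows = []
    for cow, sub in services.sort_values("dim").groupby("cow_lactation_id"):
        dims = sub["dim"].to_numpy()
        for a, b in zip(dims, dims[1:]):
            iv = int(b - a)
            rows.append({"cow_lactation_id": cow, "interval_days": iv,
                         "block": categorize_isi(iv),
                         "group": sub["group"].iloc[0]})
    return pd.DataFrame(rows, columns=["cow_lactation_id", "interval_days",
                                       "block", "group"])


# ------------------------------------------------------- progesterone rules

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def classify_p4_profile(dims, p4, ai_dims=()) -> tuple[str, str | None]:
    """Classify a milk-progesterone trajectory.

    Returns ``(class, subtype)`` with class in {"Normal", "DOV", "Abnormal"}
    and subtype in {"cessation", "prolonged_luteal", "short_luteal", None}.

    Rules (run lengths in calendar days, first-to-last sample of the run,
    because sampling is thrice weekly):

    * first rise = first sample above 3 ng/ml; after day 45 (or never) -> DOV;
    * a sub-5 ng/ml run longer than 12 days after the first luteal episode
      -> Abnormal (cessation of cyclicity);
    * a luteal (>5 ng/ml) run longer than 21 days containing no AI
      -> Abnormal (prolonged luteal activity);
    * a non-first luteal run shorter than 10 days -> Abnormal (short luteal
      phase); the first cycle is exempt (a short first phase is typical), as
      is a final run cut off by the end of sampling;
    * otherwise Normal.
    """
    dims = np.asarray(dims, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    if dims.size == 0:
        raise ClassificationError("empty progesterone series")
    if dims.size >= 2 and not (np.diff(dims) > 0).all():
        raise ClassificationError("sample days must be strictly increasing")
    ai_dims = np.asarray(list(ai_dims), dtype=float)

    rise_idx = np.nonzero(p4 > P4_RISE_THRESHOLD)[0]
    if rise_idx.size == 0 or dims[rise_idx[0]] > DOV_DAY_LIMIT:
        return "DOV", None

    luteal = p4 > P4_LUTEAL_THRESHOLD
    luteal_runs = _runs(luteal)
    if luteal_runs:
        first_end = luteal_runs[0][1]
        # sub-luteal runs after the first luteal episode (incl. trailing)
        for s, e in _runs(~luteal):
            if s > first_end and dims[e] - dims[s] > CESSATION_LOW_DAYS:
                return "Abnormal", "cessation"
    for s, e in luteal_runs:
        span = dims[e] - dims[s]
        if span > PROLONGED_LUTEAL_DAYS:
            inside_ai = ((ai_dims >= dims[s]) & (ai_dims <= dims[e])).any()
            if not inside_ai:
                return "Abnormal", "prolonged_luteal"
    for k, (s, e) in enumerate(luteal_runs):
        if k == 0:
            continue          # first-cycle exemption
        if e == len(dims) - 1:
            continue          # truncated by end of sampling, not short
        if dims[e] - dims[s] < SHORT_LUTEAL_DAYS:
            return "Abnormal", "short_luteal"
    return "Normal", None


def detect_cla(dims, p4) -> tuple[float, bool]:
    """Commencement of luteal activity: day of the first sample of the
    earliest pair of consecutive samples both above 5 ng/ml.

    Returns ``(day, censored)``; censored at 84 DIM when no such pair exists.
    """
    dims = np.asarray(dims, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    if dims.size < 2:
        return float(P4_LAST_DIM), True
    above = p4 > P4_LUTEAL_THRESHOLD
    pair = above[:-1] & above[1:]
    idx = np.nonzero(pair)[0]
    if idx.size == 0:
        return float(P4_LAST_DIM), True
    return float(dims[idx[0]]), False


# ------------------------------------------------------------- contingency

def contingency_chisq(table, correction: str | bool = "auto"):
    """Pearson chi-squared on a contingency table of counts.

    ``correction="auto"`` applies the Yates continuity correction exactly for
    2x2 tables (the convention matching the published service-outcome
    comparison); pass True/False to force.
    Returns ``(statistic, df, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DegenerateTableError("need a table of at least 2x2")
    if (arr < 0).any():
        raise DomainError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    if correction == "auto":
        correction = arr.shape == (2, 2)
    res = chi2_contingency(arr, correction=bool(correction))
    return float(res[0]), int(res[2]), float(res[1])


# -------------------------------------------------------------- metabolites

def flag_metabolite_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Flag high beta-hydroxybutyrate (>= 1.2 mmol/l) and NEFA (>= 0.8 mmol/l).

    Thresholds are inclusive.  Returns the panel with ``bhb_high`` /
    ``nefa_high`` columns added.
    """
    if (panel[["bhb_mmol_l", "nefa_mmol_l"]] < 0).any().any():
        raise DomainError("metabolite concentrations must be non-negative")
    out = panel.copy()
    out["bhb_high"] = panel["bhb_mmol_l"] >= BHB_HIGH
    out["nefa_high"] = panel["nefa_mmol_l"] >= NEFA_HIGH
    return out


def metabolite_exclusion_pairs(flagged: pd.DataFrame,
                               roster: pd.DataFrame) -> set:
    """Pairs to drop from the sensitivity survival rerun: any pair where at
    least one cow has at least one high BHB or NEFA result."""
    high_cows = set(flagged.loc[flagged["bhb_high"] | flagged["nefa_high"],
                                "cow_lactation_id"])
    return set(roster.loc[roster["cow_lactation_id"].isin(high_cows),
                          "pair_id"])
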