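"""Pipeline orchestration: simulate -> fit -> report.

Stages communicate through plain CSV files (UTF-8, header row, empty fields
for missing values) so any stage can also be run against externally supplied
tables with the same schemas.  Every exclusion rule applied is logged with a
count.  Blinded recoding replaces cow identifiers with pseudonyms and masks
group labels to A/B, reversibly via a key file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import published
from .config import HerdConfig
from .errors import SchemaError
from .lactation import (add_rolling_volume, compute_lactation_residuals,
                        fit_group_by_dim_mixed_model, fit_milkbot,
                        predict_305d_yield, predict_mean_rumination,
                        PARITY_GROUPS)
from .reproduction import (build_tte_dataset, contingency_chisq, fit_cox_ph,
                           flag_metabolite_panel, inter_service_intervals,
                           km_estimate, classify_p4_profile)
from .solids import (daily_solids_mass, exclude_zero_constituents,
                     fit_polynomial_group_mixed_model, predict_305d_solids)
from .simulate import (child_streams, simulate_locations,
                       simulate_metabolites, simulate_milk_recording,
                       simulate_milk_rumination, simulate_progesterone,
                       simulate_reproduction_events, simulate_roster)

log = logging.getLogger("herdspace")

SCHEMAS = {
    "daily_milk.csv": ["cow_lactation_id", "dim", "volume_l",
                       "rumination_min", "parity_group", "group"],
    "milk_recording.csv": ["cow_lactation_id", "dim", "fat_pct",
                           "protein_pct", "volume_l", "group"],
    "services.csv": ["cow_lactation_id", "dim", "conceived", "group"],
    "progesterone.csv": ["cow_lactation_id", "dim", "p4_ng_ml"],
    "metabolites.csv": ["cow_lactation_id", "group", "window",
                        "bhb_mmol_l", "nefa_mmol_l"],
    "locations.csv": ["cow_lactation_id", "t_s", "x_m", "y_m"],
    "roster.csv": ["cow_lactation_id", "pair_id", "group", "parity",
                   "parity_group", "entry_dim", "pregnant_at_entry",
                   "exit_day"],
}


def read_table(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}",
                          file=str(path), column=missing[0])
    return df


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    n_pairs: int = 35
    trial_days: int = 364
    stages: tuple = ("simulate", "lactation", "reproduction", "behaviour")
    rolling_source: str = "rolling"     # series fitted by the curve model
    coverage_threshold: float = 0.8
    yates_correction: str | bool = "auto"
    n_location_pairs: int = 16
    n_location_days: int = 2
    bootstrap_reps: int = 500
    blinded: bool = False
    crossover_days: tuple = ()          # trial days excluded from fitting


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    return obj


def simulate_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    herd = HerdConfig(n_pairs=config.n_pairs, trial_days=config.trial_days,
                      seed=config.seed)
    rngs = child_streams(config.seed)
    roster = simulate_roster(herd, rngs["roster"])
    milk = simulate_milk_rumination(roster, herd.truth.lactation,
                                    rngs["milk"])
    recording = simulate_milk_recording(milk, rngs["recording"])
    services, conceptions = simulate_reproduction_events(
        roster, herd.truth.reproduction, rngs["reproduction"])
    p4, p4_labels = simulate_progesterone(roster, herd.truth.progesterone,
                                          rngs["progesterone"])
    metabolites = simulate_metabolites(roster, herd.truth.metabolites,
                                       rngs["metabolites"])
    zonemap = bhv.default_zonemap()
    subset = roster.sort_values("entry_dim").groupby("pair_id").head(2)
    subset = subset[subset["pair_id"].isin(
        subset["pair_id"].unique()[:config.n_location_pairs])]
    fixes = simulate_locations(subset, zonemap, herd.truth.behaviour,
                               rngs["locations"],
                               n_days=config.n_location_days)
    tables = {"roster.csv": roster, "daily_milk.csv": milk,
              "milk_recording.csv": recording, "services.csv": services,
              "conceptions.csv": conceptions, "progesterone.csv": p4,
              "p4_labels.csv": p4_labels, "metabolites.csv": metabolites,
              "locations.csv": fixes}
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    zonemap.to_yaml(out / "zonemap.yaml")
    log.info("simulated %d cows, %d milk days, %d services",
             len(roster), len(milk), len(services))
    return {"n_cows": len(roster), "n_milk_days": len(milk),
            "n_services": len(services)}


def lactation_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    milk = read_table(out / "daily_milk.csv", "daily_milk.csv")
    if config.crossover_days:
        before = len(milk)
        milk = milk[~milk["dim"].isin(config.crossover_days)]
        log.info("excluded %d rows on cross-over days", before - len(milk))
    milk = milk[(milk["dim"] >= 1) & (milk["dim"] <= 305)]
    milk = add_rolling_volume(milk)
    curve = fit_milkbot(milk, init=published.MILKBOT_INIT,
                        source=config.rolling_source)
    milk["milk_residual"] = compute_lactation_residuals(milk, curve.params)
    mixed = fit_group_by_dim_mixed_model(milk, outcome="milk_residual")
    yields_305 = {g: predict_305d_yield(curve.params, mixed, g)
                  for g in PARITY_GROUPS}
    rum = fit_group_by_dim_mixed_model(milk, outcome="rumination_min")
    rum_means = {g: predict_mean_rumination(rum, g, (1, 100))
                 for g in PARITY_GROUPS}
    recording = read_table(out / "milk_recording.csv", "milk_recording.csv")
    recording, dropped = exclude_zero_constituents(recording)
    log.info("excluded %d zero-constituent milk recordings", dropped)
    recording["solids_kg"] = daily_solids_mass(
        recording["fat_pct"], recording["protein_pct"],
        recording["volume_l"])
    solids_fit = fit_polynomial_group_mixed_model(recording)
    report = {
        "curve": {"scale": curve.params.scale, "ramp": curve.params.ramp,
                  "offset": curve.params.offset, "decay": curve.params.decay,
                  "t_values": list(curve.t_values)},
        "milk_mixed": {"icc": mixed.icc, "cow_variance": mixed.cow_variance,
                       "residual_variance": mixed.residual_variance,
                       "coefficients": mixed.table["estimate"].to_dict()},
        "yield_305d": yields_305,
        "rumination_mean_1_100": rum_means,
        "solids_305d": {g: predict_305d_solids(solids_fit, g)
                        for g in ("high", "control")},
        "solids_icc": solids_fit.icc,
    }
    (out / "lactation_report.json").write_text(
        json.dumps(_jsonable(report), indent=2))
    return report


def reproduction_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    roster = read_table(out / "roster.csv", "roster.csv")
    services = read_table(out / "services.csv", "services.csv")
    conceptions = pd.read_csv(out / "conceptions.csv")
    p4 = read_table(out / "progesterone.csv", "progesterone.csv")
    metab = read_table(out / "metabolites.csv", "metabolites.csv")
    tte = build_tte_dataset(roster, conceptions)
    n_excluded = roster["pair_id"].nunique() - len(tte) // 2
    log.info("TTE dataset: %d cows (%d events); %d pregnant-at-entry pairs "
             "excluded", len(tte), tte["event"].sum(), n_excluded)
    km = km_estimate(tte, by="group")
    cox = fit_cox_ph(tte, covariate="parity_group")
    isi = inter_service_intervals(services)
    conc_by_group = (services.groupby("group")["conceived"]
                     .agg(["sum", "count"]))
    chi_table = [[int(conc_by_group.loc[g, "sum"]),
                  int(conc_by_group.loc[g, "count"]
                      - conc_by_group.loc[g, "sum"])]
                 for g in ("high", "control")]
    stat, df_, p = contingency_chisq(chi_table,
                                     correction=config.yates_correction)
    ai = services.groupby("cow_lactation_id")["dim"].apply(list)
    profiles = []
    for cow, sub in p4.groupby("cow_lactation_id"):
        cls, subtype = classify_p4_profile(sub["dim"], sub["p4_ng_ml"],
                                           ai.get(cow, []))
        profiles.append({"cow_lactation_id": cow, "profile_class": cls,
                         "subtype": subtype})
    profiles = pd.DataFrame(profiles).merge(
        roster[["cow_lactation_id", "group"]], on="cow_lactation_id")
    counts = (profiles.groupby(["group", "profile_class"]).size()
              .unstack(fill_value=0))
    flagged = flag_metabolite_panel(metab)
    report = {
        "km_medians": km.medians,
        "risk_table": km.risk_table,
        "cox": cox.table[["coef", "hr", "p"]].to_dict(),
        "service_outcome_chisq": {"table": chi_table, "statistic": stat,
                                  "df": df_, "p": p},
        "isi_blocks": isi.groupby(["group", "block"]).size().to_dict()
        if len(isi) else {},
        "p4_profile_counts": counts,
        "n_high_bhb": int(flagged["bhb_high"].sum()),
        "n_high_nefa": int(flagged["nefa_high"].sum()),
    }
    tte.to_csv(out / "tte.csv", index=False)
    profiles.to_csv(out / "profiles.csv", index=False)
    (out / "reproduction_report.json").write_text(
        json.dumps(_jsonable(report), indent=2))
    return report


def behaviour_stage(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    fixes = read_table(out / "locations.csv", "locations.csv")
    roster = read_table(out / "roster.csv", "roster.csv")
    zonemap = bhv.ZoneMap.from_yaml(out / "zonemap.yaml")
    minutes = bhv.minute_average_fixes(fixes)
    budgets = bhv.compute_daily_budgets(
        minutes, zonemap, roster, coverage_threshold=config.coverage_threshold)
    budgets.to_csv(out / "budgets.csv", index=False)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    cis = []
    for grp in sorted(budgets["group"].unique()):
        zones = [z for z in zonemap.zone_names(grp) if z in budgets]
        for method in ("within_cow", "all_rows"):
            cis.extend(bhv.bootstrap_budget_ci(
                budgets, grp, zones, method=method,
                n_reps=config.bootstrap_reps, seed=rng))
    ci_df = pd.DataFrame([vars(c) for c in cis])
    ci_df.to_csv(out / "budget_ci.csv", index=False)
    report = {"n_cow_days": len(budgets),
              "cubicle_hours": {
                  grp: float(budgets.loc[budgets["group"] == grp,
                                         "cubicles"].mean())
                  for grp in sorted(budgets["group"].unique())}}
    (out / "behaviour_report.json").write_text(
        json.dumps(_jsonable(report), indent=2))
    return report


def run_study_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; returns the study
    report (also written to report.json)."""
    report, timings = {}, {}
    stage_funcs = {"simulate": simulate_stage, "lactation": lactation_stage,
                   "reproduction": reproduction_stage,
                   "behaviour": behaviour_stage}
    for name in ("simulate", "lactation", "reproduction", "behaviour"):
        if name not in config.stages:
            continue
        t0 = time.perf_counter()
        report[name] = stage_funcs[name](config)
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s finished in %.2fs", name, timings[name])
    report["timings_s"] = timings
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


# ------------------------------------------------------------- blinding

def blind_recode(tables: dict, seed: int = 0,
                 ) -> tuple[dict, dict]:
    """Pseudonymise cow identifiers and mask group labels to A/B.

    The same cow gets the same pseudonym in every table; the A/B assignment
    is a seeded random permutation.  Returns (recoded tables, key); decode
    with ``blind_decode``.
    """
    rng = np.random.default_rng(seed)
    cows = sorted({c for df in tables.values()
                   if "cow_lactation_id" in df
                   for c in df["cow_lactation_id"].unique()})
    pseudo = [f"X{n:04d}" for n in rng.permutation(len(cows))]
    id_map = dict(zip(cows, pseudo))
    groups = ["high", "control"]
    masked = list(rng.permutation(["A", "B"]))
    group_map = dict(zip(groups, masked))
    recoded = {}
    for name, df in tables.items():
        df = df.copy()
        if "cow_lactation_id" in df:
            df["cow_lactation_id"] = df["cow_lactation_id"].map(id_map)
        if "group" in df:
            df["group"] = df["group"].map(group_map)
        if "parity_group" in df:
            df["parity_group"] = df["parity_group"].str.replace(
                "high", group_map["high"], regex=False).str.replace(
                "control", group_map["control"], regex=False)
        recoded[name] = df
    key = {"ids": id_map, "groups": group_map}
    return recoded, key


def blind_decode(tables: dict, key: dict) -> dict:
    """Invert ``blind_recode`` using its key file."""
    inv_ids = {v: k for k, v in key["ids"].items()}
    inv_groups = {v: k for k, v in key["groups"].items()}
    decoded = {}
    for name, df in tables.items():
        df = df.copy()
        if "cow_lactation_id" in df:
            df["cow_lactation_id"] = df["cow_lactation_id"].map(inv_ids)
        if "group" in df:
            df["group"] = df["group"].map(inv_groups)
        if "parity_group" in df:
            for masked, real in inv_groups.items():
                df["parity_group"] = df["parity_group"].str.replace(
                    masked, real, regex=False)
        decoded[name] = df
    return decoded
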