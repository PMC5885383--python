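"""CSV input/output, run configuration, and the pipeline driver."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants
from .accounting import Participant, course_summary, ffm_from_tbw, profiles_frame
from .dlw import UrineSeries
from .paf import (
    DEFAULT_SCHEME,
    MODEL_A,
    MODEL_B,
    PAFScheme,
    PredictionModel,
    assign_paf,
    derive_paf_scheme,
    evaluate_models,
    fit_prediction_model,
)

log = logging.getLogger("opsfuel")

__all__ = [
    "RunConfig",
    "read_participants",
    "write_participants",
    "read_urine_series",
    "run_pipeline",
    "constants_log",
]

REQUIRED_COLUMNS = ("id", "course", "body_mass_kg")


def read_participants(path) -> List[Participant]:
    """Load a participant table, validating every row.

    Required columns: id, course, body_mass_kg, and ffm_kg or tbw_kg (FFM is
    computed from TBW when absent). Optional: tdee_kcal_d, intake_kcal_d,
    delta_bm_kg. Row-level problems are collected and reported together with
    1-based data-row numbers, never silently dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "ffm_kg" not in df.columns and "tbw_kg" not in df.columns:
        raise ValueError(f"{path}: need an ffm_kg or tbw_kg column")

    participants: List[Participant] = []
    errors: List[str] = []
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        try:
            ffm = rec.get("ffm_kg")
            tbw = rec.get("tbw_kg")
            tbw = None if tbw is None or pd.isna(tbw) else float(tbw)
            if ffm is None or pd.isna(ffm):
                if tbw is None:
                    raise ValueError("no ffm_kg and no tbw_kg to derive it from")
                ffm = ffm_from_tbw(tbw)
            intake = rec.get("intake_kcal_d")
            intake = None if intake is None or pd.isna(intake) else float(intake)
            dbm = rec.get("delta_bm_kg")
            dbm = None if dbm is None or pd.isna(dbm) else float(dbm)
            tdee = rec.get("tdee_kcal_d", float("nan"))
            participants.append(
                Participant(
                    id=str(rec["id"]),
                    course=str(rec["course"]),
                    body_mass_kg=float(rec["body_mass_kg"]),
                    ffm_kg=float(ffm),
                    tbw_kg=tbw,
                    tdee_kcal_d=float(tdee) if not pd.isna(tdee) else float("nan"),
                    intake_kcal_d=intake,
                    delta_bm_kg=dbm,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid participant rows:\n" + "\n".join(errors))
    return participants


def write_participants(participants: Sequence[Participant], path) -> None:
    from .synthetic import write_cohort_csv

    write_cohort_csv(participants, path)


def read_urine_series(path) -> List[UrineSeries]:
    """Load long-format isotope series (columns id,isotope,time_d,enrichment).

    Rows with time_d < 0 are treated as the pre-dose baseline for that
    participant/isotope pair.
    """
    df = pd.read_csv(path)
    needed = {"id", "isotope", "time_d", "enrichment"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    out = []
    for (pid, iso), grp in df.groupby(["id", "isotope"], sort=False):
        base_rows = grp[grp["time_d"] < 0]
        if base_rows.empty:
            raise ValueError(f"{path}: no baseline (time_d < 0) row for {pid}/{iso}")
        post = grp[grp["time_d"] >= 0].sort_values("time_d")
        out.append(
            UrineSeries(
                participant_id=str(pid),
                isotope=str(iso),
                times_d=post["time_d"].to_numpy(),
                enrichments=post["enrichment"].to_numpy(),
                baseline=float(base_rows["enrichment"].iloc[0]),
            )
        )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Settings for one end-to-end analysis run."""

    participants: str                      # path to participant CSV
    out_dir: str
    scheme_source: str = "default"         # "default" | "derived"
    model_source: str = "published-A"      # published-A | published-B | fit-bm | fit-ffm
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.scheme_source not in ("default", "derived"):
            raise ValueError(f"unknown scheme_source {self.scheme_source!r}")
        if self.model_source not in ("published-A", "published-B", "fit-bm", "fit-ffm"):
            raise ValueError(f"unknown model_source {self.model_source!r}")


def constants_log(scheme: PAFScheme, model: PredictionModel) -> Dict:
    """Every constant entering the run's numbers, for the audit log."""
    return {
        "rq": constants.DEFAULT_RQ,
        "co2_kcal_per_l": constants.WEIR_A + constants.WEIR_B / constants.DEFAULT_RQ,
        "molar_volume_l_mol": constants.MOLAR_VOLUME_L_MOL,
        "ffm_hydration": constants.FFM_HYDRATION,
        "rmr_intercept": constants.RMR_INTERCEPT_KCAL_D,
        "rmr_slope_per_kg_ffm": constants.RMR_SLOPE_KCAL_D_PER_KG,
        "dit_fraction": constants.DIT_FRACTION,
        "quantile_method": "linear interpolation",
        "paf_cutpoints": list(scheme.cutpoints),
        "model": dataclasses.asdict(model),
    }


def run_pipeline(config: RunConfig):
    """Profiles -> course summary -> PAF scheme -> predictions -> evaluation.

    Writes profiles.csv, course_summary.csv, paf_assignments.csv,
    predictions.csv, evaluation.csv and run_log.yaml under ``out_dir`` and
    returns the bundle as a dict of DataFrames. Deterministic given the
    config (the seed only matters for fitted-model bootstrap extensions).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        participants = read_participants(config.participants)
    except ValueError as exc:
        raise RuntimeError(f"stage=read_participants: {exc}") from exc

    profiles = profiles_frame(participants)
    summary = course_summary(participants)
    if profiles["balance"].isna().all():
        profiles = profiles.drop(columns=["balance"])
        log.warning("no intake data: balance column omitted")

    course_pal = profiles.groupby("course", sort=False)["pal"].mean()
    try:
        scheme = (
            DEFAULT_SCHEME
            if config.scheme_source == "default"
            else derive_paf_scheme(course_pal.to_numpy())
        )
        pafs = {c: assign_paf(p, scheme) for c, p in course_pal.items()}
    except ValueError as exc:
        raise RuntimeError(f"stage=paf_scheme: {exc}") from exc

    try:
        if config.model_source == "published-A":
            model = MODEL_A
        elif config.model_source == "published-B":
            model = MODEL_B
        else:
            kind = "body_mass" if config.model_source == "fit-bm" else "ffm"
            model = fit_prediction_model(participants, kind, pafs)
    except ValueError as exc:
        raise RuntimeError(f"stage=model: {exc}") from exc

    predictions = pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "course": [p.course for p in participants],
            "paf": [pafs[p.course] for p in participants],
            "predicted_kcal_d": [
                model.predict(model.mass_of(p), pafs[p.course]) for p in participants
            ],
            "measured_kcal_d": [p.tdee_kcal_d for p in participants],
        }
    )

    have_tdee = profiles["tdee"].notna().all()
    evaluation = None
    if have_tdee:
        try:
            evaluation = evaluate_models(participants, model, pafs)
        except ValueError as exc:
            raise RuntimeError(f"stage=evaluate: {exc}") from exc

    assignments = pd.DataFrame(
        {"course": course_pal.index, "mean_pal": course_pal.to_numpy(),
         "paf": [pafs[c] for c in course_pal.index]}
    )

    profiles.to_csv(out / "profiles.csv", index=False)
    summary.to_csv(out / "course_summary.csv", index=False)
    assignments.to_csv(out / "paf_assignments.csv", index=False)
    predictions.to_csv(out / "predictions.csv", index=False)
    if evaluation is not None:
        evaluation.per_course.to_csv(out / "evaluation.csv", index=False)
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(constants_log(scheme, model), fh, sort_keys=True)

    return {
        "profiles": profiles,
        "course_summary": summary,
        "paf_assignments": assignments,
        "predictions": predictions,
        "evaluation": evaluation,
        "scheme": scheme,
        "model": model,
    }
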