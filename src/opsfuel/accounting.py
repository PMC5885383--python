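"""Body composition and energy-budget accounting.

Given a participant's total daily energy expenditure (TDEE, from doubly
labeled water) and fat-free mass (FFM, from isotope dilution), this module
derives the standard field-study energy budget:

* resting metabolic rate, RMR = 370 + 21.6 * FFM  (kcal/d)
* diet-induced thermogenesis, DIT = 0.10 * TDEE
* activity-induced energy expenditure, AIEE = TDEE - RMR - DIT
* physical activity level, PAL = TDEE / RMR
* energy balance = intake - TDEE (negative in deficit)

The decomposition RMR + DIT + AIEE = TDEE holds exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    DIT_FRACTION,
    FFM_HYDRATION,
    RMR_INTERCEPT_KCAL_D,
    RMR_SLOPE_KCAL_D_PER_KG,
)

__all__ = [
    "Participant",
    "EnergyProfile",
    "ffm_from_tbw",
    "fm_from_bm_ffm",
    "rmr_from_ffm",
    "energy_profile",
    "energy_balance",
    "course_summary",
    "profiles_frame",
]


@dataclass
class Participant:
    """One service member's anthropometry and energy measurements."""

    id: str
    course: str
    body_mass_kg: float
    ffm_kg: float
    fm_kg: float = field(default=float("nan"))
    tbw_kg: Optional[float] = None
    tdee_kcal_d: float = float("nan")
    intake_kcal_d: Optional[float] = None
    delta_bm_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.ffm_kg <= self.body_mass_kg):
            raise ValueError(
                f"participant {self.id!r}: ffm_kg={self.ffm_kg} must satisfy "
                f"0 < ffm_kg <= body_mass_kg={self.body_mass_kg}"
            )
        if math.isnan(self.fm_kg):
            self.fm_kg = fm_from_bm_ffm(self.body_mass_kg, self.ffm_kg)


@dataclass(frozen=True)
class EnergyProfile:
    """Derived energy budget for one participant (all energies kcal/d)."""

    tdee: float
    rmr: float
    dit: float
    aiee: float
    pal: float
    pct_aiee: float
    balance: Optional[float] = None


def ffm_from_tbw(tbw_kg: float) -> float:
    """Fat-free mass (kg) from total body water assuming 73% hydration."""
    if tbw_kg < 0:
        raise ValueError(f"tbw_kg must be non-negative, got {tbw_kg}")
    return tbw_kg / FFM_HYDRATION


def fm_from_bm_ffm(bm_kg: float, ffm_kg: float) -> float:
    """Fat mass (kg) = body mass - fat-free mass."""
    if ffm_kg > bm_kg:
        raise ValueError(f"ffm_kg={ffm_kg} exceeds body_mass_kg={bm_kg}")
    return bm_kg - ffm_kg


def rmr_from_ffm(ffm_kg: float) -> float:
    """Resting metabolic rate (kcal/d) from fat-free mass (kg).

    At FFM = 0 the regression intercept (370 kcal/d) is returned; negative
    mass is an error.
    """
    if ffm_kg < 0:
        raise ValueError(f"ffm_kg must be non-negative, got {ffm_kg}")
    return RMR_INTERCEPT_KCAL_D + RMR_SLOPE_KCAL_D_PER_KG * ffm_kg


def energy_balance(intake_kcal_d: float, tdee_kcal_d: float) -> float:
    """Daily energy balance (kcal/d): intake minus expenditure.

    Negative values indicate a deficit, the usual state during strenuous
    field training.
    """
    if intake_kcal_d < 0 or tdee_kcal_d < 0:
        raise ValueError("intake and expenditure must be non-negative")
    return intake_kcal_d - tdee_kcal_d


def energy_profile(
    tdee_kcal_d: float,
    ffm_kg: float,
    intake_kcal_d: Optional[float] = None,
) -> EnergyProfile:
    """Full energy budget for one participant.

    Parameters
    ----------
    tdee_kcal_d
        Total daily energy expenditure, kcal/d (> 0).
    ffm_kg
        Fat-free mass, kg (> 0); feeds the RMR estimate.
    intake_kcal_d
        Daily energy intake, kcal/d; when given, the balance is reported.
    """
    if tdee_kcal_d <= 0:
        raise ValueError(f"tdee_kcal_d must be positive, got {tdee_kcal_d}")
    rmr = rmr_from_ffm(ffm_kg)
    dit = DIT_FRACTION * tdee_kcal_d
    aiee = tdee_kcal_d - rmr - dit
    pal = tdee_kcal_d / rmr
    pct_aiee = 100.0 * aiee / tdee_kcal_d
    balance = None if intake_kcal_d is None else energy_balance(intake_kcal_d, tdee_kcal_d)
    return EnergyProfile(
        tdee=tdee_kcal_d, rmr=rmr, dit=dit, aiee=aiee,
        pal=pal, pct_aiee=pct_aiee, balance=balance,
    )


def profiles_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    """Energy profile per participant as a tidy table (one row each)."""
    rows = []
    for p in participants:
        prof = energy_profile(p.tdee_kcal_d, p.ffm_kg, p.intake_kcal_d)
        rows.append(
            {
                "id": p.id,
                "course": p.course,
                "body_mass_kg": p.body_mass_kg,
                "ffm_kg": p.ffm_kg,
                "fm_kg": p.fm_kg,
                "tdee": prof.tdee,
                "rmr": prof.rmr,
                "dit": prof.dit,
                "aiee": prof.aiee,
                "pal": prof.pal,
                "pct_aiee": prof.pct_aiee,
                "balance": np.nan if prof.balance is None else prof.balance,
            }
        )
    return pd.DataFrame(rows)


def _mean_ci(values: Sequence[float], confidence: float = 0.95):
    """Mean and t-based CI; CI is (nan, nan) for n < 2."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n < 2:
        return mean, float("nan"), float("nan")
    sem = arr.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return mean, mean - tcrit * sem, mean + tcrit * sem


def course_summary(
    participants: Sequence[Participant],
    confidence: float = 0.95,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-course mean and t-based 95% CI for each energy-budget quantity.

    Courses with a single participant get a mean with CI columns set to NaN.
    Course-level PAL is the mean of individual TDEE/RMR ratios (mean of
    ratios), matching per-participant aggregation; the ratio of course means
    can be recovered from the tdee and rmr columns if wanted.
    """
    frame = profiles_frame(participants)
    quantities = ["body_mass_kg", "ffm_kg", "fm_kg", "tdee", "rmr", "dit",
                  "aiee", "pal", "pct_aiee", "balance"]
    out_rows = []
    groups = list(frame.groupby("course", sort=False))
    if include_overall:
        groups.append(("Overall", frame))
    for name, grp in groups:
        row: dict = {"course": name, "n": len(grp)}
        for q in quantities:
            vals = grp[q].dropna().to_numpy()
            if vals.size == 0:
                row[q], row[f"{q}_ci_low"], row[f"{q}_ci_high"] = (
                    np.nan, np.nan, np.nan)
                continue
            m, lo, hi = _mean_ci(vals, confidence)
            row[q], row[f"{q}_ci_low"], row[f"{q}_ci_high"] = m, lo, hi
        out_rows.append(row)
    return pd.DataFrame(out_rows)
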