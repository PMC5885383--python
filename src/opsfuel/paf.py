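"""Physical activity factors and energy-requirement prediction equations.

Course-average physical activity levels (PAL = TDEE/RMR) are quartile-binned
into an integer physical activity factor, PAF in {0, 1, 2, 3}:

* 0 — low (briefings / mission prep), PAL <= 2.10
* 1 — low-moderate (common warrior tasks), 2.10 < PAL <= 2.40
* 2 — moderate-high (battle drills), 2.40 < PAL <= 2.75
* 3 — high (specialized intense activity), PAL > 2.75

Two published linear equations predict total daily energy expenditure
(kcal/d) from the PAF plus a mass term:

* Model A: 47.97 * BM(kg)  + 706.33 * PAF - 467.22
* Model B: 61.99 * FFM(kg) + 716.49 * PAF - 721.30

This module derives PAF schemes from PAL samples, assigns PAFs, evaluates the
published models, refits such models on new cohorts by ordinary least
squares, and compares measured vs predicted expenditures per course.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .accounting import Participant, _mean_ci

__all__ = [
    "PAFScheme",
    "PredictionModel",
    "DEFAULT_SCHEME",
    "MODEL_A",
    "MODEL_B",
    "derive_paf_scheme",
    "assign_paf",
    "predict_model_a",
    "predict_model_b",
    "fit_prediction_model",
    "evaluate_models",
]

PAF_LABELS = (
    "low (mission prep)",
    "low-moderate (common warrior tasks)",
    "moderate-high (battle drills)",
    "high (specialized intense activity)",
)


@dataclass(frozen=True)
class PAFScheme:
    """Three ascending PAL cutpoints defining four PAF categories.

    Intervals are half-open with inclusive upper bounds:
    PAF 0: pal <= c1; 1: c1 < pal <= c2; 2: c2 < pal <= c3; 3: pal > c3.
    """

    cutpoints: tuple
    labels: tuple = PAF_LABELS

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        if len(cp) != 3 or not (cp[0] < cp[1] < cp[2]):
            raise ValueError(
                f"cutpoints must be 3 strictly increasing values, got {cp}"
            )
        if len(self.labels) != 4:
            raise ValueError("exactly 4 category labels are required")


#: The published quartile scheme (PAL cutpoints 2.10 / 2.40 / 2.75), frozen so
#: downstream results never depend on the quantile estimator used to re-derive
#: it from data.
DEFAULT_SCHEME = PAFScheme(cutpoints=(2.10, 2.40, 2.75))


@dataclass(frozen=True)
class PredictionModel:
    """Linear energy-requirement model: intercept + beta_mass*mass + beta_paf*PAF.

    ``mass_kind`` selects which participant field feeds the mass term:
    "body_mass" (total body mass) or "ffm" (fat-free mass). ``see`` is the
    residual standard error of the fit, ``r`` the Pearson correlation of
    predicted with measured expenditure (both optional, populated on fits).
    """

    intercept: float
    beta_mass: float
    beta_paf: float
    mass_kind: str
    see: Optional[float] = None
    r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass_kind not in ("body_mass", "ffm"):
            raise ValueError(
                f"mass_kind must be 'body_mass' or 'ffm', got {self.mass_kind!r}"
            )

    def mass_of(self, participant: Participant) -> float:
        return (
            participant.body_mass_kg
            if self.mass_kind == "body_mass"
            else participant.ffm_kg
        )

    def predict(self, mass_kg: float, paf: float) -> float:
        if mass_kg < 0:
            raise ValueError(f"mass must be non-negative, got {mass_kg}")
        if not 0 <= paf <= 3:
            warnings.warn(
                f"PAF {paf} outside the calibrated range 0..3; extrapolating",
                stacklevel=2,
            )
        return self.intercept + self.beta_mass * mass_kg + self.beta_paf * paf


#: Published coefficients (kcal/d): total body mass + PAF.
MODEL_A = PredictionModel(
    intercept=-467.22, beta_mass=47.97, beta_paf=706.33,
    mass_kind="body_mass", see=642.0, r=0.74,
)
#: Published coefficients (kcal/d): fat-free mass + PAF.
MODEL_B = PredictionModel(
    intercept=-721.30, beta_mass=61.99, beta_paf=716.49,
    mass_kind="ffm", see=626.0, r=0.76,
)


def derive_paf_scheme(pals: Sequence[float]) -> PAFScheme:
    """Quartile cutpoints (25th/50th/75th percentiles) from PAL samples.

    Uses the linear-interpolation quantile estimator. Raises if the sample is
    too homogeneous to yield three distinct cutpoints.
    """
    arr = np.asarray(pals, dtype=float)
    if np.unique(arr).size < 4:
        raise ValueError(
            "need at least 4 distinct PAL values to derive a quartile scheme"
        )
    c1, c2, c3 = np.quantile(arr, [0.25, 0.50, 0.75], method="linear")
    if not (c1 < c2 < c3):
        raise ValueError(
            f"degenerate scheme: quartiles {c1, c2, c3} are not strictly increasing"
        )
    return PAFScheme(cutpoints=(float(c1), float(c2), float(c3)))


def assign_paf(pal: float, scheme: PAFScheme = DEFAULT_SCHEME) -> int:
    """PAF category (0..3) of a physical activity level under ``scheme``."""
    if pal <= 0:
        raise ValueError(f"pal must be positive, got {pal}")
    c1, c2, c3 = scheme.cutpoints
    if pal <= c1:
        return 0
    if pal <= c2:
        return 1
    if pal <= c3:
        return 2
    return 3


def predict_model_a(bm_kg: float, paf: float) -> float:
    """Published Model A: TDEE (kcal/d) from total body mass and PAF."""
    return MODEL_A.predict(bm_kg, paf)


def predict_model_b(ffm_kg: float, paf: float) -> float:
    """Published Model B: TDEE (kcal/d) from fat-free mass and PAF."""
    return MODEL_B.predict(ffm_kg, paf)


PafInput = Union[Sequence[float], Mapping[str, float]]


def _paf_array(participants: Sequence[Participant], pafs: PafInput) -> np.ndarray:
    if isinstance(pafs, Mapping):
        try:
            return np.asarray([pafs[p.course] for p in participants], dtype=float)
        except KeyError as exc:
            raise ValueError(f"no PAF supplied for course {exc.args[0]!r}") from None
    arr = np.asarray(pafs, dtype=float)
    if arr.size != len(participants):
        raise ValueError(
            f"got {arr.size} PAFs for {len(participants)} participants"
        )
    return arr


def fit_prediction_model(
    participants: Sequence[Participant],
    mass_kind: str,
    pafs: PafInput,
) -> PredictionModel:
    """Refit the two-covariate energy-requirement model by OLS.

    ``pafs`` is either a per-participant sequence or a course -> PAF mapping.
    PAF enters as a numeric 0-3 covariate (single slope), matching the
    published models. SEE = sqrt(RSS / (n - 3)); ``r`` is the Pearson
    correlation of fitted vs measured TDEE.
    """
    if len(participants) < 4:
        raise ValueError("need at least 4 participants to fit 3 coefficients")
    paf_arr = _paf_array(participants, pafs)
    probe = PredictionModel(0.0, 0.0, 0.0, mass_kind)
    mass = np.asarray([probe.mass_of(p) for p in participants], dtype=float)
    y = np.asarray([p.tdee_kcal_d for p in participants], dtype=float)
    if np.ptp(mass) == 0 or np.ptp(paf_arr) == 0:
        raise ValueError("singular design: both mass and PAF must vary")
    X = sm.add_constant(np.column_stack([mass, paf_arr]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design: collinear predictors")
    res = sm.OLS(y, X).fit()
    see = math.sqrt(res.ssr / (len(participants) - 3))
    r = float(stats.pearsonr(res.fittedvalues, y)[0])
    return PredictionModel(
        intercept=float(res.params[0]),
        beta_mass=float(res.params[1]),
        beta_paf=float(res.params[2]),
        mass_kind=mass_kind,
        see=see,
        r=r,
    )


@dataclass(frozen=True)
class ModelEvaluation:
    """Measured-vs-predicted comparison for one model on one cohort."""

    per_course: pd.DataFrame   # course, n, means/CIs, mean_diff, p, p_bonferroni
    r: float
    r2: float
    see: float
    f_stat: float              # omnibus F of (predicted - measured) across courses
    f_pvalue: float
    n_courses_tested: int


def evaluate_models(
    participants: Sequence[Participant],
    model: PredictionModel,
    pafs: PafInput,
) -> ModelEvaluation:
    """Compare measured and model-predicted expenditure, overall and by course.

    Per course (n >= 2): measured and predicted means with 95% CIs and a
    two-sided one-sample t-test of the paired differences, Bonferroni-adjusted
    by the number of courses tested. Courses with a single participant are
    excluded from testing with a warning. An omnibus one-way F-test asks
    whether the prediction error differs across courses. This construction is
    an approximation to a univariate ANOVA with post-hoc contrasts.
    """
    paf_arr = _paf_array(participants, pafs)
    measured = np.asarray([p.tdee_kcal_d for p in participants], dtype=float)
    predicted = np.asarray(
        [model.predict(model.mass_of(p), f) for p, f in zip(participants, paf_arr)]
    )
    diff = predicted - measured
    courses = np.asarray([p.course for p in participants])

    order = list(dict.fromkeys(courses.tolist()))
    tested = [c for c in order if np.sum(courses == c) >= 2]
    skipped = [c for c in order if c not in tested]
    if skipped:
        warnings.warn(
            f"courses with n=1 excluded from testing: {skipped}", stacklevel=2
        )
    m = len(tested)

    rows = []
    for c in order:
        mask = courses == c
        n_c = int(mask.sum())
        meas_m, meas_lo, meas_hi = _mean_ci(measured[mask])
        pred_m, pred_lo, pred_hi = _mean_ci(predicted[mask])
        row = {
            "course": c, "n": n_c,
            "measured": meas_m, "measured_ci_low": meas_lo, "measured_ci_high": meas_hi,
            "predicted": pred_m, "predicted_ci_low": pred_lo, "predicted_ci_high": pred_hi,
            "mean_diff": float(diff[mask].mean()),
            "p": np.nan, "p_bonferroni": np.nan,
        }
        if c in tested:
            if np.allclose(diff[mask], diff[mask][0]):
                # zero-variance differences: exact prediction (p=1 if diff 0)
                p = 1.0 if np.allclose(diff[mask], 0) else 0.0
            else:
                p = float(stats.ttest_1samp(diff[mask], 0.0).pvalue)
            row["p"] = p
            row["p_bonferroni"] = min(1.0, m * p)
        rows.append(row)

    if np.allclose(predicted, predicted[0]) or np.allclose(measured, measured[0]):
        r = float("nan")
    else:
        r = float(stats.pearsonr(predicted, measured)[0])
    if np.allclose(diff, 0):
        r = 1.0 if np.isnan(r) else r
    see = math.sqrt(float(np.sum((measured - predicted) ** 2)) / max(len(participants) - 3, 1))

    groups = [diff[courses == c] for c in tested]
    if m >= 2 and not np.allclose(diff, diff[0]):
        f_res = stats.f_oneway(*groups)
        f_stat, f_p = float(f_res.statistic), float(f_res.pvalue)
    else:
        f_stat, f_p = float("nan"), float("nan")

    return ModelEvaluation(
        per_course=pd.DataFrame(rows),
        r=r,
        r2=r ** 2 if not math.isnan(r) else float("nan"),
        see=see,
        f_stat=f_stat,
        f_pvalue=f_p,
        n_courses_tested=m,
    )
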