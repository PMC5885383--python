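"""Doubly-labeled-water (DLW) kinetics.

The DLW method doses a subject with water enriched in the stable isotopes
deuterium (2H) and oxygen-18 (18O). 2H leaves the body only as water; 18O
leaves as both water and CO2 (via carbonic-anhydrase exchange). The difference
between the two first-order elimination rates therefore measures CO2
production, and hence energy expenditure, over several days of free living.

Pipeline implemented here:

1. ``compute_tbw`` — total body water from isotope dilution:
   TBW (mol) = (A / MW_d) * (APE_d / 100) * 18.02
               * 1 / (R_std * (E_s - E_p)) * (1 / f_ds)
   where A is the dose mass (g), MW_d the molecular weight of the dose water
   (g/mol), APE_d its atom percent excess, R_std the heavy/light ratio of
   standard mean ocean water, E_s and E_p the post- and pre-dose urine
   enrichments, and f_ds the isotope-dilution-space correction (1.01 for 18O).
   E_s, E_p and R_std must be supplied in mutually consistent units; the
   formula is otherwise unit-agnostic.

2. ``fit_elimination_rate`` — k from log-linear least squares on the
   baseline-subtracted enrichment decay, e(t) = e0 * exp(-k t).

3. ``compute_rco2`` — CO2 production (mol/d) from body-water pool size N and
   the two rates (Schoeller's multi-point equation):
   rCO2 = (N / 2.078) * (1.01 kO - 1.04 kH) - 0.0246 * rH2Of,
   rH2Of = 1.05 * N * (1.01 kO - 1.04 kH).

4. ``energy_from_rco2`` — kcal/d via the Weir energy equivalent of CO2 at a
   food-quotient-derived respiratory quotient (default 0.86):
   kcal per liter CO2 = 1.106 + 3.941 / RQ, times 22.414 L/mol.

``compute_ee_dlw`` composes the four steps and retains every intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import (
    DEFAULT_RQ,
    DILUTION_SPACE_H2,
    DILUTION_SPACE_O18,
    EVAPORATIVE_FRACTION,
    FRACTIONATION_COEF,
    ISOTOPES,
    KH_WEIGHT,
    KO_WEIGHT,
    MOLAR_VOLUME_L_MOL,
    R_STD,
    SCHOELLER_DENOM,
    WATER_MOLAR_MASS_G_MOL,
    WEIR_A,
    WEIR_B,
)

__all__ = [
    "IsotopeDose",
    "UrineSeries",
    "DlwResult",
    "compute_tbw",
    "fit_elimination_rate",
    "compute_rco2",
    "energy_from_rco2",
    "co2_energy_equivalent",
    "compute_ee_dlw",
]


@dataclass(frozen=True)
class IsotopeDose:
    """A stable-isotope water dose for one tracer."""

    A: float                      # dose mass, g
    MW_d: float                   # molecular weight of dose water, g/mol
    APE_d: float                  # atom percent excess of dose water, %
    isotope: str                  # "2H" or "18O"
    R_std: Optional[float] = None  # defaults to the VSMOW ratio for isotope

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPES:
            raise ValueError(f"isotope must be one of {ISOTOPES}, got {self.isotope!r}")
        if self.A <= 0:
            raise ValueError(f"dose mass A must be positive, got {self.A}")
        if not (18.0 <= self.MW_d <= 22.0):
            raise ValueError(f"MW_d must lie in [18, 22] g/mol, got {self.MW_d}")
        if not (0.0 < self.APE_d <= 100.0):
            raise ValueError(f"APE_d must lie in (0, 100], got {self.APE_d}")
        if self.R_std is None:
            object.__setattr__(self, "R_std", R_STD[self.isotope])
        if self.R_std <= 0:
            raise ValueError(f"R_std must be positive, got {self.R_std}")


@dataclass
class UrineSeries:
    """Time-stamped urine enrichments for one participant and one tracer.

    ``times_d`` are days post-dose (strictly increasing); ``enrichments`` share
    whatever unit the baseline and R_std were expressed in.
    """

    participant_id: str
    isotope: str
    times_d: np.ndarray
    enrichments: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        self.times_d = np.asarray(self.times_d, dtype=float)
        self.enrichments = np.asarray(self.enrichments, dtype=float)
        if self.isotope not in ISOTOPES:
            raise ValueError(f"isotope must be one of {ISOTOPES}, got {self.isotope!r}")
        if self.times_d.size != self.enrichments.size:
            raise ValueError("times_d and enrichments must have equal length")
        if self.times_d.size < 2:
            raise ValueError("at least 2 post-dose samples are required")
        if np.any(np.diff(self.times_d) <= 0):
            raise ValueError("times_d must be strictly increasing")
        if not np.all(np.isfinite(self.enrichments)):
            raise ValueError("enrichments must be finite")


@dataclass(frozen=True)
class DlwResult:
    """All quantities derived from one participant's DLW study."""

    participant_id: str
    tbw_mol: float
    tbw_kg: float
    kO: float                 # 1/d
    kH: float                 # 1/d
    rh2of: float              # fractionated evaporative water loss, mol/d
    rco2: float               # mol/d
    tdee: float               # kcal/d
    rq: float
    negative_production: bool = field(default=False)


def _dilution_space(isotope: str, use_h2_space: bool) -> float:
    if isotope == "18O":
        return DILUTION_SPACE_O18
    return DILUTION_SPACE_H2 if use_h2_space else DILUTION_SPACE_O18


def compute_tbw(
    dose: IsotopeDose,
    e_final: float,
    e_predose: float,
    use_h2_dilution_space: bool = False,
) -> Tuple[float, float]:
    """Total body water from isotope dilution.

    Returns ``(tbw_mol, tbw_kg)``. By default the printed dilution-space
    factor 1/1.01 is applied regardless of tracer; pass
    ``use_h2_dilution_space=True`` to use 1/1.04 for a 2H dose instead.

    Raises if the post-dose enrichment does not exceed the baseline (no
    dilution gradient, or inconsistent enrichments).
    """
    gradient = e_final - e_predose
    if gradient == 0:
        raise ValueError(
            "e_final equals e_predose: isotope dilution is undefined "
            "without an enrichment gradient"
        )
    f_ds = _dilution_space(dose.isotope, use_h2_dilution_space)
    tbw_mol = (
        (dose.A / dose.MW_d)
        * (dose.APE_d / 100.0)
        * WATER_MOLAR_MASS_G_MOL
        * (1.0 / (dose.R_std * gradient))
        * (1.0 / f_ds)
    )
    if tbw_mol <= 0:
        raise ValueError(
            f"inconsistent enrichments: e_final={e_final} below "
            f"e_predose={e_predose} yields non-positive body water"
        )
    return tbw_mol, tbw_mol * WATER_MOLAR_MASS_G_MOL / 1000.0


def fit_elimination_rate(series: UrineSeries) -> Tuple[float, float]:
    """Isotope elimination rate by log-linear least squares.

    Fits ln(e(t) - baseline) = ln(e0) - k*t by ordinary least squares over all
    usable post-dose samples and returns ``(k, e0_excess)`` where ``k`` (1/d)
    is the negative slope and ``e0_excess`` the back-extrapolated zero-time
    enrichment above baseline. Samples at or below baseline carry no tracer
    signal and are dropped with a warning; fewer than two usable samples is an
    error.
    """
    excess = series.enrichments - series.baseline
    usable = excess > 0
    if not np.all(usable):
        dropped = series.times_d[~usable]
        warnings.warn(
            f"series {series.participant_id}/{series.isotope}: dropping "
            f"{dropped.size} sample(s) at or below baseline (t={dropped.tolist()})",
            stacklevel=2,
        )
    t = series.times_d[usable]
    y = np.log(excess[usable])
    if t.size < 2:
        raise ValueError(
            f"series {series.participant_id}/{series.isotope}: fewer than 2 "
            "samples above baseline; cannot fit an elimination rate"
        )
    slope, intercept = np.polyfit(t, y, 1)
    return -float(slope), float(np.exp(intercept))


def compute_rco2(n_mol: float, kO: float, kH: float) -> Tuple[float, float]:
    """CO2 production rate (mol/d) and evaporative water loss (mol/d).

    Negative production (1.01*kO < 1.04*kH, physically a measurement
    inconsistency) is returned as-is with a warning, never clipped.
    """
    if n_mol <= 0:
        raise ValueError(f"body water pool n_mol must be positive, got {n_mol}")
    if kO < 0 or kH < 0:
        raise ValueError("elimination rates must be non-negative")
    turnover = KO_WEIGHT * kO - KH_WEIGHT * kH
    rh2of = EVAPORATIVE_FRACTION * n_mol * turnover
    rco2 = (n_mol / SCHOELLER_DENOM) * turnover - FRACTIONATION_COEF * rh2of
    if rco2 < 0:
        warnings.warn(
            f"negative CO2 production ({rco2:.4g} mol/d): 1.01*kO < 1.04*kH",
            stacklevel=2,
        )
    return rco2, rh2of


def co2_energy_equivalent(rq: float = DEFAULT_RQ) -> float:
    """Energy equivalent of CO2 (kcal/mol) at respiratory quotient ``rq``.

    Weir: kcal per liter CO2 = 1.106 + 3.941/RQ; one mole of gas occupies
    22.414 L at STP. At RQ 0.86 this is ~127.5 kcal/mol.
    """
    if not (0.7 <= rq <= 1.0):
        raise ValueError(f"rq must lie in the physiologic range [0.7, 1.0], got {rq}")
    return MOLAR_VOLUME_L_MOL * (WEIR_A + WEIR_B / rq)


def energy_from_rco2(rco2_mol_d: float, rq: float = DEFAULT_RQ) -> float:
    """Total daily energy expenditure (kcal/d) from CO2 production."""
    if rco2_mol_d < 0:
        raise ValueError(f"rco2_mol_d must be non-negative, got {rco2_mol_d}")
    return rco2_mol_d * co2_energy_equivalent(rq)


def compute_ee_dlw(
    dose_pair: Sequence[IsotopeDose],
    series_pair: Sequence[UrineSeries],
    rq: float = DEFAULT_RQ,
    tbw_isotope: str = "18O",
) -> DlwResult:
    """Full DLW computation for one participant.

    Parameters
    ----------
    dose_pair, series_pair
        One dose and one urine series per tracer; both 2H and 18O must be
        present.
    rq
        Respiratory quotient for the energy equivalent of CO2.
    tbw_isotope
        Tracer whose dilution defines total body water (default 18O).

    The post-dose enrichment used for the dilution is the zero-time intercept
    of the log-linear elimination fit, which equals the first post-dose sample
    exactly for noiseless mono-exponential decay and is noise-robust
    otherwise.
    """
    doses = {d.isotope: d for d in dose_pair}
    series = {s.isotope: s for s in series_pair}
    for iso in ISOTOPES:
        if iso not in doses or iso not in series:
            raise ValueError(f"missing dose or urine series for isotope {iso}")

    kH, _ = fit_elimination_rate(series["2H"])
    kO, _ = fit_elimination_rate(series["18O"])

    s_tbw = series[tbw_isotope]
    _, e0_excess = fit_elimination_rate(s_tbw)
    tbw_mol, tbw_kg = compute_tbw(
        doses[tbw_isotope], s_tbw.baseline + e0_excess, s_tbw.baseline
    )
    rco2, rh2of = compute_rco2(tbw_mol, kO, kH)
    negative = rco2 < 0
    tdee = energy_from_rco2(max(rco2, 0.0), rq) if negative else energy_from_rco2(rco2, rq)
    pid = s_tbw.participant_id
    return DlwResult(
        participant_id=pid,
        tbw_mol=tbw_mol,
        tbw_kg=tbw_kg,
        kO=kO,
        kH=kH,
        rh2of=rh2of,
        rco2=rco2,
        tdee=tdee,
        rq=rq,
        negative_production=negative,
    )
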