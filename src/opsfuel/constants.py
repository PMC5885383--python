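"""Physical and physiological constants used throughout the package.

Every constant that enters a reported number is defined here once, so a run
log can state exactly which values produced the output.
"""

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS_G_MOL = 18.02

#: Hydration fraction of fat-free tissue: FFM = TBW / 0.73.
FFM_HYDRATION = 0.73

#: Resting metabolic rate from fat-free mass (kcal/d): RMR = 370 + 21.6*FFM.
RMR_INTERCEPT_KCAL_D = 370.0
RMR_SLOPE_KCAL_D_PER_KG = 21.6

#: Diet-induced thermogenesis as a fraction of total expenditure.
DIT_FRACTION = 0.10

#: Respiratory quotient assumed from the average field-ration food quotient.
DEFAULT_RQ = 0.86

#: Molar volume of an ideal gas at STP, L/mol (converts kcal/L CO2 to kcal/mol).
MOLAR_VOLUME_L_MOL = 22.414

#: Weir coefficients: energy equivalent of CO2 in kcal per liter is
#: 1.106 + 3.941/RQ.
WEIR_A = 1.106
WEIR_B = 3.941

#: CO2 production from isotope turnover (Schoeller two-point/multi-point form):
#: rCO2 = (N/2.078)*(1.01*kO - 1.04*kH) - 0.0246*rH2Of, with the fractionated
#: evaporative water loss rH2Of estimated as 1.05*N*(1.01*kO - 1.04*kH).
SCHOELLER_DENOM = 2.078
KO_WEIGHT = 1.01
KH_WEIGHT = 1.04
FRACTIONATION_COEF = 0.0246
EVAPORATIVE_FRACTION = 1.05

#: Isotope-dilution space corrections: the 18O (2H) dilution space exceeds
#: total body water by ~1% (~4%).
DILUTION_SPACE_O18 = 1.01
DILUTION_SPACE_H2 = 1.04

#: Heavy/light isotope abundance ratios of Vienna Standard Mean Ocean Water.
R_STD = {"18O": 2.0052e-3, "2H": 1.5576e-4}

#: Recognised isotope labels.
ISOTOPES = ("2H", "18O")
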