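# Default reference configuration: conventional literature values, clearly
# replaceable. Screening values: surface-water Class III limits (ug/L),
# regional soil geochemical backgrounds (mg/kg), food contaminant limits for
# vegetables (mg/kg). Crop screening intentionally omits Mo and V: no unified
# contamination criteria exist for those elements in crops, so crop indices
# exclude them via absent screening values.
screening:
  surface_water:   # ug/L
    Pb: 50.0
    Cr: 50.0
    Ni: 20.0
    Cu: 1000.0
    Zn: 1000.0
    As: 50.0
    Mo: 70.0
    Cd: 5.0
    Sb: 5.0
    V: 50.0
  soil:            # mg/kg, regional background
    Pb: 26.0
    Cr: 63.8
    Ni: 26.9
    Cu: 22.6
    Zn: 74.2
    As: 11.2
    Mo: 0.5
    Cd: 0.3
    Sb: 0.9
    V: 82.0
  crop:            # mg/kg fresh-weight contaminant limits (vegetables)
    Pb: 0.1
    Cr: 0.5
    Ni: 0.5
    Cu: 10.0
    Zn: 20.0
    As: 0.5
    Cd: 0.05
    Sb: 1.0

# Hakanson toxicity response coefficients; Sb/Mo/V are literature extensions.
toxicity:
  Pb: 5.0
  Cr: 2.0
  Ni: 5.0
  Cu: 5.0
  Zn: 1.0
  As: 10.0
  Mo: 5.0
  Cd: 30.0
  Sb: 7.0
  V: 2.0

# Reference doses, mg/kg/day, per exposure pathway.
rfd:
  Pb: {ingestion: 3.5e-3, dermal: 5.25e-4, inhalation: 3.52e-3}
  Cr: {ingestion: 3.0e-3, dermal: 6.0e-5, inhalation: 2.86e-5}
  Ni: {ingestion: 2.0e-2, dermal: 5.4e-3, inhalation: 2.06e-2}
  Cu: {ingestion: 4.0e-2, dermal: 1.2e-2, inhalation: 4.02e-2}
  Zn: {ingestion: 3.0e-1, dermal: 6.0e-2, inhalation: 3.0e-1}
  As: {ingestion: 3.0e-4, dermal: 1.23e-4, inhalation: 3.01e-4}
  Mo: {ingestion: 5.0e-3, dermal: 1.9e-3, inhalation: 5.0e-3}
  Cd: {ingestion: 1.0e-3, dermal: 2.5e-5, inhalation: 1.0e-3}
  Sb: {ingestion: 4.0e-4, dermal: 8.0e-6, inhalation: 4.0e-4}
  V: {ingestion: 7.0e-3, dermal: 7.0e-5, inhalation: 7.0e-3}

# Cancer slope factors, (mg/kg/day)^-1. Elements without entries contribute
# only to non-carcinogenic risk.
slope:
  Pb: {ingestion: 8.5e-3}
  Cr: {ingestion: 0.5, dermal: 20.0, inhalation: 42.0}
  Ni: {ingestion: 1.7, dermal: 42.5, inhalation: 0.84}
  As: {ingestion: 1.5, dermal: 3.66, inhalation: 15.1}
  Cd: {ingestion: 6.1, inhalation: 6.3}

# Factor converting a raw concentration in the medium's native unit to the
# mg-based quantity in the intake equations: 1e-6 for mg/kg media (intake
# rate in mg/day), 1e-3 for ug/L water (intake rate in L/day).
unit_factor:
  surface_water: 1.0e-3
  soil: 1.0e-6
  crop: 1.0e-6

# Element-specific dermal absorption fractions overriding the generic abs.
abs_override:
  As: 0.03

# Exposure parameters per population and medium. Bare numbers are point
# values; mappings give Monte Carlo sampling distributions. Units:
# r_ing mg/day (soil) or L/day (water); r_inh m3/day; ef days/year;
# ed years; bw kg; sa cm2; af mg/cm2/day; abs dimensionless; pef m3/kg.
# Water omits r_inh/pef: no airborne particulate pathway is meaningful.
exposure:
  child:
    soil:
      r_ing: {kind: lognormal, mean: 200.0, sd: 60.0, truncation: [0.0, null]}
      r_inh: {kind: normal, mean: 7.5, sd: 1.5, truncation: [0.0, null]}
      ef: {kind: triangular, left: 335.0, mode: 350.0, right: 365.0}
      ed: 6.0
      bw: {kind: normal, mean: 15.0, sd: 2.3, truncation: [0.0, null]}
      sa: {kind: normal, mean: 2800.0, sd: 400.0, truncation: [0.0, null]}
      af: {kind: uniform, low: 0.1, high: 0.3}
      abs: 0.001
      pef: 1.36e+9
    surface_water:
      r_ing: {kind: normal, mean: 0.7, sd: 0.15, truncation: [0.0, null]}
      ef: {kind: triangular, left: 335.0, mode: 350.0, right: 365.0}
      ed: 6.0
      bw: {kind: normal, mean: 15.0, sd: 2.3, truncation: [0.0, null]}
      sa: {kind: normal, mean: 2800.0, sd: 400.0, truncation: [0.0, null]}
      af: {kind: uniform, low: 0.1, high: 0.3}
      abs: 0.001
  adult:
    soil:
      r_ing: {kind: lognormal, mean: 100.0, sd: 30.0, truncation: [0.0, null]}
      r_inh: {kind: normal, mean: 14.5, sd: 2.0, truncation: [0.0, null]}
      ef: {kind: triangular, left: 335.0, mode: 350.0, right: 365.0}
      ed: 24.0
      bw: {kind: normal, mean: 60.0, sd: 9.0, truncation: [0.0, null]}
      sa: {kind: normal, mean: 5700.0, sd: 800.0, truncation: [0.0, null]}
      af: {kind: uniform, low: 0.04, high: 0.1}
      abs: 0.001
      pef: 1.36e+9
    surface_water:
      r_ing: {kind: normal, mean: 2.0, sd: 0.4, truncation: [0.0, null]}
      ef: {kind: triangular, left: 335.0, mode: 350.0, right: 365.0}
      ed: 24.0
      bw: {kind: normal, mean: 60.0, sd: 9.0, truncation: [0.0, null]}
      sa: {kind: normal, mean: 5700.0, sd: 800.0, truncation: [0.0, null]}
      af: {kind: uniform, low: 0.04, high: 0.1}
      abs: 0.001
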