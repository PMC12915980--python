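# Published per-type length-mass power-law coefficients, v1.
# Fitted on n = 873 vessels as log(mass_kg) = slope * log(loa_m) + intercept
# (natural log), one (intercept, slope) pair per vessel type; multiplier and
# exponent are the printed power-law form mass_kg = multiplier * loa_m^exponent.
# Intercepts/slopes and their standard errors are on the log-kg scale and are
# transcribed at the precision at which they were published.
version: "1"
provenance: "peer-reviewed length-mass regression on 873 vessels, twelve types; coefficients transcribed at printed precision"
types:
  bulk_carrier:
    {intercept: 1.729, intercept_se: 1.117, slope: 3.058, slope_se: 0.208, multiplier: 5.64, exponent: 3.06}
  container_ship:
    {intercept: 4.459, intercept_se: 0.917, slope: 2.461, slope_se: 0.168, multiplier: 86.40, exponent: 2.46}
  cruise:
    {intercept: 4.580, intercept_se: 0.786, slope: 2.281, slope_se: 0.147, multiplier: 97.51, exponent: 2.28}
  ferry:
    {intercept: 3.225, intercept_se: 0.691, slope: 2.619, slope_se: 0.153, multiplier: 25.15, exponent: 2.62}
  fishing:
    {intercept: -0.344, intercept_se: 0.185, slope: 3.785, slope_se: 0.061, multiplier: 0.71, exponent: 3.79}
  government_research:
    {intercept: 1.083, intercept_se: 0.455, slope: 3.217, slope_se: 0.112, multiplier: 2.95, exponent: 3.22}
  other:
    {intercept: 0.973, intercept_se: 0.364, slope: 3.354, slope_se: 0.085, multiplier: 2.64, exponent: 3.35}
  passenger:
    {intercept: 1.463, intercept_se: 0.358, slope: 3.081, slope_se: 0.122, multiplier: 4.32, exponent: 3.08}
  pleasure_craft:
    {intercept: 3.540, intercept_se: 0.261, slope: 2.685, slope_se: 0.073, multiplier: 34.47, exponent: 2.68}
  sailing:
    {intercept: 0.2082, intercept_se: 0.298, slope: 3.529, slope_se: 0.106, multiplier: 1.23, exponent: 3.53}
  tanker:
    {intercept: 1.981, intercept_se: 1.154, slope: 3.032, slope_se: 0.219, multiplier: 7.25, exponent: 3.03}
  tug:
    {intercept: 4.649, intercept_se: 0.508, slope: 2.512, slope_se: 0.136, multiplier: 104.48, exponent: 2.51}
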