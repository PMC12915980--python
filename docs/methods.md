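# Methods

## The estimation problem

Size-aware whale-strike lethality models need a vessel's displacement Δ
(total mass, kg), which equals the light-ship weight W_L plus the deadweight
tonnage DWT (cargo, fuel, crew, passengers, provisions, non-permanent
ballast). Static AIS reports LOA (m) and maximum DWT (tonnes); vessel
catalogues report displacement or net weight for small craft; gross tonnage
is a volume measure and is never used as a mass. The package therefore has
two layers: a *record-level* converter that turns whatever mass-adjacent
field a record has into kg, and a *type-level* power law linking LOA to the
converted masses.

## Record-level conversion

Dispatch order per record: a reported displacement passes through
unchanged; otherwise a net weight is corrected by (75 + 20) kg per person
up to the maximum capacity (one person when the capacity is unknown, since
someone is aboard); otherwise the type's DWT strategy applies.

DWT strategies take three functional forms — ratio Δ = s·DWT, linear
Δ = s·DWT + c, power Δ = s·DWT^e — each tagged with the unit its result is
expressed in. DWT is always fed in as reported (tonnes); the *output* of the
bulk-carrier, container-ship and tanker equations is interpreted as U.S.
customary tons and converted at 1016 kg/ton, the rest at 1000 kg/tonne. The
sources do not state the input dialect of the footnoted equations; treating
only the output as U.S. tons matches the stated workflow of the procedure
these equations come from, and is a deliberate interpretation recorded
here.

Ratio strategies are reciprocals of a class deadweight coefficient
C_D = DWT/Δ. Class tables give C_D as two (LOA, C_D) endpoints; the
coefficient at a given length is obtained by linear interpolation, clamped
to the endpoint outside the range, and rounded to 3 decimals (the precision
at which such ratios are quoted). Linear interpolation with clamping
reproduces every quoted class ratio — 0.243, 0.233, 0.334, 0.478, 0.176,
0.580 (clamped), 0.212, 0.167, 0.159, 0.155 — which we take as confirmation
of both choices. The default mode fixes one C_D per type, anchored at the
type's sample-average LOA, because that is how the shipped ratio multipliers
(4.1152, 4.2918, 2.9940, 5.988, 6.2893, 6.4516 — each 1/C_D to 4 decimals)
were derived; per-record interpolation at each vessel's own LOA is available
as an opt-in (`per_record_cd=True`).

Heterogeneous categories (government/research, "other") mix hull forms, so
their estimate is the unweighted arithmetic mean of three estimates —
container-ship equation, stern-trawler C_D, small-passenger C_D, the
coefficients evaluated at the category's AIS-subsample average LOA (68.1 m
and 93.4 m respectively) — with every component converted to kg *before*
averaging; the order matters because the components carry different units.

Replicate removal: two vessels of the same type with identical LOA and DWT
are treated as the same model and collapsed to the first occurrence in file
order (the keep-first tie-break is our convention; records without DWT key
on displacement instead). LOA outside [3 m, 450 m] warns rather than
errors, spanning dinghies to the largest container ships.

## The regression

OLS on natural logs with a full vessel-type interaction:

    log Δ_i = a_{t(i)} · log LOA_i + b_{t(i)} + ε_i ,  ε_i ~ N(0, σ²)

Natural logs are required so the back-transform Δ = e^b·LOA^a yields the
power form directly; the slope is the length-elasticity of mass (≈3 for
isometric hulls). Two parameterisations of the same model are fitted: the
treatment-coded interaction model supplies the overall F statistic and
adjusted R² (24 parameters, so F has (23, n−24) df on twelve types), and a
cell-means parameterisation (`0 + C(type) + C(type):log_loa`) reads off each
type's absolute (a, b) and standard errors — identical to what a refit with
that type as reference level reports, without twelve refits. Residual
normality (Shapiro–Wilk) and homoscedasticity (Breusch–Pagan) summaries and
a |r| > 3 SD outlier count are emitted as diagnostics, never as gates.

All-pairs type comparisons use *literal releveling*: the model is refit
with each type as the reference level and the reported p-values for the
other types' intercept and slope terms are collected into symmetric
matrices. No multiple-testing correction is applied by default (matching
the procedure the coefficients come from); Bonferroni over the 66 unordered
pairs is available as an option. An independent covariance-based route
(t-tests of linear contrasts on the cell-means fit) must agree with the
releveling route; their agreement is asserted in the test suite at 1e-8 on
the p-values, and releveling invariance of the fitted values at 1e-10
relative.

## Published coefficients

The shipped bundle stores, per type, the log-scale (intercept, slope) with
standard errors at printed precision *and* the printed (multiplier,
exponent) power form. Printed multipliers were evidently computed from
unrounded intercepts (e.g. exp(1.729) = 5.635 vs the printed 5.64), so the
loader enforces consistency at 1% rather than exactly; two rows
(container ship 86.40, tug 104.48) agree exactly at printed precision. SEs
are metadata only: the full coefficient covariance is not published, so no
prediction intervals are derived from the bundle.

## Synthetic fleets

The generator emulates the reference sample's structure, not any real
fleet. Per type it draws n LOA values from a truncated normal with the
observed mean, SD and range (873 vessels total across twelve types, the
observed per-type counts and AIS/catalogue split), then sets
mass = multiplier·LOA^exponent·exp(ε), ε ~ N(0, σ_log²), generating from
the published bundle by default. AIS-style records then carry only a DWT,
obtained by inverting the type's conversion strategy at the noisy mass
(analytically for ratios; Brent's method at 1e-9 relative for power, linear
and mixed forms, which are strictly increasing); catalogue-style records
carry the displacement directly. Estimation followed by refitting is
therefore an exact round trip of the generating law, which is what makes
parameter-recovery a sharp test. One edge case: extreme downward noise can
push a mass below a linear strategy's DWT = 0 floor (the tanker offset);
such records clamp to DWT = 0, a ~2e-5-probability event per tanker record
with negligible effect on fits.

Default σ_log = 0.2 is a modelling choice (dispersion visually consistent
with the reference scatter), not a published value. The truncated normal is
likewise a stand-in: only summary statistics of the LOA distributions are
published, and some types imply heavy truncation (fishing: mean 25.9 ± 22.2
on [4.6, 104.5]), so the realised per-type mean is compared against the
*truncated* distribution's mean in tests. What passing synthetic tests show
is that the pipeline recovers a power law it generated — they cannot
validate the conversion strategies against real hulls, the representativeness
of the original sample, or regional/temporal fleet composition (construction
year and region are deliberately excluded covariates).

At the default conditions (Table-style sizes, σ_log = 0.2, seeds 0–99) the
refit slopes of all twelve types fall within ±3 SE of the generating
exponents in 95 of 100 seeds, and noiseless fleets recover coefficients to
1e-8; refits at σ_log ∈ [0.15, 0.3] keep adjusted R² above 0.9. These are
consistency checks of the pipeline, not reproductions of the original fit,
whose own statistics require the original dataset.

## Lethality harness

The harness reproduces the standard demonstration design: six types
(container ship, cruise, ferry, pleasure craft, sailing, tug) × LOA
{10, 20, 50, 100} m × {10, 20} kn (1 kn = 1.852 km/h, so 10 kn = 5.144 m/s),
with the flared-bow impact area held constant at 1.15 m × 1.15 m across
vessel sizes, masses from the published equations, against an adult North
Atlantic right whale tag. The biophysical collision model itself is out of
scope and is consumed only through the contract
`(mass_kg, speed_m_s, area_m², whale_tag) → p ∈ [0, 1]`; outputs outside
[0, 1] raise, naming the offending grid cell. The built-in stand-in is a
documented toy logistic, p = expit(0.75·ln m + 0.5·v − 10) — deterministic,
strictly increasing in mass and speed, asymptote 1, labelled "toy" in every
output — sufficient to test grid completeness and the monotonicity that any
mass-monotone model must inherit from the length–mass equations, and
nothing more.

## Numerical and design notes

- All randomness flows from a single `numpy.random.default_rng(seed)`; no
  global state. Identical seeds give byte-identical simulated CSVs.
- Coefficient rounding to printed precision (2 decimals) is display-only;
  full precision is carried everywhere internally.
- `fit_loglog` refuses types with fewer than 2 records or fewer than 2
  distinct LOA values (the slope would be unidentified) and any non-positive
  mass or length; degenerate single-type inputs fit but cannot produce
  contrasts.
- Strategy tables and coefficient bundles are versioned YAML, overridable
  per run (`--strategy-file`, `--coefficient-file`), and validated on load
  (twelve types present, multipliers consistent with intercepts at 1%).
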