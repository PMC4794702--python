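# Methods

`droughtwue` implements an analysis chain for the question: *does drought
raise or lower ecosystem water-use efficiency (WUE = GPP/ET), and through
which flux?*  The chain is (1) drought indices from monthly meteorology,
(2) annual WUE, (3) detrended correlation maps stratified by aridity zone,
(4) a GPP-vs-ET dominance classification, and (5) a previous-year "memory"
regression.  A synthetic generator supplies data whose regime structure is
known exactly, so every stage can be validated end to end.

## Drought indices

**Penman PET.** Open-water Penman (1948) combination form, daily basis
scaled by days-in-month:

    PET = Δ/(Δ+γ)·Rn/λ + γ/(Δ+γ)·2.6·(1 + 0.536·u)·(e_s(T) − e_a)

with Tetens e_s, Δ = 4098·e_s/(T+237.3)², λ = 2.501 − 0.002361·T MJ kg⁻¹,
γ = 0.000665·P_atm(z), and ground heat flux taken as zero at the monthly
scale.  Inputs: T (°C), Rn (MJ m⁻² d⁻¹), e_a (kPa), u (m s⁻¹), elevation
(m).  Supersaturated humidity readings (e_a > e_s) are clipped to zero
deficit with a warning.  No Penman–Monteith/FAO-56 option is provided.

**Wetness index.** WI = annual P / annual PET on calendar years.  UNEP
classes: hyper-arid < 0.05 ≤ arid < 0.2 ≤ semi-arid < 0.5 ≤ dry sub-humid
< 0.65 ≤ humid, with lower-closed intervals (WI exactly 0.65 is humid) and
the three analysis zones {arid, semi-arid/sub-humid, humid} obtained by
merging hyper-arid with arid and semi-arid with dry sub-humid.  A location
is classified on its period-mean annual WI.

**PDSI.** Palmer's monthly procedure with Penman PET substituted for
Thornthwaite.  The two-layer bucket (surface layer 25.4 mm; default AWC
152.4 mm, configurable) wets and dries top-down, with underlying-layer loss
proportional to its relative content.  CAFEC coefficients are per-calendar-
month ratios of calibration means (α = ET̄/PĒ, β = R̄/PR̄, γ = RŌ/PRŌ,
δ = L̄/PL̄; 0/0 → 1 for α, 0 otherwise); the calibration window defaults to
the full record.  Departures d = P − P̂ are converted to inches before
Palmer's climatic characteristic

    K'_j = 1.5·log10((T_j + 2.8)/D̄_j) + 0.5,  K_j = 17.67·K'_j / Σ D̄_i K'_i

because the empirical constants were fitted in inches.  The recursion
X = 0.897·X₋₁ + Z/3 runs on the incipient-wet (X1 ≥ 0), incipient-dry
(X2 ≤ 0) and established-spell (X3) tracks; spells establish at |X| ≥ 1 and
end when the accumulated effective moisture V reaches the requirement
Ze = ∓2.691·X3 ∓ 1.5 (termination probability 100·V/(V+Q)).  Backtracking
follows the operational convention: months whose fate is uncertain are held
in a buffer and retroactively assigned the winning track's values once a
spell establishes, terminates, or both incipient tracks die out (larger
|value| wins at the end of a record).  Annual PDSI is the mean of the 12
monthly values.  Water-balance starts from full stores; the engine warns on
records shorter than 10 years.  Self-calibrating PDSI duration factors and
snow processes are out of scope.

The engine satisfies, to machine precision: water conservation
P − ET − RO = ΔS each month; calibration-mean departure = 0 per calendar
month; Σ D̄·K = 17.67; X1 ≥ 0 ≥ X2 and pdsi ∈ {x1, x2, x3} everywhere.
The constant-Z fixed point Z/(3·(1−0.897)) is reached to 1e-6 after ~150
steps (the contraction factor is 0.897 per month).

## Correlation analysis

Annual WUE is the ratio of annual sums (not the mean of monthly ratios);
incomplete calendar years and zero-ET years are dropped with warnings.
All annual series are detrended by subtracting the OLS line (residuals have
zero mean and slope; the operation is idempotent), and Pearson's r between
detrended WUE and the detrended drought index is tested with the regression
F-test, F = r²(n−2)/(1−r²) on (1, n−2) df — identical to the two-sided
t-test on r.  Default significance: 0.1 at sites (short records), 0.05 on
grids; both configurable, and the non-detrended variant is available via a
flag.  Stratified summaries are boxplot statistics (median, type-7
quartiles, extremes) of r per zone or biome.

## Dominance classification

Relative sensitivity is the OLS slope of flux/mean(flux) on
index/mean(index) (mean-normalisation before detrending, so the slope is
unit-free).  GPP-controlled where slope_GPP > slope_ET, otherwise
ET-controlled — ties deliberately fall to ET, and the comparison uses
signed slopes by default (an `absolute=True` option compares magnitudes,
since the "higher slope" rule is ambiguous when slopes are negative).
Pixels whose WUE–index correlation fails the significance gate are
"undetermined".

## Memory effect

WUE_t = a·D_t + b·D_{t−1} + c by OLS after detrending, first year dropped
to form the lag pair.  Independent effects of the two predictors come from
hierarchical partitioning — the Shapley decomposition of R² over predictor
entry orderings, computed for general k with subset-R² caching and weights
|S|!(k−|S|−1)!/k! — and are reported as percentages of the full-model R²
(they sum to 100 by construction).  Model comparison uses the Gaussian
least-squares AIC, n·ln(RSS/n) + 2(p+1) with the error variance counted as
a parameter; only differences matter, and the lagged model is flagged an
improvement when AIC drops by more than 2.0.  RSS = 0 yields a −inf
sentinel with a warning.

## Synthetic data

Each location draws i.i.d. standard-normal annual wetness anomalies w_t
(one extra pre-record draw feeds the first lag).  Monthly precipitation is
a fixed seasonal shape scaled so annual P/PET equals the regime's target
WI, times exp(0.3·w_t − 0.045) — mean-one lognormal, so realized WI is
unbiased; 30% interannual variability is typical of dryland precipitation.
Temperature, radiation, humidity and wind are climatological cycles plus
small Gaussian perturbations independent of w_t, isolating the
precipitation-driven signal.  Annual fluxes respond multiplicatively:

    GPP_t = GPP0·(1 + trend·Δt)·exp(g·w_t + λ·w_{t−1} + ε_g)
    ET_t  = ET0 ·(1 + trend·Δt)·exp(e·w_t + ε_e)

Positivity is guaranteed; with g = e and no noise the WUE ratio is exactly
constant.  The lag term acts on GPP (a productivity legacy), so the WUE lag
slope equals λ; by default λ = −0.5·(g − e), opposite in sign to the
current-year WUE response.  Default regimes: arid (WI 0.12, g = 0.10,
e = 0.30 — ET-dominated, WUE rises in drought), semi-arid/sub-humid
(WI 0.40, g = 0.30, e = 0.10 — GPP-dominated), humid (WI 1.20, g = 0.03,
e = 0.02 — weak response); noise σ = 0.05 on each flux.  Magnitudes of the
sensitivities are design choices targeting the qualitative sign pattern,
not published effect sizes.  Per-cell sub-seeds come from an explicit
FNV-1a/splitmix64 mixing of the master seed and the cell id, so grids are
bit-reproducible across platforms and cell count.

What the generator does **not** emulate: drought-spell persistence beyond
the one-year lag, spatial autocorrelation between cells, covariance between
wetness and temperature/radiation, and month-scale precipitation
variability independent of the annual anomaly.  Because one annual anomaly
drives all twelve months, Palmer-index excursions are larger than typical
observational values (|PDSI| can exceed 6); correlation- and sign-based
conclusions are unaffected, but synthetic PDSI magnitudes should not be
read as climatology.  Passing recovery tests therefore demonstrates that
the analysis chain detects the structure it assumes, not that real
ecosystems contain it.

## Problem sizes and numerics

Recovery analyses use 200 cells per regime × 30 years (the study-period
length); the zero-lag AIC control uses 100 cells; the F-test calibration
uses 10,000 null replicates at n = 30; the Penman oracle sweep uses 1,000
random forcing points.  Degenerate inputs are handled explicitly: zero
variance flags correlations as undefined rather than raising; zero mean
|d| or zero mean precipitation aborts the Palmer calibration (degenerate
climate); collinear lag predictors abort the memory regression.
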