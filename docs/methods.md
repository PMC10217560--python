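# Methods

## Scope and model

`hmetex` models texturization in the screw section of a high-moisture
extruder as an enthalpy-balance problem. The material enters at feed
temperature T₀ = 20 °C and leaves the screws at the measured material
temperature T_in. Neglecting kinetic and potential energy changes and
reaction heats other than protein melting, the specific enthalpy delivered
to the protein–water mass is

    ΔH_extruder = cp(T̄) · (T_in − T₀) / 1000 + ΔH_m   [J/g]

with cp in J kg⁻¹ K⁻¹. Mechanical energy input (SME) is *not* an extra
term: the measured T_in already contains viscous dissipation, so thermal
and mechanical input together equal cp·(T_in − T₀). Adding the SME
separately would double-count it; the package verifies this numerically —
the two-term balance reproduces all six packaged validation TI values to
two decimals, while the three-term variant (exposed as a diagnostic
`include_sme_term` flag in `compute_extrusion_enthalpy`) does not.

The texturization indicator TI = ΔH_extruder / ΔH_DSC compares this with
the enthalpy a DSC measurement says is needed for a complete protein melt
(sensible heat from 20 °C to the endotherm end plus the endotherm itself).
Classification uses TI rounded to two decimals (<1 poorly-textured,
=1 textured, >1 well-textured); this rounding convention is what makes the
packaged validation triple (0.99 / 1.00 / 1.02-and-up) a consistent rule.
TI between 1.05 and 1.10 is surfaced as an advisory "robust
texturization" band, not a class boundary.

## cp determination

`cp_from_heatflow` reduces a scan triple as
cp(T) = (Φ_sample − Φ_blank)/(m·β), with β converted from K/min to K/s,
then applies a temperature-wise calibration factor
k(T) = cp_water,lit(T)/cp_water,meas(T) from a distilled-water reference
scan, interpolated linearly between reference grid points. The literature
water-cp curve is a packaged table of standard saturated-liquid steam-table
values on 0–150 °C with linear interpolation; the identity of the original
tabulation is immaterial at the ≤0.1% level these corrections operate at.
The MLR model cp = y0 + a·Xw + b·T is an ordinary least-squares fit
(statsmodels); its reported standard error is the residual standard error
(denominator n − 3). Whether the published SEs are residual or coefficient
errors is ambiguous; residual SE is assumed. Out-of-box prediction warns
rather than errors, because the pure-water extrapolation check (Xw = 1)
is itself a legitimate use.

## Endotherm analysis

The thermogram model is heat flow per gram (endothermic positive) on a
strictly increasing temperature grid. Detection fits a straight baseline
through the signal means of two user-supplied peak-free windows (defaults
25–70 °C and 150–168 °C, suitable for plant-protein endotherms at
80–135 °C). T_m is the maximum of the baseline-subtracted signal; T_onset
and T_end are found by scanning outward from T_m to the 1%-of-peak-height
crossing (`onset_fraction = 0.01`; tangent conventions differ between
instrument softwares, and threshold crossing is robust on broad single
peaks). A peak must exceed 3× the pre-window residual SD (plus a tiny
absolute floor for numerically flat signals) to count as a transition.
ΔH_m integrates the baseline-subtracted signal over [T_onset, T_end] by
the trapezoidal rule, divided by β in K/s; partial negative areas are kept
(signed integration). ΔH_DSC integrates the raw signal (no baseline
subtraction) from T₀ = 20 °C to T_end — the magnitudes of the packaged
reference values (ΔH_DSC ≈ ∫cp dT + ΔH_m) are consistent with that
convention. The small 7S shoulder some soy proteins show near 80 °C is not
modelled separately; the single-peak assumption is deliberate.

## EMH solver

Solving TI_target = TI(T_in) under the midpoint-cp convention is a scalar
fixed-point problem T_in = (TI_target·ΔH_DSC − ΔH_m)·1000/cp((T₀+T_in)/2) + T₀.
The iteration starts from the T₀-evaluated closed form, tolerance 1e-6 °C,
at most 100 iterations; the contraction constant (≈ b·ΔH/cp², about 0.03
for realistic parameters) makes it converge in a handful of steps, and a
bisection fallback on [T₀, 250 °C] guards against oscillation. A test
verifies equivalence with a brute-force 1e-4 °C grid search. The T0-only
convention (cp evaluated at the feed temperature, used when T_in is
unknown a priori) returns the closed form directly and slightly
overestimates the hurdle, since cp at 20 °C is below cp at the midpoint.

## Texture metrics

SI = F_l,middle / F_l,outer with the outer force averaged over the two
edge specimens (product symmetry). Class statistics use sample SDs,
scipy's one-way ANOVA and Tukey HSD pairwise comparisons at α = 0.05.
Rows with missing SI are excluded everywhere; SME values logged as zero
mean "no recordable shear" and carry an `SME_unmeasured` flag — they are
excluded from regressions and threshold screens, never imputed as zero.
The SI–temperature regression over all 21 index-bearing screening runs
gives R² ≈ 0.60; the exact value depends on whether the three
centre-point replicates are averaged first, which is why an optional
`average_center_points` mode exists (off by default).

## Synthetic-data generators

All generators are pure functions of (parameters, seed), with defaults
set to the packaged reference campaign conditions:

- **CCD**: 2⁴ factorial + 8 axial + 3 centre runs, axial distance
  α = 1.5, over screw speed 310 ± 90 rpm, moisture 65 ± 5%, mass flow
  9.5 ± 3.5 kg/h, barrel temperature 140 ± 20 °C.
- **Thermograms**: cp-plane baseline (cp/1000 · β) plus an endotherm with
  compact support [T_onset, T_end]. The default peak is a beta-type bump
  u^p(1−u)^q with exponents p = s·m, q = s·(1−m)
  (m the normalised mode position, sharpness s = 1.5), which places the
  mode exactly at T_m and rises steeply enough from its support edges that
  the 1% threshold crossing sits within a few tenths of a degree of the
  true onset; a truncated-Gaussian alternative is available. The amplitude
  is normalised numerically so the grid integral over β equals ΔH_m.
  Default grid 10–170 °C at 0.05 °C, β = 5 K/min.
- **cp scans**: sample/blank/water triples at β = 0.2 K/min, 0.65 g
  sample mass, with an optional multiplicative instrument gain that the
  water-reference correction must remove.
- **Extrusion responses**: a documented linear response surface (torque
  rising with dry matter and speed, falling with throughput; T_in tracking
  barrel temperature plus dissipation minus a moisture penalty; pressure
  falling with moisture, rising with throughput) calibrated so simulated
  ranges overlap a realistic pilot campaign (T_in ≈ 90–140 °C,
  SME 0–35 Wh/kg, 1–30 bar). Negative net torque is clipped to zero and
  flagged unmeasured, mimicking low-viscosity melts. Each simulated run
  receives a ground-truth texture label by running the TI pipeline on its
  own simulated T_in.
- **SSF profiles**: longitudinal forces on a downward parabola through
  the outer-specimen centres (x = 10, 50 mm of a 60 mm strand) at the base
  force and the middle (x = 30 mm) at SI_target × base force; transverse
  forces flat. The specimen-level middle/outer ratio equals SI_target
  exactly at zero noise.

What the generators do *not* emulate: instrument drift and sigmoidal DSC
baselines, overlapping 7S/11S endotherms, heating-rate-dependent
denaturation kinetics, and any real extruder rheology. Passing tests
therefore demonstrate correctness of the analysis chain and internal
consistency of the enthalpy balance, not predictive validity for new
proteins — that validity rests on the packaged validation campaign, where
the pipeline reproduces all six reference TI values and sensory classes.

## Numerical and design choices

- Unit conversions defined once: Wh/kg → J/g is 3.6; β K/min → K/s inside
  the integrators; cp J/kg/K → J/g/K at the STE step.
- Integration bounds are inserted into the trapezoid by linear
  interpolation, so enthalpies are exactly additive over adjacent
  intervals and rectangle peaks integrate in closed form.
- The packaged 27-run design fixture stores the internally consistent high
  axial mass-flow level 14.75 kg/h (its mirror point 4.25 = 9.5 − 1.5·3.5
  fixes α = 1.5); the responses fixture keeps the campaign log's 14.25 for
  that run. The provenance note lives in the fixture header.
- Machine constants n_max = 500 min⁻¹ and P_max = 8600 W, feed
  temperature 20 °C, TI_target = 1 and two-decimal classification are
  `PipelineConfig` defaults; the config round-trips through a plain-text
  key=value format that rejects unknown keys.
- Problem sizes in the test suite (e.g. 0.05–0.1 °C thermogram grids,
  50-replicate noise studies, 1e-4 °C oracle grids) keep the full suite
  under a couple of minutes on one CPU while leaving quadrature error an
  order of magnitude below every asserted tolerance.

## Known limitations

- The wet-basis/dry-basis labelling of moisture contents is inconsistent
  in the source campaign tables; the package follows the identification
  Xw = moisture% / 100 when evaluating cp models, which is the convention
  that reproduces the packaged validation results.
- EMH values recomputed from the rounded packaged regression coefficients
  differ from the reference hurdle temperatures by up to ≈0.8 °C; the
  acceptance tolerance of ±1 °C reflects that input rounding, not solver
  error (the solver agrees with its brute-force oracle to 1e-3 °C).
- Texture classes for TI very near 1 are sensitive to the two-decimal
  rounding convention by construction.
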