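# Methods

All fluxes are in PgC yr⁻¹ under the atmospheric sign convention (negative =
uptake by land; stock-change terms negative when storage increases), carbon
stocks in PgC, CO₂ in ppm (2.124 PgC ppm⁻¹), temperature anomalies in K.
Reported values are rounded half-away-from-zero at the quoted precision;
internal computation is at full double precision.

## Regional budget model (`budget_core`)

Each region's net ecosystem exchange is diagnosed from inventories and
lateral fluxes as

    NEE = ΔC − F_rivers − F_trade,
    ΔC  = δ₁ + δ₂ + δ₃ + δ₄.

Carbon fixed from the atmosphere but exported (riverine carbon, traded crop
and wood products) never appears in regional stock inventories, so exports
deepen the apparent sink relative to ΔC and net imports (oxidized in-region
by people and livestock) shallow it. Two lithogenic corrections keep
rock-derived carbon out of the atmospheric budget: the stock term δ₅
(carbonate lost to weathering) is never added to ΔC, and only half of the
carbonate-derived riverine DIC is counted in F_rivers (carbonate weathering
draws ½ mol of atmospheric CO₂ per mol DIC; silicate weathering draws 1 mol,
so silicate DIC counts fully).

Error terms are treated as independent Gaussians and combined in quadrature
everywhere in the budget; correlations matter only for the SHR/NPP ratio and
are handled there by construction (paired draws), not by covariance algebra.
A property test checks every quadrature composition against a brute-force
Gaussian Monte-Carlo of the same sum.

The global total adds a scalar sink of −0.4 PgC yr⁻¹ for land outside the
nine regions (Middle East, Ukraine, Belarus, Kazakhstan, New Zealand); the
anthropogenic value subtracts a scalar background natural sink of −0.6
PgC yr⁻¹ (carbon fixed, leached to rivers and delivered to the ocean even in
an unperturbed world). Both scalars are configurable and carry no
uncertainty of their own, so the anthropogenic σ equals the total σ.

An optional flag inflates the tropical biomass/litter/soil stock term by the
estimated 26% bias from soil-carbon changes being unmeasured in tropical
inventories. It is off by default: the number is a bias bound, not an
applied correction.

## Synthetic budget table (`synthetic_data`)

The generator emulates the compiled per-region flux table the analysis
consumes. Entries fall into two classes, marked in the source:

* **Literature-printed**: the eight regional NEE values and σ (South Asia
  −0.25 ± 0.11 … Russia −0.73 ± 0.22), the global source components (fires
  1.6 split 0.2 residue + two-product {1.3, 1.5}; crop 1.5; grazing 1.0;
  reduced carbon 0.8; wood 0.7; land-use change two-product {1.0, 1.2}),
  the global NPP median −50 with IQR −57..−44, the 20% internal NPP error,
  the δ₄ burial terms for North America / Europe / Russia, and the global
  adjustments −0.4 / −0.6.
* **Fixture-closed**: everything the printed record does not pin down —
  Australia's NEE (−0.08 ± 0.30, chosen so the nine regions plus the
  non-RECCAP sink close the −2.8 ± 0.7 global budget), the regional NPP
  magnitudes (summing to 50), the regional source totals (summing to 8.25),
  and the decomposition of each NEE into stock/river/trade components. The
  regional NPP and source totals were solved jointly so the central
  regional SHR/NPP ratios reproduce the published pattern: South Asia 0.38,
  East Asia 0.56, all others within 0.64–0.86. Source components are
  allocated to regions proportionally to each region's source total; the
  inland-water outgassing pair {0.65, 2.15} plus a 0.15 estuarine term spans
  the published 0.8–2.3 range.

Within each region the components recombine to the target NEE exactly
(closure by construction), and component σ are normalized shares of the
target NEE σ so the quadrature closes exactly too.

**NPP product calibration.** Product k of region r takes the value
−m_r·g_k, with one set of positive factors g_k shared by all regions and a
Gaussian internal error of 20% of each value. Under the default coherent
sampling scheme the global draw is an equal-weight mixture of Gaussians, so
its quantiles are available analytically (mixture CDF + root finding) and
the g_k can be fitted without sampling. Because the internal error is
proportional to magnitude, a symmetric product ladder yields a skewed
mixture; the ladder therefore carries scale, shift and skew degrees of
freedom, solved so the 25th/50th/75th percentiles hit the configured
−57 / −50 / −44 exactly (two products: scale+shift against the IQR
endpoints; one product: no calibration). A configured IQR narrower than the
internal-error floor is reported as infeasible rather than approximated.
One consequence of matching the asymmetric printed IQR: the product *mean*
sits ~1.4% above the *median* (−50.7 vs −50.0 globally).

The generator is deterministic — identical configs give bit-identical
tables; the seed it stores drives the downstream Monte-Carlo. `sigma_scale`
scales every σ (0 = degenerate table) and `collapse_products` replaces each
multi-product flux by its mean, which together make the downstream
Monte-Carlo collapse to a point mass — useful as a test limit.

**What the generator does not emulate:** spatial (gridded) structure,
interannual variability, non-Gaussian flux errors, correlated inventory
errors between neighboring regions, and any raw-data processing chain
(satellite retrievals, fire products, trade statistics enter only as table
entries). Passing tests therefore validate the accounting and uncertainty
machinery under the published summary statistics, not the upstream data
products themselves. Negative draws of strictly positive fluxes (e.g.
outgassing) are allowed, consistent with plain Gaussian propagation.

## Residual SHR Monte-Carlo (`shr_inference`)

Per draw: one product index per multi-product flux (NPP ×4, other fires ×2,
land-use change ×2, inland-water outgassing ×2) drawn uniformly; Gaussian
internal error added to every component; NEE rebuilt from its budget
components; SHR taken as the exact residual

    SHR = NEE − NPP − Σ(non-SHR sources);

and the ratio computed as SHR/(−NPP) with the same NPP realization in
numerator and denominator (zero-NPP draws are excluded and counted). The
residual identity holds per draw to machine precision, and global draws
equal the sum of regional draws (plus the scalar non-RECCAP sink for NEE and
SHR).

Product choice is **coherent** across regions by default — one index per
flux per draw — because the published global NPP interquartile range
reflects between-product spread, which independent per-region choice would
average away (both modes are implemented; the independent mode demonstrably
narrows the global quantiles). The draw count defaults to 10⁵ (quantile
standard errors ≲0.05 PgC yr⁻¹ on SHR, ≲0.001 on the ratio, a second of
runtime); quantiles use linear interpolation between order statistics, and
tie-breaking is irrelevant at that count.

With the default table this yields: global SHR median ≈39 PgC yr⁻¹, IQR
≈33–46; sampled global NPP median ≈−50, IQR ≈−57..−44; ratio median ≈0.78,
IQR ≈0.75–0.81 — with the ratio relatively far tighter than NPP because of
the per-draw pairing. These are computed by the test suite and
`scripts/acceptance.py`, never asserted as constants in library code.

## Product-pool bookkeeping (`bookkeeping`)

Harvested products enter named pool classes and decay as single
exponentials; defaults are three classes (short/medium/long-lived) with
e-folding times {2, 25, 35} years and inflow split {0.4, 0.3, 0.3}. The
published record does not state whether the original decay functions are
first-order or fixed-lifetime cohorts; first-order is standard bookkeeping
practice and any parameterization can be dropped in via the config. Inflow
is spread uniformly through the year; the released flux is computed as the
mass-balance residual, so conservation holds at machine precision over
arbitrary inflow series, and the steady-state flux converges to the inflow
(tested to 1e-6 after 20 e-folds). Pool growth reported to the budget is
negative (storage increase), matching δ₁/δ₂. Consumption and emission
fluxes (crop consumption = harvest − net export − storage increase; wood
emission = decay + fuelwood·burn factor) carry a default 20% relative σ.
Landfill CH₄ from products is counted inside these fluxes in carbon units,
never in the reduced-carbon term; sewage losses of consumed products are
ignored as globally small.

## Carbon-climate box model (`feedback_boxmodel`)

A structural analogue of the SIM-1/SIM-2 emulator experiment — one
atmosphere, one soil box, an inert ocean/export sink — not a re-calibration
of any Earth System Model:

* NPP = NPP₀·(1 + β_fert·ln(CO₂/CO₂₀)); default NPP₀ = 50 PgC yr⁻¹,
  β_fert = 0.6.
* SHR = (C_soil/τ)·Q10^(ΔT/10); default τ = 30 yr, Q10 = 2.
* ΔT = S·ln(CO₂/CO₂₀)/ln 2, instantaneous; default S = 3 K per doubling.
* SIM-2 removes a fraction f of NPP before litterfall. A river share
  (default 0.075 of the lateral flux, scaled by 1 + 0.06·ΔT +
  0.3·ΔNPP/NPP₀) is routed to inland waters, of which half outgasses back
  to the atmosphere and half is exported to the ocean; the non-river
  remainder is oxidized to the atmosphere within the year. The
  *preindustrial* river export is returned by a constant compensation flux
  (the natural riverine loop is closed through the ocean), so an unforced
  run is exactly flat and only export anomalies act as a net sink.
* Ocean uptake is a fixed fraction (default 0.45) of annual emissions; the
  default emissions path grows ~2.5%/yr to 8 PgC yr⁻¹ in 2000 and ramps
  linearly to 28 PgC yr⁻¹ by 2100 (a high-emissions shape).
* Integration: annual explicit Euler, 1850–2100, soil initialized at
  equilibrium (1−f)·NPP₀·τ; carbon conservation across all boxes is checked
  every step (<1e-9 PgC drift).

Diagnostics follow the standard feedback decomposition: β_soil = ΔC_soil /
ΔCO₂(ppm) from a biogeochemically-coupled run (temperature pinned at zero),
γ_soil = ΔC_soil/ΔT from a radiatively-coupled run (NPP pinned at NPP₀).
`calibrate_lateral_fraction` finds f by root bracketing so the fully coupled
present-day (2000–2009) SHR/NPP ratio matches a target to 1e-3; the
budget-derived target 0.78 gives f ≈ 0.20.

With that calibration the documented sweep (f ∈ {0.10, 0.22, 0.35} ×
β_fert ∈ {0.5, 0.8} × Q10 ∈ {1.5, 2.0}) reproduces the experiment's
qualitative result everywhere: β_soil is ~20% lower in SIM-2, γ_soil ~20%
less negative, and end-of-century CO₂ and temperature are higher in SIM-2
(a few to ~25 ppm and up to ~0.2 K at default settings), with river
outgassing rising strongly by 2100. These are sign/ordering claims only;
the published quantitative ranges depend on seven CMIP5-calibrated
emulations that a one-box analogue cannot and does not reproduce.
**Domain of validity:** the net CO₂ ordering expresses β-dominance — with
weak fertilization and strong temperature sensitivity (e.g. β_fert ≤ 0.5
with Q10 = 2.5) the γ reduction wins and the CO₂ difference flips sign.
The sweep deliberately spans the fertilization-dominated regime the
emulated models occupy; the flip outside it is a known property of the
compensating feedbacks, not a numerical artifact.

## Numerical choices

* Quantile calibration roots are found with `scipy.optimize.brentq`
  (xtol 1e-10) inside a `scipy.optimize.root` solve (hybr, residuals
  ≤1e-6 enforced); degenerate σ uses a 1e-12 floor in the mixture CDF.
* Lateral-fraction calibration: `brentq` on [0, 0.98], xtol 1e-6, achieved
  ratio verified to 1e-3.
* Budget-table CSVs store floats as shortest round-trip decimal strings and
  are parsed with `float_precision="round_trip"`, so write→read→write is
  byte-identical.
* Pipeline JSON summaries round to 6 decimals with sorted keys: identical
  config+seed gives identical bytes.
* Rounding for reported values is decimal half-away-from-zero
  (`round_printed`), matching printed-table conventions (8.25 → 8.3).

## Known limitations

* The per-region decomposition (NPP magnitudes, source composition, stock/
  river/trade splits) is fixture-closed, not observed; regional conclusions
  beyond the calibrated ratio pattern should not be read off the synthetic
  table. Russia's non-SHR source total in particular comes out small (0.17
  PgC yr⁻¹) as the closure residual of the published constraints.
* Gaussian, independent errors throughout the budget; no spatial fields; no
  interannual variability.
* The box model has no vegetation pool (NPP becomes litterfall within the
  year), no ocean carbonate chemistry, no permafrost, no land-use module,
  and a single global soil box; only paired SIM-1/SIM-2 differences are
  meaningful, not absolute projections.
* The anthropogenic NEE σ equals the total σ because the background-sink
  uncertainty is not published.
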