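# Methods

This note records the models, conventions and numerical choices behind
`anacat`, and what the synthetic-data tests do and do not demonstrate.

## Degree of reduction and yield theory

All compositions are stored per carbon mole; molecular formulas are divided
by their carbon number (including the charge).  The degree of reduction of
`CHaObNcPpSs` with net charge z is

```
γ = 4 + a − 2b − 3c + 5p + 6s − z
```

with CO2, H2O, NH3, phosphate and sulfate as the zero-electron reference
states.  The P (+5), S (+6) and charge conventions are exactly those that
make γ/4 equal the O2 demand of combustion to CO2/H2O/NH3/H3PO4/H2SO4 — an
identity the test suite checks against an independent element-balance
solver.  Comparisons γS ≤ γX use an absolute tolerance of 1e−9.

The maximal carbon yield is `Y_max = γS/γX` for γS ≤ γX (else 1).  The ideal
anabolic equation `b1 [S] + b2 NH3 → [X] + b3 CO2 + b4 H2O` is fixed by
`b3 = (γX − γS)/γS`, `b1 = 1 + b3 = 1/Y_max`, `b2 = c`,
`b4 = (b1·x + 3 b2 − a)/2`.  For CHON biomass all four element balances
close exactly (the O balance is implied by the redox balance); for biomass
containing P, S or charge these enter only through γ — the implicit
phosphate/sulfate assimilation is not written out, so the O balance of the
displayed equation is then approximate while `b1 = 1/Y_max` remains exact.

## Formation energies and the vendored table

Reaction energies are Hess sums `Σ νi ΔfG'°i` over transformed standard
formation energies at 298.15 K, pH 7.4, pMg 3.0, I = 0.25 M.  The vendored
table (`src/anacat/data/formation_energies.tsv`, regenerated by
`scripts/make_formation_table.py`) is built from Alberty's chemical-standard
aqueous species energies by the Legendre transform

```
ΔfG'° = ΔfG° + N_H·RT·ln(10)·pH − 2.91482·(z² − N_H)·√I/(1 + 1.6·√I)
```

with protonation states merged as pseudoisomers
(`−RT ln Σ exp(−g_i/RT)`).  Water and the proton keep unit activity.  Mg
binding is not modelled: pMg is recorded in the conditions sidecar but no
Mg-bound species are included, which mainly affects the absolute ATP/ADP
entries (tagged `no-Mg-species`); every pipeline quantity that matters here
is Mg-insensitive because ATP work is priced by the fixed
`ΔrG_ATPase = 46.5 kJ/mol` constant instead.

Against this table complete aerobic glucose combustion releases 2921.6
kJ/mol (−486.9 kJ C-mol⁻¹), well within the ±49.5 kJ/mol uncertainty band
quoted for group-contribution estimates of this reaction.  Individual
compound energies from different compilations differ by several kJ/mol, so
derived per-C-mol quantities (e.g. the anabolic reaction energy of yeast
biomass, ≈ −48 kJ C-mol⁻¹ here against published estimates near −42) carry
an uncertainty of roughly ±10 kJ C-mol⁻¹; tests assert neighbourhoods of
that width, never exact table values.

The concentration correction `RT Σ νi ln ci` is available but off by
default: overall catabolic conversions have standard energies of 30–500
kJ C-mol⁻¹, while each decade of concentration contributes only
RT·ln 10 = 5.7 kJ/mol, so standard energies characterize routes adequately.

## Biomass formation energy

`battley_formation_energy` estimates the standard Gibbs energy of formation
of dry biomass from its elemental composition, in the spirit of Battley's
empirical composition-based approach, as a linear correlation

```
ΔfG°X [kJ C-mol⁻¹] = −956.2553 + 201.1145·γX + 44.4960·n_N
```

whose three coefficients are calibrated to published estimates for three
experimentally characterized biomass compositions (yeast CH1.79O0.57N0.15 →
−104.9; *E. coli* CH1.811O0.503N0.258P0.022S0.006 with charge −0.018 →
−101.10; yeast CH1.8243O0.6589N0.1557P0.0055S0.0022 → −128.76).  Direct
reconstructions from combustion energetics (a per-electron combustion Gibbs
energy, with either chemical-standard or transformed product energies, or
an entropy-rule/enthalpy split) could not reproduce all three published
values within 1 kJ C-mol⁻¹ with any single physical constant, so the
calibrated correlation is used and is exact at the three anchors.  It is an
interpolation over ordinary heterotrophic biomass (H 1.4–2.2, O 0.3–0.9,
N ≤ 0.35 per C-mol); outside that box a warning flags the estimate as an
extrapolation.  When combined with transformed compound energies the value
is Legendre-transformed with the biomass hydrogen content and charge, so
both conventions stay consistent within one reaction.

## Conversion-mode enumeration

The conversion cone `{c = N_ext v : N v = 0, v_irr ≥ 0}` is enumerated by
(1) splitting reversible reactions so the flux cone lies in the nonnegative
orthant, (2) running the double-description method with exact
`fractions.Fraction` arithmetic (adjacency by the combinatorial zero-set
test), (3) projecting rays onto exchange fluxes, deduplicating up to
positive scaling, and (4) removing conversions that are nonnegative
combinations of the others via LP membership tests (HiGHS).  Exact
arithmetic removes any possibility of spurious or missing rays from
round-off; the LP filter operates on small rational data where the 1e−9
feasibility tolerance is far below the coefficient scale.  The minimal
generating set is unique only for pointed cones; if a conversion and its
reverse are both feasible the enumerator raises and asks for one exchange
direction to be closed.  The intended scale is toy to core-size networks
(an intermediate-ray cap, default 200 000, guards against combinatorial
blow-up); genome-scale models should be reduced first with the hide/dismiss
rules (`hide_externals`: N/P/S-containing externals hidden, compounds with
more than six carbons closed) or imported as precomputed conversion tables.

Each conversion is normalized so its designated carbon source contributes
−1 C-mol; conversions consuming several carbon sources are normalized by
the alphabetically first (logged), and carbon-source-free conversions are
reported unnormalized.

## Linear programs

All three analyses share one LP builder over the full stoichiometric matrix
(equality steady state, per-reaction bounds, ±1e6 standing in for
unbounded).  ATP-yield: all exchanges pinned to the conversion (absent
compounds closed), any maintenance bound on ATP hydrolysis lifted, maximize
hydrolysis flux.  Substrate minimization: biomass reaction (scaled to 1
C-mol per unit flux) fixed to 1, only substrate and optionally O2
importable, other exchanges secrete-only, ATP hydrolysis free to run
backwards; the ATP minimization then re-imposes the substrate optimum and
maximizes the (negative) hydrolysis flux.  Only objective values are
contractual — flux certificates are marked non-unique because these LPs are
almost always degenerate.

## Chemostat splitting and the energy-converter picture

Unit handling: gram-based specific rates are converted with the compound
molar mass and the biomass C-mol mass (26.11 g C-mol⁻¹ for *E. coli*-style
data); per-mol-substrate coefficients are divided by the substrate carbon
number, carbon-containing products re-expressed per their own carbon.
Water is always closed from the hydrogen balance; O2 is taken from the
measurement when present, otherwise closed from the oxygen balance.  The
carbon recovery CR = α2 + α3 + α4 must lie in [0, 1.1] (hard error
otherwise); CR < 0.9 attaches a data-quality warning to the point but never
halts the pipeline.

Subtracting α2 times the anabolic equation gives the catabolic
coefficients `c1 = 1 − b1α2, c2 = α1, c3 = α4 − b3α2, c4 = α3,
c5 = α5 − b4α2`, renormalized to c1 = 1.  A record whose yield sits at the
theoretical maximum (c1 ≤ 1e−9) has no catabolic half-reaction: splitting
it raises, while the series-level converter analysis records a
zero-catabolism point (Jcat = Pcat = 0) with a warning.

Converter points use `Jcat = D·(1/α2 − b1)` (C-mol catabolized substrate
per C-mol biomass per hour — the paper-style "kJ C-mol⁻¹" power axis is per
hour on this basis), `Jana = D`, standard energies as forces, and
`ΔanaG°` computed once per series since the anabolic stoichiometry does not
depend on D.  The ATP yield of each realized catabolic stoichiometry is the
same pinned-exchange LP run against a supplied network; without a network
the ATP columns are omitted with a warning.  `fit_linear_converter` solves
the 2×2 least-squares problem `J ≈ L X` and reports per-point residuals
plus the Spearman rank correlation of Jcat against −ΔcatG°, whose sign is
the model diagnostic: truly linear data give machine-precision residuals,
overflow series give a significantly negative correlation.

## Synthetic data: what it emulates, and what it does not

The chemostat generator composes each condition exactly as
`α2·(anabolic equation) + (1 − α2 b1)·[(1 − φ)·respiration +
φ·fermentation]`.  Defaults emulate a yeast-like culture: glucose,
CH1.79O0.57N0.15 biomass, D grid 0.05–0.45 h⁻¹, overflow switch at
D_crit = 0.3 h⁻¹ (0.4 h⁻¹ and acetate for the *E. coli* preset, matching
the growth rates at which overflow metabolism is observed for the two
organisms), yield 0.55 C-mol C-mol⁻¹ below D_crit declining linearly above
(slope 2.5 per h⁻¹), fermentation fraction rising at 4 per h⁻¹ above the
switch, ATP yields 26/6 and 2/6 mol C-mol⁻¹ for the two modes.  Measurement
noise is multiplicative Gaussian on every measured rate (sd 0 by default;
the noise studies use 2 %, a typical relative error of chemostat exchange
measurements), and an unmeasured-carbon fraction diverts CO2 carbon to
mimic incomplete product spectra.  One RNG seeded per specification makes
every series reproducible.

Zero-noise series are exactly balanced, so the round-trip
simulate → assemble → split → decompose recovers φ and the catabolic
stoichiometry to 1e−9 — this validates the algebra, not the biology.  Real
chemostat data additionally contain correlated errors, slow drifts,
maintenance metabolism and composition shifts with D, none of which the
generator produces; passing tests therefore demonstrate correctness of the
decomposition machinery, not that the ideal anabolic equation is an
accurate model of any particular organism.

## Numerical choices and degenerate inputs

* Gas constant 8.314462618e−3 kJ mol⁻¹ K⁻¹; energies in kJ throughout.
* Exact rational arithmetic in enumeration and model files (Fractions
  preserved by the JSON-TSV dialect); floats elsewhere.
* LP backend: scipy's HiGHS; objective values reproducible across backends
  to 1e−6 relative on the bundled fixtures.
* Exchange sign convention: uptake negative, secretion positive,
  everywhere.
* Efficiencies above 1 warn (second-law violation signals inconsistent
  inputs); positive standard catabolic energies flag a conversion as
  infeasible forward rather than erroring.

## Known limitations

* Enumeration assumes a pointed conversion cone and desk-scale networks;
  no parallel or genome-scale enumeration.
* Single nitrogen source (NH3); P/S assimilation only via the degree of
  reduction; no nitrate or N2 fixation stoichiometry.
* No uncertainty propagation of formation-energy errors, no temperature
  dependence beyond the RT factor, no Mg-bound pseudoisomers.
* The biomass formation-energy correlation is an interpolation over
  ordinary heterotrophic compositions, not a general group-contribution
  method.
* No growth kinetics: D is an input, never predicted.
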