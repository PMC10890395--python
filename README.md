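# anacat

Splitting microbial growth stoichiometry into its anabolic and catabolic
half-reactions — and asking whether growth behaves like a linear energy
converter.

A growing microbial culture can be summarized by one *macrochemical
equation*, e.g. for yeast on glucose

```
[S] + α1 O2 + c·α2 NH3  →  α2 [X] + α3 C2H5OH + α4 CO2 + α5 H2O
```

with `[S]` one carbon mole (C-mol) of substrate and `[X]` one C-mol of
biomass `CHaObNc`.  This package implements the theory and the machinery to
take that equation apart:

* **Yield theory from elemental composition.**  The degree of reduction
  γ = 4 + a − 2b − 3c (+5 P, +6 S, − charge) counts available electrons per
  C-mol; when biomass is more reduced than substrate the carbon yield is
  bounded by `Y_max = γS/γX`, and an *ideal anabolic equation*
  `b1 [S] + b2 NH3 → [X] + b3 CO2 + b4 H2O` follows from the element and
  redox balances alone (`b1 = 1/Y_max`).
* **Catabolic route enumeration.**  All *elementary conversion modes* (ECMs)
  — the extreme generators of the cone of feasible net conversions of
  external compounds at zero-biomass steady state — are enumerated exactly
  by double description in rational arithmetic, then annotated with their
  standard Gibbs energy of reaction (Hess's law over a vendored table of
  transformed formation energies at 298.15 K, pH 7.4, pMg 3.0, I = 0.25 M),
  their maximal ATP yield (an LP pinning the exchanges and maximizing ATP
  hydrolysis), and the thermodynamic efficiency
  `η = c_ATP·ΔrG_ATPase / |ΔcatG|`.
* **Anabolic LPs.**  Minimal substrate for one C-mol biomass with ATP free
  (giving the model yield `Y_sim ≤ Y_max`), then the minimal ATP requirement
  at that optimum.
* **Chemostat splitting.**  Measured chemostat series (dilution rate D plus
  exchange rates in gram, mol or C-mol units) are converted to C-mol
  macrochemical equations, the ideal anabolic equation is subtracted
  (`c1 = 1 − b1·α2`, …), and each condition becomes a point of the linear
  energy-converter model `J = L·X`: fluxes `Jcat, Jana = D` against forces
  `−ΔcatG, −ΔanaG`, with powers `Pcat = −Jcat·ΔcatG`, `Pana = −D·ΔanaG`,
  `PATP = c_ATP·Jcat·ΔrG_ATPase`.
* **Synthetic data with known truth.**  Toy networks with analytically known
  conversion modes and ATP yields, and chemostat series with a configurable
  respiration→fermentation overflow switch, measurement noise and
  unmeasured-carbon fraction — the ground truth every test is checked
  against.

## Worked example

Ideal anabolism of yeast biomass (CH1.79O0.57N0.15) on glucose:

```
$ anacat anabolic-ideal --biomass-formula CH1.79O0.57N0.15
gamma_S = 4.0000  gamma_X = 4.2000
Y_max = 0.9524
1.0500 [S] + 0.1500 NH3 -> [X] + 0.0500 CO2 + 0.3800 H2O
```

At most 95.24 % of substrate carbon can become biomass carbon; the other
0.05 C-mol must be oxidized to CO2 to pay for the extra reduction of
biomass.

Enumerate and characterize the catabolic routes of the bundled
fermentation–respiration toy network (glucose, four fates of pyruvate):

```
$ anacat make-toy --kind fermentation-respiration --out toy
$ anacat catabolome --model toy --out ecms.tsv
4 ECMs (2 using O2, 2 with |dG| > 50 kJ/C-mol) -> ecms.tsv
```

The table lists, per C-mol glucose: full respiration (ΔcatG° = −486.9
kJ C-mol⁻¹, 4.33 mol ATP C-mol⁻¹, η = 41 %), ethanol fermentation (−36.6,
0.33, 42 %), lactate fermentation (−34.2, 0.33, 45 %) and aerobic acetate
overflow (−198.3, 2.0, 47 %) — fermentations release an order of magnitude
less free energy than respiration yet conserve a *larger fraction* of it as
ATP.

Simulate a yeast-like chemostat with an overflow switch at D = 0.3 h⁻¹ and
split every condition into anabolism and catabolism:

```
$ anacat simulate --organism yeast --out chem.tsv --seed 1
$ anacat chemostat-split --data chem.tsv --out conv.tsv
17 converter points -> conv.tsv
spearman(Jcat, -dGcat) = -0.818 (p = 6.08e-05)
```

The *negative* rank correlation between the catabolic flux and the catabolic
driving force is the falsification of the linear converter model over
pathway-switching conditions: past the overflow switch cells catabolize
faster while the energy gradient per C-mol shrinks.  The per-point table
(`conv.tsv`) carries the catabolic coefficients c1…c5, both forces, the
force ratio x = ΔcatG°/ΔanaG°, the three powers and the carbon recovery.

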