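"""From chemostat measurements to catabolic/anabolic half-reactions.

At steady state a chemostat culture realizes one macrochemical equation per
dilution rate D (= specific growth rate),

.. math:: [S] + \\alpha_1 O_2 + c\\,\\alpha_2 NH_3 \\rightarrow
          \\alpha_2 [X] + \\alpha_3 P + \\alpha_4 CO_2 + \\alpha_5 H_2O,

with [S], [X] and the overflow product P in carbon moles.  Subtracting
:math:`\\alpha_2` times the ideal anabolic equation isolates the catabolic
conversion, which is then normalized to 1 C-mol substrate, annotated with its
standard Gibbs energy, and interpreted in the linear-energy-converter picture
(fluxes Jcat, Jana = D against forces -dGcat, -dGana, powers = flux x force).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .composition import AnabolicStoichiometry, ElementalComposition, parse_formula
from .thermo import (
    DELTA_G_ATPASE_DEFAULT,
    ConversionStoichiometry,
    FormationEnergyTable,
    battley_formation_energy,
    standard_reaction_energy,
)

__all__ = [
    "ChemostatRecord", "MacrochemicalEquation", "CatabolicStoichiometry",
    "ConverterPoint", "LinearConverterFit", "to_cmol_units",
    "assemble_macrochemical", "split_catabolic", "anabolic_reaction_energy",
    "converter_analysis", "fit_linear_converter", "decompose_catabolic",
    "read_chemostat_tsv", "write_chemostat_tsv", "write_converter_table",
    "DEFAULT_COMPOUNDS", "molar_mass", "ECOLI_CMOL_MASS",
]

logger = logging.getLogger(__name__)

#: Mass of one C-mol of E. coli biomass (g), the default for gram-based data.
ECOLI_CMOL_MASS = 26.11

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974, "S": 32.06}

#: Molecular (not per-C-mol) compositions of the compounds chemostat tables
#: typically report, under the same ids as the vendored formation table.
DEFAULT_COMPOUNDS: dict[str, ElementalComposition] = {
    cid: parse_formula(f, label=cid)
    for cid, f in {
        "glc": "C6H12O6", "xyl": "C5H10O5", "pyr": "C3H4O3", "akg": "C5H6O5",
        "etoh": "C2H6O", "ac": "C2H4O2", "lac": "C3H6O3", "for": "CH2O2",
        "o2": "O2", "co2": "CO2", "h2o": "H2O", "nh3": "NH3",
    }.items()
}

_RATE_KEYS = ("substrate", "o2", "co2", "product", "biomass")

#: recognized unit tags
UNITS = ("specific_cmol", "per_cmol_substrate", "g_per_g_h", "g_per_l_h",
         "mol_per_mol_substrate")

CR_WARN_THRESHOLD = 0.9


def molar_mass(comp: ElementalComposition) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in comp.counts.items())


@dataclass
class ChemostatRecord:
    """One dilution-rate condition of a chemostat series.

    ``values[k]``/``units[k]`` for k in substrate/o2/co2/product/biomass hold
    the measured exchange quantities.  Units: ``specific_cmol`` (C-mol — mol
    for carbon-free species — per C-mol biomass per h), ``per_cmol_substrate``
    (stoichiometric coefficient), ``g_per_g_h``, ``g_per_l_h`` (biomass
    only), ``mol_per_mol_substrate``.  ``values["o2"] = None`` marks oxygen
    as unmeasured (closed from the O balance instead).
    """

    D: float
    values: dict[str, float | None]
    units: dict[str, str]
    substrate: str = "glc"
    product: str = "etoh"
    biomass_composition: ElementalComposition = field(
        default_factory=lambda: parse_formula("CH1.79O0.57N0.15", label="biomass")
    )
    biomass_cmol_mass: float | None = None
    compounds: Mapping[str, ElementalComposition] = field(default_factory=lambda: DEFAULT_COMPOUNDS)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError("dilution rate must be positive")
        for key in self.values:
            if key not in _RATE_KEYS:
                raise ValueError(f"unknown rate key {key!r}")
            if self.values[key] is not None and key not in self.units:
                raise ValueError(f"no unit declared for rate {key!r}")
            if key in self.units and self.units[key] not in UNITS:
                raise ValueError(f"unknown unit tag {self.units[key]!r} for {key!r}")


def _compound_for(record: ChemostatRecord, key: str) -> ElementalComposition:
    cid = {"substrate": record.substrate, "product": record.product}.get(key, key)
    if cid not in record.compounds:
        raise KeyError(f"no molecular composition registered for {cid!r}")
    return record.compounds[cid]


def to_cmol_units(record: ChemostatRecord) -> ChemostatRecord:
    """Convert every measured quantity to carbon-mole units.

    Gram-based specific rates become C-mol (mol for O2) per C-mol biomass per
    hour via the compound molar mass and the biomass C-mol mass; per-mol
    stoichiometric coefficients are rescaled per C-mol substrate (divide by
    the substrate carbon number, products re-expressed per their own carbon).
    Idempotent on already-converted records.
    """
    values = dict(record.values)
    units = dict(record.units)
    sub_carbons = _compound_for(record, "substrate")["C"]
    for key, val in record.values.items():
        if val is None:
            continue
        unit = record.units[key]
        if unit in ("specific_cmol", "per_cmol_substrate"):
            continue
        if key == "biomass":
            if record.biomass_cmol_mass is None:
                raise ValueError("gram-based biomass rate needs biomass_cmol_mass")
            if unit == "g_per_l_h":
                values[key] = val / record.biomass_cmol_mass  # C-mol L^-1 h^-1
                units[key] = "specific_cmol"
                continue
            if unit == "g_per_g_h":
                raise ValueError("biomass rate per gram biomass is not meaningful")
        comp = _compound_for(record, key)
        if unit == "g_per_g_h":
            if record.biomass_cmol_mass is None:
                raise ValueError("gram-based rates need biomass_cmol_mass")
            mol_rate = val * record.biomass_cmol_mass / molar_mass(comp)
            values[key] = mol_rate * max(comp["C"], 1.0)
            units[key] = "specific_cmol"
        elif unit == "mol_per_mol_substrate":
            values[key] = val * max(comp["C"], 1.0) / sub_carbons
            units[key] = "per_cmol_substrate"
        else:  # pragma: no cover - guarded in __post_init__
            raise ValueError(f"unknown unit {unit!r}")
    return replace(record, values=values, units=units)


@dataclass
class MacrochemicalEquation:
    """Per-C-mol-substrate overall growth stoichiometry.

    ``alpha1`` (O2, mol), ``alpha2`` (biomass, C-mol), ``alpha3`` (overflow
    product, C-mol), ``alpha4`` (CO2, mol), ``alpha5`` (H2O, mol) per C-mol
    substrate; NH3 enters as ``n_X * alpha2``.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    alpha5: float
    substrate: str
    product: str
    substrate_composition: ElementalComposition  # per C-mol
    biomass_composition: ElementalComposition    # per C-mol
    product_composition: ElementalComposition    # per C-mol
    D: float
    carbon_recovery: float = float("nan")
    oxygen_measured: bool = False
    warnings: list[str] = field(default_factory=list)


def assemble_macrochemical(record: ChemostatRecord) -> MacrochemicalEquation:
    """Build the C-mol macrochemical equation from one (converted) record.

    Water is always closed from the hydrogen balance; oxygen is taken from
    the measurement when present, otherwise closed from the oxygen balance.
    A carbon recovery below 0.9 annotates the result with a data-quality
    warning (it never raises).
    """
    record = to_cmol_units(record)
    vals, units = record.values, record.units

    def alpha(key: str) -> float | None:
        v = vals.get(key)
        if v is None:
            return None
        if units[key] == "per_cmol_substrate":
            return v
        # specific rate: divide by specific substrate consumption
        q_s = vals["substrate"]
        if q_s is None or units["substrate"] != "specific_cmol":
            raise ValueError("specific rates require a measured substrate rate")
        return abs(v) / abs(q_s)

    if vals.get("substrate") is None:
        raise ValueError("substrate measurement is required")
    a2 = alpha("biomass")
    if a2 is None:
        if units["substrate"] != "specific_cmol":
            raise ValueError("biomass coefficient missing and substrate rate not specific")
        a2 = record.D / abs(vals["substrate"])  # growth rate over uptake rate
    a3 = alpha("product") or 0.0
    a4 = alpha("co2")
    if a4 is None:
        raise ValueError("CO2 measurement is required")
    a1_measured = alpha("o2")

    sub = _compound_for(record, "substrate").normalize_per_cmol()
    prod = _compound_for(record, "product").normalize_per_cmol()
    bio = record.biomass_composition
    if not bio.is_cmol_normalized:
        bio = bio.normalize_per_cmol()
    x_s, y_s = sub["H"], sub["O"]
    a_x, b_x, c_x = bio["H"], bio["O"], bio["N"]
    h_p, o_p = prod["H"], prod["O"]

    # hydrogen balance -> water; oxygen balance -> O2 when unmeasured
    a5 = (x_s + 3.0 * c_x * a2 - a2 * a_x - a3 * h_p) / 2.0
    if a1_measured is not None:
        a1 = a1_measured
    else:
        a1 = (a2 * b_x + a3 * o_p + 2.0 * a4 + a5 - y_s) / 2.0
    cr = a2 + a3 + a4
    eq = MacrochemicalEquation(
        alpha1=a1, alpha2=a2, alpha3=a3, alpha4=a4, alpha5=a5,
        substrate=record.substrate, product=record.product,
        substrate_composition=sub, biomass_composition=bio,
        product_composition=prod, D=record.D,
        carbon_recovery=cr, oxygen_measured=a1_measured is not None,
    )
    if cr < 0 or cr > 1.1:
        raise ValueError(
            f"carbon recovery {cr:.3f} outside [0, 1.1]: carbon balance violated "
            f"(alpha2={a2:.3f}, alpha3={a3:.3f}, alpha4={a4:.3f})"
        )
    if cr < CR_WARN_THRESHOLD:
        msg = (f"carbon recovery {cr:.3f} < {CR_WARN_THRESHOLD}: unmeasured products likely; "
               "catabolic stoichiometry will be unreliable")
        eq.warnings.append(msg)
        logger.warning("D = %.3f /h: %s", record.D, msg)
    return eq


@dataclass
class CatabolicStoichiometry:
    """``[S] + c2 O2 -> c3 CO2 + c4 P + c5 H2O`` per 1 C-mol substrate.

    ``c4`` is in C-mol of the overflow product; ``c2``, ``c3``, ``c5`` in mol.
    """

    c2: float
    c3: float
    c4: float
    c5: float
    substrate: str
    product: str
    substrate_composition: ElementalComposition
    product_composition: ElementalComposition
    delta_cat_g_std: float | None = None

    c1: float = 1.0  # by normalization

    def to_conversion(self, substrate_carbons: float, product_carbons: float) -> ConversionStoichiometry:
        """Mol-basis signed conversion per C-mol substrate (for Hess's law)."""
        return ConversionStoichiometry(
            {
                self.substrate: -1.0 / substrate_carbons,
                "o2": -self.c2,
                "co2": self.c3,
                self.product: self.c4 / product_carbons,
                "h2o": self.c5,
            },
            basis="per_cmol_substrate",
            label=f"catabolism({self.substrate}->{self.product})",
        )

    def element_residuals(self) -> dict[str, float]:
        s, p = self.substrate_composition, self.product_composition
        return {
            "C": 1.0 - (self.c3 + self.c4),
            "H": s["H"] - (self.c4 * p["H"] + 2.0 * self.c5),
            "O": s["O"] + 2.0 * self.c2 - (2.0 * self.c3 + self.c4 * p["O"] + self.c5),
        }


def split_catabolic(
    macro: MacrochemicalEquation, ana: AnabolicStoichiometry
) -> CatabolicStoichiometry:
    """Subtract ``alpha2 x`` (anabolic equation) and renormalize to c1 = 1.

    ``c1 = 1 - b1 alpha2`` is the substrate fraction burnt by catabolism; it
    must be positive (a yield at the theoretical maximum leaves nothing to
    split).
    """
    if macro.biomass_composition.counts != ana.biomass.counts:
        raise ValueError("macrochemical and anabolic biomass compositions differ")
    if macro.substrate_composition.counts != ana.substrate.counts:
        raise ValueError("macrochemical and anabolic substrate compositions differ")
    c1 = 1.0 - ana.b1 * macro.alpha2
    if c1 <= 1e-9:
        raise ValueError(
            f"record at D = {macro.D:.3f} /h: anabolism consumes all substrate "
            f"(b1*alpha2 = {ana.b1 * macro.alpha2:.4f} >= 1); no catabolic equation exists"
        )
    c2 = macro.alpha1
    c3 = macro.alpha4 - ana.b3 * macro.alpha2
    c4 = macro.alpha3
    c5 = macro.alpha5 - ana.b4 * macro.alpha2
    return CatabolicStoichiometry(
        c2=c2 / c1, c3=c3 / c1, c4=c4 / c1, c5=c5 / c1,
        substrate=macro.substrate, product=macro.product,
        substrate_composition=macro.substrate_composition,
        product_composition=macro.product_composition,
    )


def anabolic_reaction_energy(
    ana: AnabolicStoichiometry,
    table: FormationEnergyTable,
    substrate_id: str,
    substrate_carbons: float,
    biomass_dfg: float | None = None,
) -> float:
    """Standard anabolic reaction energy (kJ per C-mol biomass).

    The biomass formation energy defaults to the empirical composition-based
    estimate, Legendre-transformed into the table's convention so it can be
    combined with the transformed compound energies.
    """
    if biomass_dfg is None:
        biomass_dfg = battley_formation_energy(ana.biomass, table.conditions)
    conv = ConversionStoichiometry(
        {
            substrate_id: -ana.b1 / substrate_carbons,
            "nh3": -ana.b2,
            "co2": ana.b3,
            "h2o": ana.b4,
        },
        basis="per_cmol_biomass",
        label="anabolism",
    )
    return standard_reaction_energy(conv, table) + biomass_dfg


@dataclass
class ConverterPoint:
    """Fluxes, forces and powers of one chemostat condition.

    Jcat is the catabolized substrate flux (C-mol substrate per C-mol biomass
    per h), Jana = D.  Forces are the negated standard reaction energies
    (kJ C-mol^-1); powers are flux times force (kJ (C-mol biomass)^-1 h^-1).
    """

    D: float
    j_cat: float
    j_ana: float
    delta_cat_g: float
    delta_ana_g: float
    force_ratio: float
    p_cat: float
    p_ana: float
    c_atp: float | None = None
    p_atp: float | None = None
    carbon_recovery: float = float("nan")
    catabolic: CatabolicStoichiometry | None = None
    warnings: list[str] = field(default_factory=list)


def converter_analysis(
    records: Sequence[ChemostatRecord],
    ana: AnabolicStoichiometry,
    table: FormationEnergyTable,
    net=None,
    delta_g_atpase: float = DELTA_G_ATPASE_DEFAULT,
    biomass_dfg: float | None = None,
) -> list[ConverterPoint]:
    """Full flux/force/power analysis of a chemostat series.

    The anabolic energy is computed once (the anabolic stoichiometry, hence
    its standard reaction energy, does not change with D); the catabolic
    energy is that of each record's realized catabolic stoichiometry.  When a
    metabolic network with an ATP-hydrolysis reaction is supplied, the
    maximal ATP yield of each catabolic conversion and the ATP-production
    power are added.
    """
    if not records:
        return []
    first = records[0]
    sub_carbons = _compound_for(first, "substrate")["C"]
    dana = anabolic_reaction_energy(ana, table, first.substrate, sub_carbons,
                                    biomass_dfg=biomass_dfg)
    points = []
    for rec in records:
        macro = assemble_macrochemical(rec)
        if 1.0 - ana.b1 * macro.alpha2 <= 1e-9:
            # yield at the theoretical maximum: nothing is catabolized
            points.append(ConverterPoint(
                D=rec.D, j_cat=0.0, j_ana=rec.D,
                delta_cat_g=0.0, delta_ana_g=dana, force_ratio=0.0,
                p_cat=0.0, p_ana=-rec.D * dana,
                carbon_recovery=macro.carbon_recovery,
                warnings=list(macro.warnings) + ["zero catabolism: yield at theoretical maximum"],
            ))
            continue
        cat = split_catabolic(macro, ana)
        prod_carbons = _compound_for(rec, "product")["C"]
        conv = cat.to_conversion(sub_carbons, prod_carbons)
        dcat = standard_reaction_energy(conv, table)
        cat = replace(cat, delta_cat_g_std=dcat)
        j_cat = rec.D * (1.0 / macro.alpha2 - ana.b1)
        c_atp = p_atp = None
        if net is not None:
            try:
                from .conversion_cone import ECM
                from .lp_analyses import max_atp_yield

                c_atp = max_atp_yield(net, ECM(stoich=conv))
                p_atp = c_atp * j_cat * delta_g_atpase
            except ValueError as exc:
                logger.warning("ATP yield omitted: %s", exc)
        points.append(ConverterPoint(
            D=rec.D, j_cat=j_cat, j_ana=rec.D,
            delta_cat_g=dcat, delta_ana_g=dana,
            force_ratio=dcat / dana,
            p_cat=-j_cat * dcat, p_ana=-rec.D * dana,
            c_atp=c_atp, p_atp=p_atp,
            carbon_recovery=macro.carbon_recovery,
            catabolic=cat, warnings=list(macro.warnings),
        ))
    return points


@dataclass
class LinearConverterFit:
    """Least-squares phenomenological matrix L with diagnostics.

    ``J approx L X`` with J = (Jcat, Jana) and X = (-dGcat, -dGana).  A
    negative ``spearman_jcat_force`` documents fluxes that *decrease* with
    increasing catabolic force — the signature of overflow metabolism that
    falsifies the linear converter over pathway-switching conditions.
    """

    L: np.ndarray
    residuals: np.ndarray  # (n, 2) per-point flux residuals
    max_residual: float
    spearman_jcat_force: float
    spearman_pvalue: float


def fit_linear_converter(points: Sequence[ConverterPoint]) -> LinearConverterFit:
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit the converter matrix")
    X = np.array([[-p.delta_cat_g, -p.delta_ana_g] for p in points]).T  # 2 x n
    J = np.array([[p.j_cat, p.j_ana] for p in points]).T
    gram = X @ X.T
    if np.linalg.matrix_rank(gram, tol=1e-12 * max(1.0, float(np.abs(gram).max()))) < 2:
        raise ValueError("degenerate force variation: forces do not span two dimensions")
    L = J @ X.T @ np.linalg.inv(gram)
    resid = (J - L @ X).T
    from scipy.stats import spearmanr

    forces = X[0]
    jcat = J[0]
    if np.allclose(forces, forces[0]) or np.allclose(jcat, jcat[0]):
        rho, pval = 0.0, 1.0
    else:
        rho, pval = spearmanr(jcat, forces)
    return LinearConverterFit(
        L=L,
        residuals=resid,
        max_residual=float(np.abs(resid).max()),
        spearman_jcat_force=float(rho),
        spearman_pvalue=float(pval),
    )


def decompose_catabolic(
    cat: CatabolicStoichiometry,
    respiration: ConversionStoichiometry,
    fermentation: ConversionStoichiometry,
    substrate_carbons: float,
    product_carbons: float,
) -> float:
    """Fermentation fraction phi of a catabolic conversion.

    Projects the realized conversion (per C-mol substrate) onto the segment
    between a pure respiration and a pure fermentation mode (both normalized
    per -1 C-mol substrate) by scalar least squares.
    """
    conv = cat.to_conversion(substrate_carbons, product_carbons)
    compounds = sorted(set(conv.coefficients) | set(respiration.coefficients)
                       | set(fermentation.coefficients))
    c = np.array([conv[m] for m in compounds])
    r = np.array([respiration[m] for m in compounds])
    f = np.array([fermentation[m] for m in compounds])
    d = f - r
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("respiration and fermentation modes are identical")
    return float((c - r) @ d / denom)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "D_per_h", "q_substrate", "q_o2", "q_co2", "q_product", "q_biomass",
    "unit_substrate", "unit_o2", "unit_co2", "unit_product", "unit_biomass",
    "substrate", "product", "biomass_formula", "biomass_cmol_mass",
]


def write_chemostat_tsv(records: Sequence[ChemostatRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            row = [repr(float(rec.D))]
            for key in _RATE_KEYS:
                v = rec.values.get(key)
                row.append("" if v is None else repr(float(v)))
            for key in _RATE_KEYS:
                row.append(rec.units.get(key, ""))
            row += [rec.substrate, rec.product, rec.biomass_composition.formula(),
                    "" if rec.biomass_cmol_mass is None else repr(float(rec.biomass_cmol_mass))]
            writer.writerow(row)


def read_chemostat_tsv(path) -> list[ChemostatRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        ):
            values: dict[str, float | None] = {}
            units: dict[str, str] = {}
            for key in _RATE_KEYS:
                raw = row.get(f"q_{key}", "")
                values[key] = float(raw) if raw not in ("", None) else None
                unit = row.get(f"unit_{key}", "")
                if unit:
                    units[key] = unit
            records.append(ChemostatRecord(
                D=float(row["D_per_h"]),
                values=values,
                units=units,
                substrate=row.get("substrate") or "glc",
                product=row.get("product") or "etoh",
                biomass_composition=parse_formula(row["biomass_formula"], label="biomass"),
                biomass_cmol_mass=float(row["biomass_cmol_mass"]) if row.get("biomass_cmol_mass") else None,
            ))
    return records


def write_converter_table(points: Sequence[ConverterPoint], path) -> None:
    """Per-condition TSV: catabolic coefficients, forces, fluxes, powers, CR."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["D_per_h", "c1", "c2", "c3", "c4", "c5", "dG_cat", "dG_ana",
                         "J_cat", "J_ana", "x", "P_cat", "P_ana", "c_atp", "P_atp",
                         "CR", "warnings"])
        for p in points:
            cat = p.catabolic
            writer.writerow([
                f"{p.D:.6g}",
                *(("", "", "", "", "") if cat is None else
                  (f"{cat.c1:.6g}", f"{cat.c2:.6g}", f"{cat.c3:.6g}",
                   f"{cat.c4:.6g}", f"{cat.c5:.6g}")),
                f"{p.delta_cat_g:.6g}", f"{p.delta_ana_g:.6g}",
                f"{p.j_cat:.6g}", f"{p.j_ana:.6g}", f"{p.force_ratio:.6g}",
                f"{p.p_cat:.6g}", f"{p.p_ana:.6g}",
                "" if p.c_atp is None else f"{p.c_atp:.6g}",
                "" if p.p_atp is None else f"{p.p_atp:.6g}",
                f"{p.carbon_recovery:.6g}",
                "; ".join(p.warnings),
            ])
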