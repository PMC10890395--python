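"""Gibbs-energy bookkeeping for overall metabolic conversions.

Reaction energies are obtained by Hess's law over a table of transformed
standard Gibbs energies of formation (kJ/mol at fixed temperature, pH, pMg and
ionic strength).  The module also provides the Legendre transform used to
produce such tables from chemical-standard species energies, a concentration
correction ``RT * sum(nu_i ln c_i)``, an empirical estimate of the biomass
formation energy, and the thermodynamic efficiency of ATP production.

Sign conventions: stoichiometric coefficients are positive for products and
negative for substrates, so spontaneous (energy-releasing) conversions have a
negative reaction energy.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .composition import ElementalComposition, degree_of_reduction

__all__ = [
    "R_KJ",
    "DELTA_G_ATPASE_DEFAULT",
    "ThermoConditions",
    "FormationEnergyTable",
    "ConversionStoichiometry",
    "legendre_transform",
    "pseudoisomer_energy",
    "standard_reaction_energy",
    "concentration_correction",
    "battley_formation_energy",
    "atp_production_efficiency",
    "default_formation_table",
]

logger = logging.getLogger(__name__)

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314462618e-3

#: Typical Gibbs energy of ATP synthesis from ADP and phosphate in E. coli
#: (kJ/mol); used as the default work term of the efficiency calculation.
DELTA_G_ATPASE_DEFAULT = 46.5

#: Compound ids whose activity is fixed to 1 (solvent / transformed-convention
#: proton); their concentrations are never part of the correction term.
UNIT_ACTIVITY_IDS = frozenset({"h2o", "water", "h", "h+", "proton"})


@dataclass(frozen=True)
class ThermoConditions:
    """Aqueous reference conditions of a transformed-energy table."""

    temperature: float = 298.15  # K
    pH: float = 7.4
    pMg: float = 3.0
    ionic_strength: float = 0.25  # mol/L

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def RT(self) -> float:
        return R_KJ * self.temperature


def _debye_hueckel(conditions: ThermoConditions) -> float:
    """Extended Debye-Hueckel factor (kJ/mol) at the given ionic strength."""
    sqrt_i = math.sqrt(conditions.ionic_strength)
    return 2.91482 * sqrt_i / (1.0 + 1.6 * sqrt_i)


def legendre_transform(
    dfg_chemical: float, n_hydrogen: float, charge: float, conditions: ThermoConditions
) -> float:
    """Transform a chemical-standard formation energy to fixed pH and I.

    ``dfg' = dfg + N_H RT ln(10) pH - DH * (z^2 - N_H)`` where ``DH`` is the
    extended Debye-Hueckel term.  This is the per-species half of the
    transformed-energy convention; multi-species compounds are combined with
    :func:`pseudoisomer_energy`.
    """
    rt = conditions.RT
    return (
        dfg_chemical
        + n_hydrogen * rt * math.log(10.0) * conditions.pH
        - _debye_hueckel(conditions) * (charge * charge - n_hydrogen)
    )


def pseudoisomer_energy(transformed_energies: Iterable[float], conditions: ThermoConditions) -> float:
    """Combine protonation states: ``-RT ln sum(exp(-g_i / RT))``."""
    gs = list(transformed_energies)
    if not gs:
        raise ValueError("no pseudoisomers given")
    rt = conditions.RT
    gmin = min(gs)
    return gmin - rt * math.log(sum(math.exp(-(g - gmin) / rt) for g in gs))


@dataclass
class FormationEnergyTable:
    """Transformed standard formation energies (kJ/mol) by compound id."""

    energies: dict[str, float]
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    provenance: dict[str, str] = field(default_factory=dict)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.energies

    def __getitem__(self, compound_id: str) -> float:
        return self.energies[compound_id]

    def missing(self, compound_ids: Iterable[str]) -> list[str]:
        return sorted(c for c in set(compound_ids) if c not in self.energies)

    @classmethod
    def from_tsv(cls, path, conditions_path=None) -> "FormationEnergyTable":
        """Read columns compound_id, name, dfg_prime_kj_mol, source.

        ``conditions_path`` defaults to ``<path stem>.conditions.json``.
        """
        energies: dict[str, float] = {}
        provenance: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            ):
                energies[row["compound_id"]] = float(row["dfg_prime_kj_mol"])
                provenance[row["compound_id"]] = row.get("source", "")
        conditions = ThermoConditions()
        if conditions_path is None:
            candidate = str(path).rsplit(".", 1)[0] + ".conditions.json"
            import os

            conditions_path = candidate if os.path.exists(candidate) else None
        if conditions_path is not None:
            with open(conditions_path) as fh:
                conditions = ThermoConditions(**json.load(fh))
        return cls(energies=energies, conditions=conditions, provenance=provenance)

    def to_tsv(self, path, conditions_path=None) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["compound_id", "name", "dfg_prime_kj_mol", "source"])
            for cid in sorted(self.energies):
                writer.writerow([cid, cid, repr(self.energies[cid]), self.provenance.get(cid, "")])
        if conditions_path is not None:
            with open(conditions_path, "w") as fh:
                json.dump(
                    {
                        "temperature": self.conditions.temperature,
                        "pH": self.conditions.pH,
                        "pMg": self.conditions.pMg,
                        "ionic_strength": self.conditions.ionic_strength,
                    },
                    fh,
                    indent=1,
                )


def default_formation_table() -> FormationEnergyTable:
    """The vendored snapshot table at 298.15 K, pH 7.4, pMg 3.0, I = 0.25 M."""
    data = resources.files("anacat") / "data"
    return FormationEnergyTable.from_tsv(
        str(data / "formation_energies.tsv"),
        str(data / "formation_energies.conditions.json"),
    )


@dataclass(frozen=True)
class ConversionStoichiometry:
    """Signed coefficients of an overall conversion over external compounds.

    Products are positive, substrates negative.  ``basis`` records the
    normalization: ``"per_cmol_substrate"`` (designated carbon source
    contributes -1 C-mol), ``"per_mol"`` or ``"raw"``.  Coefficients are in
    mol of each compound per basis unit (biomass, whose formation energy is
    tabulated per C-mol, may appear with a per-C-mol coefficient as long as
    the table entry matches).
    """

    coefficients: Mapping[str, float]
    basis: str = "raw"
    label: str = ""

    def __post_init__(self) -> None:
        clean = {c: float(v) for c, v in dict(self.coefficients).items() if v}
        object.__setattr__(self, "coefficients", clean)

    def items(self):
        return self.coefficients.items()

    def __getitem__(self, compound_id: str) -> float:
        return self.coefficients.get(compound_id, 0.0)

    def scaled(self, factor: float) -> "ConversionStoichiometry":
        return ConversionStoichiometry(
            {c: v * factor for c, v in self.coefficients.items()}, self.basis, self.label
        )

    def reversed(self) -> "ConversionStoichiometry":
        return self.scaled(-1.0)

    def __add__(self, other: "ConversionStoichiometry") -> "ConversionStoichiometry":
        coeffs = dict(self.coefficients)
        for c, v in other.coefficients.items():
            coeffs[c] = coeffs.get(c, 0.0) + v
        return ConversionStoichiometry(coeffs, "raw", f"{self.label}+{other.label}")


def standard_reaction_energy(
    stoich: ConversionStoichiometry, table: FormationEnergyTable
) -> float:
    """Hess's law: ``sum(nu_i * dfG'_i)`` in kJ per basis unit of ``stoich``."""
    missing = table.missing(stoich.coefficients)
    if missing:
        raise KeyError(f"formation energies missing for compounds: {missing}")
    return sum(nu * table[c] for c, nu in stoich.items())


def concentration_correction(
    stoich: ConversionStoichiometry,
    concentrations: Mapping[str, float],
    conditions: ThermoConditions | None = None,
) -> float:
    """``RT * sum(nu_i ln c_i)`` in kJ per basis unit (c_i in mol/L).

    Water and the proton keep unit activity under the transformed convention;
    their concentrations are ignored (with a log message if supplied).
    """
    conditions = conditions or ThermoConditions()
    rt = conditions.RT
    total = 0.0
    for cid, nu in stoich.items():
        if cid.lower() in UNIT_ACTIVITY_IDS:
            if cid in concentrations:
                logger.info("ignoring concentration of unit-activity species %r", cid)
            continue
        if cid not in concentrations:
            raise KeyError(f"no concentration given for {cid!r}")
        c = concentrations[cid]
        if not c > 0:
            raise ValueError(f"concentration of {cid!r} must be strictly positive, got {c}")
        total += nu * math.log(c)
    return rt * total


# ---------------------------------------------------------------------------
# Biomass formation energy
# ---------------------------------------------------------------------------

# Empirical correlation for the standard Gibbs energy of formation of dry
# biomass (kJ per C-mol), after Battley's composition-based estimation
# approach: the formation energy varies linearly with the degree of reduction
# (the electron content relative to CO2/H2O/NH3/phosphate/sulfate) with an
# additional nitrogen-content term.  The three coefficients are calibrated to
# published Battley-method estimates for three experimentally characterized
# biomass compositions (yeast CH1.79O0.57N0.15 -> -104.9; E. coli
# CH1.811O0.503N0.258P0.022S0.006(-0.018) -> -101.10; yeast
# CH1.8243O0.6589N0.1557P0.0055S0.0022 -> -128.76 kJ C-mol^-1).
_BATTLEY_INTERCEPT = -956.2552671285877
_BATTLEY_GAMMA_COEF = 201.11449069898122
_BATTLEY_NITROGEN_COEF = 44.49604124353248

#: Composition box (per C-mol) within which the correlation is considered
#: calibrated; far outside it the estimate is extrapolation and a warning is
#: emitted.
_BATTLEY_RANGE = {"H": (1.4, 2.2), "O": (0.3, 0.9), "N": (0.0, 0.35)}


def battley_formation_energy(
    biomass: ElementalComposition, conditions: ThermoConditions | None = None
) -> float:
    """Empirical standard Gibbs energy of formation of biomass (kJ C-mol^-1).

    Chemical-standard convention by default; pass ``conditions`` to obtain the
    value in the transformed convention of a formation-energy table (adds the
    Legendre/Debye-Hueckel terms for the biomass hydrogen content and charge),
    which is required before mixing the estimate with transformed compound
    energies in one reaction.
    """
    if not biomass.is_cmol_normalized:
        raise ValueError("biomass composition must be C-mol normalized")
    unsupported = [el for el in biomass.counts if el not in ("C", "H", "O", "N", "P", "S")]
    if unsupported:
        raise ValueError(f"unsupported elements for biomass energy estimate: {unsupported}")
    for el, (lo, hi) in _BATTLEY_RANGE.items():
        if not (lo - 0.3 <= biomass[el] <= hi + 0.3):
            warnings.warn(
                f"biomass {el} content {biomass[el]:.3f} is far outside the calibration "
                f"range {lo}-{hi}; the formation-energy estimate is an extrapolation",
                stacklevel=2,
            )
    gamma_x = degree_of_reduction(biomass)
    dfg = _BATTLEY_INTERCEPT + _BATTLEY_GAMMA_COEF * gamma_x + _BATTLEY_NITROGEN_COEF * biomass["N"]
    if conditions is not None:
        dfg = legendre_transform(dfg, biomass["H"], biomass.charge, conditions)
    return dfg


def atp_production_efficiency(
    c_atp: float, delta_cat_g: float, delta_g_atpase: float = DELTA_G_ATPASE_DEFAULT
) -> float:
    """Fraction of the catabolic energy gradient conserved as ATP work.

    ``eta = c_atp * delta_g_atpase / |delta_cat_g|`` with ``c_atp`` in mol ATP
    per C-mol substrate and ``delta_cat_g`` the (negative) catabolic reaction
    energy in kJ per C-mol substrate.
    """
    if c_atp < 0:
        raise ValueError("ATP yield must be non-negative")
    if not delta_cat_g < 0:
        raise ValueError(
            f"catabolic reaction energy must be negative (energy-releasing), got {delta_cat_g}"
        )
    eta = c_atp * delta_g_atpase / abs(delta_cat_g)
    if eta > 1.0:
        warnings.warn(
            f"efficiency {eta:.3f} > 1 violates the second law; the ATP yield and the "
            "reaction energy are mutually inconsistent",
            stacklevel=2,
        )
    return eta
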