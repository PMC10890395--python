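"""Elemental-composition algebra for black-box growth stoichiometry.

Compounds and biomass are described by per-carbon-mole (C-mol) sum formulas
such as ``CH2O`` (glucose) or ``CH1.79O0.57N0.15`` (yeast biomass).  The degree
of reduction :math:`\\gamma` counts the electrons per C-mol that become
available on full oxidation to CO2, H2O and NH3, and bounds the carbon yield
of growth: at most :math:`\\gamma_S/\\gamma_X` C-mol biomass can be made per
C-mol substrate when the biomass is more reduced than the substrate.  From the
two compositions alone an ideal (redox- and element-balanced) anabolic
equation

.. math:: b_1\\,[S] + b_2\\,NH_3 \\rightarrow [X] + b_3\\,CO_2 + b_4\\,H_2O

can be written down; it is the reference half-reaction that the chemostat
analysis subtracts from measured macrochemical equations.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "ELEMENTS",
    "REDUCTION_DEGREE_WEIGHTS",
    "ElementalComposition",
    "AnabolicStoichiometry",
    "parse_formula",
    "degree_of_reduction",
    "max_theoretical_yield",
    "ideal_anabolic_stoichiometry",
    "read_compound_registry",
    "write_compound_registry",
]

#: Elements tracked by the composition algebra.
ELEMENTS = ("C", "H", "O", "N", "P", "S")

#: Electrons made available per atom on full oxidation to CO2 / H2O / NH3 /
#: phosphate / sulfate (the references of the degree-of-reduction convention).
REDUCTION_DEGREE_WEIGHTS = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "P": 5.0, "S": 6.0}

GAMMA_TOL = 1e-9

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")
# trailing charge: sign-first ("-0.018", "+2", bare "+") or caret-magnitude
# ("^2-"); a bare "<digits><sign>" form would be ambiguous with subscripts
_CHARGE_SUFFIX_RE = re.compile(r"(?:\^(?P<mag>\d*\.?\d*)(?P<tsign>[+-])|(?P<signed>[+-]\d*\.?\d*))$")


class FormulaError(ValueError):
    """Raised for malformed or unsupported sum formulas."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts per formula unit plus a net charge.

    Counts are non-negative reals (fractional subscripts are the norm for
    biomass formulas).  ``charge`` is the signed net charge per formula unit.
    """

    counts: Mapping[str, float]
    charge: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} (supported: {ELEMENTS})")
            n = float(n)
            if not n >= 0.0 or n != n or n == float("inf"):
                raise FormulaError(f"element count for {el} must be finite and >= 0, got {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)
        object.__setattr__(self, "charge", float(self.charge))

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    @property
    def carbon(self) -> float:
        return self["C"]

    @property
    def is_cmol_normalized(self) -> bool:
        return abs(self["C"] - 1.0) <= GAMMA_TOL

    def normalize_per_cmol(self) -> "ElementalComposition":
        """Divide all counts and the charge by the carbon number."""
        c = self["C"]
        if c <= 0.0:
            raise FormulaError(f"cannot C-mol-normalize carbon-free composition {self.label or self.counts}")
        return replace(
            self,
            counts={el: n / c for el, n in self.counts.items()},
            charge=self.charge / c,
        )

    def formula(self, digits: int = 4) -> str:
        """Render a sum-formula string (inverse of :func:`parse_formula`)."""
        parts = []
        for el in ELEMENTS:
            n = self[el]
            if not n:
                continue
            if abs(n - 1.0) <= 1e-12:
                parts.append(el)
            elif abs(n - round(n)) <= 1e-12:
                parts.append(f"{el}{int(round(n))}")
            else:
                parts.append(f"{el}{round(n, digits):g}")
        body = "".join(parts) or ""
        if self.charge:
            z = self.charge
            if abs(z - round(z)) <= 1e-12:
                z = int(round(z))
            body += f"{'+' if z > 0 else '-'}{abs(z):g}"
        return body


def parse_formula(text: str, label: str = "") -> ElementalComposition:
    """Parse a sum-formula string with decimal subscripts and optional charge.

    Missing subscripts mean 1 (``CH2O`` -> C1 H2 O1); a trailing charge may be
    written ``-2``, ``2-``, ``+``, ``^-0.018`` or ``0.018-``.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    body = text.strip()
    charge = 0.0
    m = _CHARGE_SUFFIX_RE.search(body)
    if m and m.start() > 0:
        if m.group("signed") is not None:
            signed = m.group("signed")
            charge = float(signed + "1") if signed in ("+", "-") else float(signed)
        else:
            mag = m.group("mag")
            charge = (float(mag) if mag else 1.0) * (1 if m.group("tsign") == "+" else -1)
        body = body[: m.start()]

    counts: dict[str, float] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(body):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r}: cannot parse {body[pos:m.start()]!r}")
        el, sub = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in formula {text!r}")
        if sub in ("", None):
            n = 1.0
        else:
            try:
                n = float(sub)
            except ValueError:  # e.g. a lone '.'
                raise FormulaError(f"malformed subscript {sub!r} in formula {text!r}") from None
        counts[el] = counts.get(el, 0.0) + n
        pos = m.end()
    if pos != len(body):
        raise FormulaError(f"malformed formula {text!r}: trailing {body[pos:]!r}")
    if not counts:
        raise FormulaError(f"formula {text!r} contains no elements")
    return ElementalComposition(counts=counts, charge=charge, label=label or text.strip())


def degree_of_reduction(comp: ElementalComposition) -> float:
    """Electrons per C-mol: ``4 + H - 2 O - 3 N + 5 P + 6 S - charge``.

    The composition must be C-mol normalized (C == 1).  Reference states are
    CO2 for carbon, H2O for oxygen, NH3 for nitrogen, phosphate for P and
    sulfate for S; a net negative charge adds electrons (subtract the signed
    charge).
    """
    if not comp.is_cmol_normalized:
        raise ValueError(
            f"degree of reduction requires a C-mol normalized composition (C == 1), "
            f"got C = {comp['C']} for {comp.label or comp.counts}"
        )
    gamma = sum(REDUCTION_DEGREE_WEIGHTS[el] * comp[el] for el in ELEMENTS)
    return gamma - comp.charge


def max_theoretical_yield(gamma_s: float, gamma_x: float) -> float:
    """Maximal C-mol biomass per C-mol substrate from degrees of reduction.

    ``gamma_s / gamma_x`` when the substrate is at most as reduced as the
    biomass, else 1 (a more reduced substrate cannot lift the carbon yield
    above one).
    """
    if not (gamma_s > 0 and gamma_x > 0):
        raise ValueError(f"degrees of reduction must be positive, got {gamma_s}, {gamma_x}")
    if gamma_s <= gamma_x + GAMMA_TOL:
        return min(gamma_s / gamma_x, 1.0)
    return 1.0


@dataclass(frozen=True)
class AnabolicStoichiometry:
    """Ideal anabolic half-reaction ``b1 [S] + b2 NH3 -> [X] + b3 CO2 + b4 H2O``.

    All coefficients are per C-mol biomass; ``[S]`` and ``[X]`` are C-mol of
    substrate and biomass.  ``b1 = 1/y_max`` and ``b1 = 1 + b3`` hold exactly.
    """

    b1: float
    b2: float
    b3: float
    b4: float
    y_max: float
    substrate: ElementalComposition
    biomass: ElementalComposition

    def element_residuals(self) -> dict[str, float]:
        """Per-element balance residuals (reactants minus products)."""
        s, x = self.substrate, self.biomass
        return {
            "C": self.b1 * s["C"] - (x["C"] + self.b3),
            "H": self.b1 * s["H"] + 3 * self.b2 - (x["H"] + 2 * self.b4),
            "O": self.b1 * s["O"] - (x["O"] + 2 * self.b3 + self.b4),
            "N": self.b2 - x["N"],
        }


def ideal_anabolic_stoichiometry(
    substrate: ElementalComposition, biomass: ElementalComposition
) -> AnabolicStoichiometry:
    """Redox-balanced ideal anabolic equation from the two compositions.

    Requires C-mol-normalized CHxOy substrate and CHaObNc biomass with
    ``gamma_S <= gamma_X``.  The fraction of substrate carbon that must be
    oxidized to CO2 to pay for the extra reduction of biomass fixes
    ``b3 = (gamma_X - gamma_S)/gamma_S``; carbon, nitrogen and hydrogen
    balances then determine ``b1``, ``b2`` and ``b4`` (the oxygen balance
    closes automatically).
    """
    for comp, who in ((substrate, "substrate"), (biomass, "biomass")):
        if not comp.is_cmol_normalized:
            raise ValueError(f"{who} composition must be C-mol normalized (C == 1)")
    for el in ("N", "P", "S"):
        if substrate[el]:
            raise ValueError(f"substrate must be a CHxOy compound, found {el}")
    if substrate.charge:
        raise ValueError("charged substrates are not supported by the ideal anabolic equation")
    # biomass P/S/charge enter only through the degree of reduction (their
    # assimilation from phosphate/sulfate is implicit); the written equation
    # then balances C, H and N exactly, O only for CHON compositions
    gamma_s = degree_of_reduction(substrate)
    gamma_x = degree_of_reduction(biomass)
    if gamma_s > gamma_x + GAMMA_TOL:
        raise ValueError(
            f"substrate (gamma_S = {gamma_s:.4f}) is more reduced than biomass "
            f"(gamma_X = {gamma_x:.4f}); the yield is then carbon- rather than "
            "electron-limited and this ideal stoichiometry does not apply"
        )
    b3 = (gamma_x - gamma_s) / gamma_s
    b1 = 1.0 + b3
    b2 = biomass["N"]
    b4 = (b1 * substrate["H"] + 3.0 * b2 - biomass["H"]) / 2.0
    y_max = max_theoretical_yield(gamma_s, gamma_x)
    return AnabolicStoichiometry(
        b1=b1, b2=b2, b3=b3, b4=b4, y_max=y_max, substrate=substrate, biomass=biomass
    )


def read_compound_registry(path) -> dict[str, ElementalComposition]:
    """Read a TSV compound registry (columns: id, name, formula, charge)."""
    registry: dict[str, ElementalComposition] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            comp = parse_formula(row["formula"], label=row.get("name") or row["id"])
            if row.get("charge") not in (None, ""):
                comp = replace(comp, charge=float(row["charge"]))
            registry[row["id"]] = comp
    return registry


def write_compound_registry(registry: Mapping[str, ElementalComposition], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "name", "formula", "charge"])
        for cid, comp in registry.items():
            # the formula string carries the charge already; keep the explicit
            # column for round-tripping fractional charges losslessly
            counts_only = ElementalComposition(comp.counts, 0.0, comp.label)
            writer.writerow([cid, comp.label, counts_only.formula(), repr(comp.charge)])
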