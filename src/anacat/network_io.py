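"""Stoichiometric-model I/O and preparation for conversion analysis.

A :class:`MetabolicNetwork` is a plain stoichiometric matrix plus the metadata
needed to reason about overall conversions: which reactions exchange a single
compound with the environment, which reaction makes biomass, and the
elemental composition of every external compound.  Exchange fluxes follow the
convention uptake < 0, secretion > 0.

Two dialects are supported: a native JSON-TSV directory (``reactions.tsv`` +
``compounds.tsv`` with human-readable equation strings, lossless round-trip)
and SBML Level 3 (read-only, via cobrapy when installed).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping

from .composition import ElementalComposition, parse_formula

__all__ = ["MetabolicNetwork", "FluxVector", "read_model", "write_model",
           "hide_externals", "normalize_biomass_to_cmol"]

logger = logging.getLogger(__name__)

_ARROWS = ("<=>", "<->", "-->", "->", "=")


@dataclass
class MetabolicNetwork:
    """Stoichiometric matrix with exchange / biomass / composition metadata.

    ``stoichiometry`` maps reaction id -> {metabolite id -> coefficient}
    (products positive).  Exchange reactions have exactly one metabolite with
    coefficient -1, so positive flux exports (secretes) the compound.
    Coefficients are :class:`fractions.Fraction` when the source file carried
    exact decimals, floats otherwise.
    """

    metabolites: list[str]
    reactions: list[str]
    stoichiometry: dict[str, dict[str, Fraction | float]]
    reversible: dict[str, bool]
    exchanges: dict[str, str]  # reaction id -> external compound id
    biomass_reaction: str | None = None
    atpm_reaction: str | None = None
    compositions: dict[str, ElementalComposition] = field(default_factory=dict)
    hidden: set[str] = field(default_factory=set)      # compounds: exchanged but unreported
    closed: set[str] = field(default_factory=set)      # reactions fixed to zero flux

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            stoichiometry={r: dict(s) for r, s in self.stoichiometry.items()},
            reversible=dict(self.reversible),
            exchanges=dict(self.exchanges),
            biomass_reaction=self.biomass_reaction,
            atpm_reaction=self.atpm_reaction,
            compositions=dict(self.compositions),
            hidden=set(self.hidden),
            closed=set(self.closed),
        )

    @property
    def external_compounds(self) -> list[str]:
        return sorted(set(self.exchanges.values()))

    def exchange_of(self, compound_id: str) -> str:
        for rxn, met in self.exchanges.items():
            if met == compound_id:
                return rxn
        raise KeyError(f"no exchange reaction for compound {compound_id!r}")

    def carbon_count(self, compound_id: str) -> float:
        comp = self.compositions.get(compound_id)
        return comp["C"] if comp is not None else 0.0

    def validate(self) -> None:
        for rxn, stoich in self.stoichiometry.items():
            for met in stoich:
                if met not in self.metabolites:
                    raise ValueError(f"reaction {rxn!r} references unknown metabolite {met!r}")
        for rxn in self.exchanges:
            stoich = self.stoichiometry[rxn]
            if len(stoich) != 1:
                raise ValueError(
                    f"exchange reaction {rxn!r} touches {len(stoich)} metabolites; "
                    "an exchange must move exactly one external compound"
                )


@dataclass
class FluxVector:
    """Reaction fluxes with a record of which entries were imposed."""

    fluxes: dict[str, float]
    fixed: set[str] = field(default_factory=set)
    unique: bool = True

    def __getitem__(self, rxn: str) -> float:
        return self.fluxes.get(rxn, 0.0)


def _parse_number(tok: str) -> Fraction | float:
    try:
        return Fraction(tok)
    except ValueError:
        return float(tok)


def _parse_equation(eq: str, rxn_id: str) -> dict[str, Fraction | float]:
    """Parse ``a + 2 b -> c`` style equation strings (either side may be empty)."""
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise ValueError(f"reaction {rxn_id!r}: no arrow in equation {eq!r}")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, Fraction | float] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            toks = term.split()
            if not toks:
                raise ValueError(f"reaction {rxn_id!r}: empty term in {eq!r}")
            if len(toks) == 1:
                coeff, met = Fraction(1), toks[0]
            elif len(toks) == 2:
                coeff, met = _parse_number(toks[0]), toks[1]
            else:
                raise ValueError(f"reaction {rxn_id!r}: cannot parse term {term!r}")
            prev = stoich.get(met, Fraction(0))
            stoich[met] = prev + sign * coeff
    add_side(lhs, -1)
    add_side(rhs, +1)
    return {m: c for m, c in stoich.items() if c}


def _format_equation(stoich: Mapping[str, Fraction | float]) -> str:
    def fmt(side):
        parts = []
        for met, c in side:
            c = abs(c)
            parts.append(met if c == 1 else f"{c} {met}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    return f"{fmt(subs)} -> {fmt(prods)}"


_TRUE = {"1", "true", "yes", "y"}


def read_model(path, dialect: str = "json-tsv") -> MetabolicNetwork:
    """Read a stoichiometric model.

    ``json-tsv``: ``path`` is a directory with ``reactions.tsv`` (id,
    equation, reversible, is_exchange, is_biomass) and ``compounds.tsv`` (id,
    formula, charge).  ``sbml``: read via cobrapy (optional dependency).
    """
    if dialect == "sbml":
        return _read_sbml(path)
    if dialect != "json-tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    import csv

    rx_path = os.path.join(path, "reactions.tsv")
    cp_path = os.path.join(path, "compounds.tsv")
    compositions: dict[str, ElementalComposition] = {}
    if os.path.exists(cp_path):
        with open(cp_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if not row.get("formula"):
                    continue
                comp = parse_formula(row["formula"], label=row["id"])
                if row.get("charge"):
                    comp = replace(comp, charge=float(row["charge"]))
                compositions[row["id"]] = comp

    reactions, stoichiometry, reversible, exchanges = [], {}, {}, {}
    biomass = atpm = None
    mets: set[str] = set()
    with open(rx_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rid = row["id"]
            stoich = _parse_equation(row["equation"], rid)
            reactions.append(rid)
            stoichiometry[rid] = stoich
            reversible[rid] = str(row.get("reversible", "0")).lower() in _TRUE
            mets.update(stoich)
            if str(row.get("is_exchange", "0")).lower() in _TRUE:
                if len(stoich) != 1:
                    raise ValueError(
                        f"exchange reaction {rid!r} touches {sorted(stoich)}; "
                        "an exchange must move exactly one external compound"
                    )
                met, coeff = next(iter(stoich.items()))
                if coeff > 0:  # normalize to 'met -> (outside)'
                    stoichiometry[rid] = {met: -coeff}
                exchanges[rid] = met
            if str(row.get("is_biomass", "0")).lower() in _TRUE:
                biomass = rid
            if rid.upper() == "ATPM":
                atpm = rid
    net = MetabolicNetwork(
        metabolites=sorted(mets),
        reactions=reactions,
        stoichiometry=stoichiometry,
        reversible=reversible,
        exchanges=exchanges,
        biomass_reaction=biomass,
        atpm_reaction=atpm,
        compositions=compositions,
    )
    net.validate()
    logger.info(
        "read %s: %d metabolites, %d reactions, %d exchanges",
        path, len(net.metabolites), len(net.reactions), len(net.exchanges),
    )
    return net


def write_model(net: MetabolicNetwork, path) -> None:
    """Write the JSON-TSV dialect (inverse of :func:`read_model`)."""
    import csv

    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "reactions.tsv"), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "equation", "reversible", "is_exchange", "is_biomass"])
        for rid in net.reactions:
            writer.writerow([
                rid,
                _format_equation(net.stoichiometry[rid]),
                int(net.reversible.get(rid, False)),
                int(rid in net.exchanges),
                int(rid == net.biomass_reaction),
            ])
    with open(os.path.join(path, "compounds.tsv"), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "formula", "charge"])
        for cid in sorted(net.compositions):
            comp = net.compositions[cid]
            bare = ElementalComposition(comp.counts, 0.0, comp.label)
            writer.writerow([cid, bare.formula(), repr(comp.charge)])


def _read_sbml(path) -> MetabolicNetwork:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading SBML requires cobrapy (pip install anacat[sbml])") from exc
    model = cobra.io.read_sbml_model(str(path))
    reactions, stoichiometry, reversible, exchanges = [], {}, {}, {}
    compositions: dict[str, ElementalComposition] = {}
    biomass = atpm = None
    for rxn in model.reactions:
        rid = rxn.id
        reactions.append(rid)
        stoichiometry[rid] = {m.id: Fraction(c).limit_denominator(10**9)
                              for m, c in rxn.metabolites.items()}
        reversible[rid] = rxn.lower_bound < 0 < rxn.upper_bound
        if rxn.boundary:  # single-metabolite boundary reaction
            met, coeff = next(iter(stoichiometry[rid].items()))
            if coeff > 0:
                stoichiometry[rid] = {met: -coeff}
            exchanges[rid] = met
        if "biomass" in rid.lower():
            biomass = rid
        if rid.upper() in ("ATPM", "R_ATPM"):
            atpm = rid
    for met in model.metabolites:
        if met.formula:
            try:
                compositions[met.id] = parse_formula(met.formula, label=met.id)
                if met.charge:
                    compositions[met.id] = replace(compositions[met.id], charge=float(met.charge))
            except Exception:
                logger.debug("skipping unparsable formula %r for %s", met.formula, met.id)
    net = MetabolicNetwork(
        metabolites=[m.id for m in model.metabolites],
        reactions=reactions,
        stoichiometry=stoichiometry,
        reversible=reversible,
        exchanges=exchanges,
        biomass_reaction=biomass,
        atpm_reaction=atpm,
        compositions=compositions,
    )
    logger.info(
        "read %s: %d metabolites, %d reactions, %d exchanges",
        path, len(net.metabolites), len(net.reactions), len(net.exchanges),
    )
    return net


def hide_externals(
    net: MetabolicNetwork,
    max_carbons: int = 6,
    exclude_elements: set[str] = frozenset({"N", "P", "S"}),
) -> MetabolicNetwork:
    """Apply the genome-scale pruning rules before conversion enumeration.

    External compounds containing any element of ``exclude_elements`` are
    *hidden*: their exchange stays open but they are dropped from reported
    conversions (and from elemental-balance checks).  Compounds with more than
    ``max_carbons`` carbon atoms are *dismissed*: their exchange is closed
    (flux fixed to zero).  Pass ``exclude_elements=frozenset()`` and a large
    ``max_carbons`` for the identity.
    """
    from .composition import ELEMENTS

    unknown = set(exclude_elements) - set(ELEMENTS)
    if unknown:
        raise ValueError(f"unknown elements in hide rule: {sorted(unknown)}")
    out = net.copy()
    for rxn, met in net.exchanges.items():
        comp = net.compositions.get(met)
        if comp is None:
            continue
        if comp["C"] > max_carbons:
            out.closed.add(rxn)
            logger.info("dismissed %s (%.0f carbons): exchange %s closed", met, comp["C"], rxn)
        elif any(comp[el] for el in exclude_elements):
            out.hidden.add(met)
            logger.info("hidden external compound %s (contains %s)", met,
                        ",".join(el for el in exclude_elements if comp[el]))
    open_sources = [
        met for rxn, met in out.exchanges.items()
        if rxn not in out.closed and met not in out.hidden and out.carbon_count(met) > 0
    ]
    if not open_sources:
        logger.warning(
            "no open, reportable carbon source remains after hiding/dismissing; "
            "no catabolic conversion can be reported"
        )
    return out


def normalize_biomass_to_cmol(net: MetabolicNetwork) -> MetabolicNetwork:
    """Scale the biomass reaction so unit flux makes exactly 1 C-mol biomass.

    The carbon produced per unit flux is the net carbon consumed from the
    precursors (the biomass pseudo-species itself carries no formula).  The
    derived per-C-mol biomass composition (net element consumption, including
    charge) is attached to the network under the id ``"biomass"``.
    """
    if net.biomass_reaction is None:
        raise ValueError("network has no biomass reaction")
    rid = net.biomass_reaction
    stoich = net.stoichiometry[rid]
    # products without a formula are the biomass pseudo-species (or released
    # cofactors); consumed species must have a formula unless they are
    # recognizable currency metabolites
    currency = {"atp", "adp", "amp", "pi", "ppi", "nad", "nadh", "nadp", "nadph",
                "coa", "h", "h+", "q8", "q8h2", "fad", "fadh2"}
    missing = [m for m, c in stoich.items()
               if c < 0 and m not in net.compositions
               and m.lower().split("_")[0] not in currency]
    if missing:
        raise ValueError(f"unknown carbon content for biomass precursors: {sorted(missing)}")
    net_elements: dict[str, float] = {}
    charge = 0.0
    for met, coeff in stoich.items():
        comp = net.compositions.get(met)
        if comp is None:
            continue
        for el, n in comp.counts.items():
            net_elements[el] = net_elements.get(el, 0.0) - float(coeff) * n
        charge -= float(coeff) * comp.charge
    cmol = net_elements.get("C", 0.0)
    if cmol <= 0:
        raise ValueError("biomass reaction consumes no net carbon; cannot normalize")
    out = net.copy()
    if abs(cmol - 1.0) > 1e-12:
        out.stoichiometry[rid] = {m: c / _as_same_kind(cmol, c) for m, c in stoich.items()}
        logger.info("scaled biomass reaction %s by 1/%s", rid, cmol)
    out.compositions["biomass"] = ElementalComposition(
        {el: n / cmol for el, n in net_elements.items() if el != "C" and n > 1e-15} | {"C": 1.0},
        charge=charge / cmol,
        label="biomass",
    )
    return out


def _as_same_kind(value: float, template) -> Fraction | float:
    if isinstance(template, Fraction):
        return Fraction(value).limit_denominator(10**12)
    return value
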