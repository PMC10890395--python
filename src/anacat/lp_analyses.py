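"""Linear programs over the stoichiometric matrix.

Three constrained LPs characterize the network's energetics:

* :func:`max_atp_yield` — with all exchange fluxes pinned to a given overall
  conversion, maximize flux through ATP hydrolysis (``ATP + H2O -> ADP + Pi``)
  to obtain the conversion's maximal ATP yield.
* :func:`min_substrate_for_biomass` — with 1 C-mol/h of biomass formation
  imposed and ATP available for free (the hydrolysis reaction may run in
  reverse), minimize substrate uptake; the optimum is the substrate cost of
  pure anabolism, and its reciprocal the model's maximal yield.
* :func:`min_atp_for_biomass` — re-impose that minimal substrate uptake and
  minimize the ATP that must be supplied, giving the minimal anabolic ATP
  requirement per C-mol biomass.

Only objective values are contractual: the LPs are typically degenerate and
the returned flux vectors are one optimum among many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .conversion_cone import ECM
from .network_io import FluxVector, MetabolicNetwork

__all__ = ["LPResult", "InfeasibleLP", "max_atp_yield",
           "min_substrate_for_biomass", "min_atp_for_biomass"]

logger = logging.getLogger(__name__)

#: Stand-in for an unbounded flux (logged, not configurable per call).
FLUX_INF = 1e6


class InfeasibleLP(RuntimeError):
    """Raised when a flux LP has no feasible solution."""


@dataclass
class LPResult:
    objective: float | None
    status: str  # optimal | infeasible | unbounded
    fluxes: FluxVector | None = None


def _solve(
    net: MetabolicNetwork,
    objective: Mapping[str, float],
    sense: str = "max",
    fixed: Mapping[str, float] | None = None,
    bounds_override: Mapping[str, tuple[float, float]] | None = None,
) -> LPResult:
    """Solve ``opt c.v  s.t.  N v = 0`` with per-reaction bounds."""
    fixed = dict(fixed or {})
    bounds_override = dict(bounds_override or {})
    rxns = net.reactions
    ridx = {r: j for j, r in enumerate(rxns)}
    mets = net.metabolites
    A = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    for rid, stoich in net.stoichiometry.items():
        for met, coeff in stoich.items():
            A[midx[met], ridx[rid]] = float(coeff)
    bounds = []
    for rid in rxns:
        if rid in fixed:
            v = float(fixed[rid])
            bounds.append((v, v))
        elif rid in bounds_override:
            lo, hi = bounds_override[rid]
            bounds.append((max(lo, -FLUX_INF), min(hi, FLUX_INF)))
        elif rid in net.closed:
            bounds.append((0.0, 0.0))
        elif net.reversible.get(rid, False):
            bounds.append((-FLUX_INF, FLUX_INF))
        else:
            bounds.append((0.0, FLUX_INF))
    c = np.zeros(len(rxns))
    for rid, w in objective.items():
        c[ridx[rid]] = w
    if sense == "max":
        c = -c
    res = linprog(c=c, A_eq=A, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
    if res.status == 2:
        return LPResult(objective=None, status="infeasible")
    if res.status == 3:
        return LPResult(objective=None, status="unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    value = float(sum(res.x[ridx[r]] * w for r, w in objective.items()))
    flux = FluxVector(
        fluxes={r: float(res.x[ridx[r]]) for r in rxns},
        fixed=set(fixed),
        unique=False,
    )
    return LPResult(objective=value, status="optimal", fluxes=flux)


def _require_atpm(net: MetabolicNetwork) -> str:
    if net.atpm_reaction is None:
        raise ValueError(
            "network has no ATP-hydrolysis (ATPM) reaction; ATP accounting is undefined"
        )
    return net.atpm_reaction


def max_atp_yield(net: MetabolicNetwork, ecm: ECM) -> float:
    """Maximal ATP per C-mol substrate for a fixed overall conversion.

    Every exchange named in the conversion is pinned to its coefficient, all
    other exchanges are closed, any maintenance lower bound on ATP hydrolysis
    is lifted, and the hydrolysis flux is maximized.
    """
    atpm = _require_atpm(net)
    fixed: dict[str, float] = {}
    for rxn, met in net.exchanges.items():
        fixed[rxn] = float(ecm.stoich[met]) if met in ecm.stoich.coefficients else 0.0
    fixed.pop(atpm, None)
    res = _solve(net, {atpm: 1.0}, "max", fixed=fixed,
                 bounds_override={atpm: (0.0, FLUX_INF)})
    if res.status == "infeasible":
        raise InfeasibleLP(
            f"no steady-state flux realizes the conversion {dict(ecm.stoich.items())}; "
            "it is not a feasible conversion of this network"
        )
    if res.status == "unbounded":
        raise RuntimeError("unbounded ATP yield: the network contains an energy-generating cycle")
    return res.objective


def min_substrate_for_biomass(
    net: MetabolicNetwork, substrate: str, allow_oxygen: bool = True
) -> LPResult:
    """Minimal substrate uptake (C-mol per C-mol biomass) with free ATP.

    The biomass reaction (normalized to 1 C-mol per unit flux) is fixed to 1;
    only the substrate (and optionally oxygen) may be imported, all other
    exchanges may only secrete; ATP hydrolysis is unconstrained so it can run
    in reverse and supply ATP.  The objective value is ``1/Y_sim``.
    """
    if net.biomass_reaction is None:
        raise ValueError("network has no biomass reaction")
    atpm = _require_atpm(net)
    sub_ex = net.exchange_of(substrate)
    overrides: dict[str, tuple[float, float]] = {atpm: (-FLUX_INF, FLUX_INF),
                                                 sub_ex: (-FLUX_INF, 0.0)}
    for rxn, met in net.exchanges.items():
        if rxn == sub_ex:
            continue
        if allow_oxygen and met.lower() in ("o2", "oxygen"):
            overrides[rxn] = (-FLUX_INF, 0.0)
        else:
            overrides[rxn] = (0.0, FLUX_INF)
    res = _solve(net, {sub_ex: 1.0}, "max",
                 fixed={net.biomass_reaction: 1.0}, bounds_override=overrides)
    if res.status != "optimal":
        return res
    carbons = net.carbon_count(substrate)
    if carbons <= 0:
        raise ValueError(f"substrate {substrate!r} has no known carbon content")
    uptake_cmol = abs(res.objective) * carbons
    logger.info("minimal substrate for 1 C-mol biomass: %.4f C-mol (Y_sim = %.4f)",
                uptake_cmol, 1.0 / uptake_cmol if uptake_cmol else float("nan"))
    return LPResult(objective=uptake_cmol, status="optimal", fluxes=res.fluxes)


def min_atp_for_biomass(
    net: MetabolicNetwork,
    substrate: str,
    substrate_flux_cmol: float,
    allow_oxygen: bool = True,
) -> float:
    """Minimal ATP (mol per C-mol biomass) at the minimal substrate uptake.

    ``substrate_flux_cmol`` is the optimum of
    :func:`min_substrate_for_biomass` (positive, C-mol per C-mol biomass);
    it is re-imposed as a fixed import while the reverse flux through ATP
    hydrolysis (ATP supplied to the network) is minimized.
    """
    if net.biomass_reaction is None:
        raise ValueError("network has no biomass reaction")
    atpm = _require_atpm(net)
    sub_ex = net.exchange_of(substrate)
    carbons = net.carbon_count(substrate)
    overrides: dict[str, tuple[float, float]] = {atpm: (-FLUX_INF, FLUX_INF)}
    for rxn, met in net.exchanges.items():
        if rxn == sub_ex:
            continue
        if allow_oxygen and met.lower() in ("o2", "oxygen"):
            overrides[rxn] = (-FLUX_INF, 0.0)
        else:
            overrides[rxn] = (0.0, FLUX_INF)
    res = _solve(
        net,
        {atpm: 1.0},
        "max",
        fixed={net.biomass_reaction: 1.0, sub_ex: -abs(substrate_flux_cmol) / carbons},
        bounds_override=overrides,
    )
    if res.status != "optimal":
        raise InfeasibleLP(
            "ATP minimization infeasible: the fixed substrate uptake does not match "
            "the minimal-substrate optimum of this network"
        )
    return abs(min(res.objective, 0.0))
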