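"""Enumeration of elementary conversion modes (ECMs).

An ECM is an extreme generator of the cone of net conversions of external
compounds that the network can realize at steady state,

.. math:: \\{ c : c = N_{ext} v,\\; N v = 0,\\; v_{irr} \\ge 0 \\},

here restricted to zero-biomass (catabolic) steady states.  The enumeration
is exact: reversible reactions are split, the extreme rays of the lifted flux
cone ``{v >= 0 : A v = 0}`` are computed by the double-description method in
rational arithmetic, projected onto the exchange fluxes, deduplicated up to
positive scaling, and non-extreme conversions are removed by LP membership
tests.  This is deterministic and oracle-verifiable, and is intended for
toy- up to core-scale networks (a few hundred split reactions at most);
genome-scale enumeration is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .network_io import MetabolicNetwork
from .thermo import ConversionStoichiometry, FormationEnergyTable, standard_reaction_energy

__all__ = ["ECM", "enumerate_ecms", "normalize_ecm", "annotate_thermodynamics",
           "extreme_rays", "write_ecm_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ECM:
    """One elementary conversion, normalized per C-mol of its carbon source.

    ``stoich`` holds mol (not C-mol) coefficients per C-mol of the designated
    carbon source; secretion positive.  Annotation fields are filled by
    :func:`annotate_thermodynamics` / :func:`anacat.lp_analyses.max_atp_yield`.
    """

    stoich: ConversionStoichiometry
    carbon_source: str | None = None
    uses_oxygen: bool | None = None
    uses_nitrogen_compounds: bool | None = None
    delta_cat_g_std: float | None = None
    max_atp_yield: float | None = None
    efficiency: float | None = None
    infeasible_forward: bool = False

    def carbon_balance(self, net: MetabolicNetwork) -> float:
        return sum(float(nu) * net.carbon_count(c) for c, nu in self.stoich.items())


# ---------------------------------------------------------------------------
# Double description in exact rational arithmetic
# ---------------------------------------------------------------------------

def extreme_rays(equalities: Sequence[Sequence[Fraction]], n_vars: int,
                 max_rays: int = 200_000) -> list[tuple[Fraction, ...]]:
    """Extreme rays of ``{v >= 0 : A v = 0}`` by double description.

    Starts from the non-negative orthant (rays = unit vectors) and intersects
    with one hyperplane at a time, combining adjacent positive/negative ray
    pairs.  Adjacency uses the combinatorial test on zero sets.  All
    arithmetic is exact, so no spurious or missing rays arise from round-off.
    """
    rays: list[list[Fraction]] = [
        [Fraction(int(i == j)) for j in range(n_vars)] for i in range(n_vars)
    ]
    zero_sets: list[frozenset[int]] = [
        frozenset(j for j in range(n_vars) if j != i) for i in range(n_vars)
    ]
    for row in equalities:
        row = [Fraction(x) for x in row]
        vals = [sum(a * r[j] for j, a in enumerate(row) if a) for r in rays]
        keep = [i for i, s in enumerate(vals) if s == 0]
        plus = [i for i, s in enumerate(vals) if s > 0]
        minus = [i for i, s in enumerate(vals) if s < 0]
        new_rays = [rays[i] for i in keep]
        new_zero = [zero_sets[i] for i in keep]
        for ip in plus:
            for im in minus:
                common = zero_sets[ip] & zero_sets[im]
                # adjacency: no third ray's zero set contains the intersection
                adjacent = True
                for k, z in enumerate(zero_sets):
                    if k != ip and k != im and common <= z:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                sp, sm = vals[ip], vals[im]
                combo = [sp * rays[im][j] - sm * rays[ip][j] for j in range(n_vars)]
                g = _content(combo)
                combo = [x / g for x in combo]
                new_rays.append(combo)
                new_zero.append(frozenset(j for j in range(n_vars) if combo[j] == 0))
        rays, zero_sets = new_rays, new_zero
        if len(rays) > max_rays:
            raise RuntimeError(
                f"double description exceeded {max_rays} intermediate rays; "
                "prune the network (hide_externals) or import precomputed conversions"
            )
    return [tuple(r) for r in rays]


def _content(vec: Iterable[Fraction]) -> Fraction:
    from math import gcd

    nums, dens = [], []
    for x in vec:
        if x:
            nums.append(abs(x.numerator))
            dens.append(x.denominator)
    if not nums:
        return Fraction(1)
    g = 0
    for n in nums:
        g = gcd(g, n)
    l = 1
    for d in dens:
        l = l * d // gcd(l, d)
    return Fraction(g, l)


# ---------------------------------------------------------------------------
# Projection and elementarity
# ---------------------------------------------------------------------------

def _build_split_system(net: MetabolicNetwork, forbid_biomass: bool):
    """Split reversibles and return (equality rows, column spec).

    Columns are (reaction id, sign); closed reactions (and the biomass
    reaction plus its exchange when ``forbid_biomass``) are dropped.
    """
    blocked = set(net.closed)
    if forbid_biomass and net.biomass_reaction is not None:
        blocked.add(net.biomass_reaction)
        for rxn, met in net.exchanges.items():
            if met == "biomass" or rxn.lower() in ("ex_biomass", "ex_x"):
                blocked.add(rxn)
    columns: list[tuple[str, int]] = []
    for rid in net.reactions:
        if rid in blocked:
            continue
        columns.append((rid, +1))
        if net.reversible.get(rid, False):
            columns.append((rid, -1))
    met_index = {m: i for i, m in enumerate(net.metabolites)}
    rows = []
    for met in net.metabolites:
        row = [Fraction(0)] * len(columns)
        any_nonzero = False
        for j, (rid, sign) in enumerate(columns):
            coeff = net.stoichiometry[rid].get(met)
            if coeff:
                row[j] = Fraction(coeff) * sign
                any_nonzero = True
        if any_nonzero:
            rows.append(row)
    return rows, columns


def _project_ray(ray, columns, net: MetabolicNetwork) -> dict[str, Fraction]:
    conv: dict[str, Fraction] = {}
    for x, (rid, sign) in zip(ray, columns):
        if not x or rid not in net.exchanges:
            continue
        met = net.exchanges[rid]
        if met in net.hidden:
            continue
        conv[met] = conv.get(met, Fraction(0)) + sign * x
    return {m: c for m, c in conv.items() if c}


def _canonical(conv: dict[str, Fraction]) -> tuple[tuple[str, Fraction], ...]:
    scale = sum(abs(c) for c in conv.values())
    return tuple(sorted((m, c / scale) for m, c in conv.items()))


def _is_nonneg_combination(target: np.ndarray, generators: np.ndarray, tol: float = 1e-9) -> bool:
    """LP feasibility of ``generators.T @ x = target, x >= 0``."""
    from scipy.optimize import linprog

    if generators.size == 0:
        return bool(np.allclose(target, 0.0, atol=tol))
    res = linprog(
        c=np.zeros(generators.shape[0]),
        A_eq=generators.T,
        b_eq=target,
        bounds=[(0, None)] * generators.shape[0],
        method="highs",
    )
    return bool(res.status == 0)


def enumerate_ecms(
    net: MetabolicNetwork,
    carbon_sources: set[str] | None = None,
    forbid_biomass: bool = True,
    max_rays: int = 200_000,
) -> list[ECM]:
    """All elementary conversion modes of the (prepared) network.

    Returns the minimal generating set of the projected conversion cone,
    each conversion normalized per C-mol of its designated carbon source
    (conversions consuming no carbon source are reported with ``basis="raw"``
    and ``carbon_source=None``).  ``carbon_sources`` restricts which consumed
    compounds may be designated; by default any consumed carbon-containing
    external compound qualifies (ties broken alphabetically, logged).
    """
    rows, columns = _build_split_system(net, forbid_biomass)
    rays = extreme_rays(rows, len(columns), max_rays=max_rays)
    seen: dict[tuple, dict[str, Fraction]] = {}
    for ray in rays:
        conv = _project_ray(ray, columns, net)
        if not conv:
            continue
        seen.setdefault(_canonical(conv), conv)
    convs = [dict(c) for _, c in sorted(seen.items())]

    compounds = sorted({m for c in convs for m in c})
    idx = {m: i for i, m in enumerate(compounds)}
    mat = np.zeros((len(convs), len(compounds)))
    for i, conv in enumerate(convs):
        for m, c in conv.items():
            mat[i, idx[m]] = float(c)
    norms = np.abs(mat).sum(axis=1, keepdims=True)
    mat_n = mat / norms
    # pointedness: a conversion and its negative both feasible would make the
    # minimal generating set ill-defined
    for i in range(len(convs)):
        for j in range(i + 1, len(convs)):
            if np.allclose(mat_n[i], -mat_n[j], atol=1e-12):
                raise ValueError(
                    "conversion cone contains a line (a conversion and its reverse); "
                    "close one direction of the corresponding exchanges before enumerating"
                )
    extreme = []
    for i in range(len(convs)):
        others = np.delete(mat_n, i, axis=0)
        if not _is_nonneg_combination(mat_n[i], others):
            extreme.append(i)

    ecms = []
    for i in extreme:
        conv = convs[i]
        ecm = ECM(stoich=ConversionStoichiometry(
            {m: float(c) for m, c in conv.items()}, basis="raw"))
        source = _designate_source(conv, net, carbon_sources)
        if source is not None:
            ecm = normalize_ecm(ecm, source, net)
        ecms.append(ecm)
    logger.info("enumerated %d elementary conversion modes (%d lifted rays)",
                len(ecms), len(rays))
    return sorted(ecms, key=lambda e: tuple(sorted(e.stoich.items())))


def _designate_source(conv, net, carbon_sources) -> str | None:
    consumed = sorted(
        m for m, c in conv.items()
        if c < 0 and net.carbon_count(m) > 0
        and (carbon_sources is None or m in carbon_sources)
    )
    if not consumed:
        return None
    if len(consumed) > 1:
        logger.info("conversion consumes several carbon sources %s; normalizing by %s",
                    consumed, consumed[0])
    return consumed[0]


def normalize_ecm(ecm: ECM, carbon_source: str, net: MetabolicNetwork) -> ECM:
    """Scale a conversion so the carbon source contributes exactly -1 C-mol."""
    nu = ecm.stoich[carbon_source]
    if not nu < 0:
        raise ValueError(f"conversion does not consume carbon source {carbon_source!r}")
    carbons = net.carbon_count(carbon_source)
    if carbons <= 0:
        raise ValueError(f"{carbon_source!r} has no known carbon content")
    factor = 1.0 / (abs(nu) * carbons)
    return replace(
        ecm,
        stoich=ConversionStoichiometry(
            {m: c * factor for m, c in ecm.stoich.items()},
            basis="per_cmol_substrate",
            label=ecm.stoich.label,
        ),
        carbon_source=carbon_source,
    )


def annotate_thermodynamics(
    ecms: Sequence[ECM], table: FormationEnergyTable, net: MetabolicNetwork
) -> list[ECM]:
    """Attach standard reaction energies and oxygen/nitrogen-use flags.

    Energies are kJ per basis unit (kJ C-mol^-1 for normalized conversions);
    a positive value flags the conversion as thermodynamically infeasible in
    the forward direction.
    """
    out = []
    for ecm in ecms:
        dg = standard_reaction_energy(ecm.stoich, table)
        uses_o2 = any(
            nu < 0 and c.lower() in ("o2", "oxygen") for c, nu in ecm.stoich.items()
        )
        uses_n = any(
            net.compositions.get(c) is not None and net.compositions[c]["N"] > 0
            for c in ecm.stoich.coefficients
        )
        out.append(replace(
            ecm,
            delta_cat_g_std=dg,
            uses_oxygen=uses_o2,
            uses_nitrogen_compounds=uses_n,
            infeasible_forward=dg > 0,
        ))
    return out


def write_ecm_table(ecms: Sequence[ECM], path) -> None:
    """One row per ECM: external-compound coefficients plus annotations."""
    import csv

    compounds = sorted({c for e in ecms for c in e.stoich.coefficients})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            compounds + ["carbon_source", "dfg_kj_per_cmol", "atp_yield", "efficiency",
                         "uses_o2", "uses_n"]
        )
        for e in ecms:
            writer.writerow(
                [f"{e.stoich[c]:.10g}" for c in compounds]
                + [e.carbon_source or "",
                   "" if e.delta_cat_g_std is None else f"{e.delta_cat_g_std:.4f}",
                   "" if e.max_atp_yield is None else f"{e.max_atp_yield:.6f}",
                   "" if e.efficiency is None else f"{e.efficiency:.4f}",
                   "" if e.uses_oxygen is None else int(e.uses_oxygen),
                   "" if e.uses_nitrogen_compounds is None else int(e.uses_nitrogen_compounds)]
            )
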