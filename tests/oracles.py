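"""Independent brute-force oracles used to validate the package.

Deliberately naive implementations that share no code with the package's
enumeration path: elementary flux modes by exhaustive support search over the
split stoichiometric matrix, projection to external conversions, and an LP
elementarity filter.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def split_matrix(net):
    """(A, columns): split reversible reactions so all fluxes are >= 0."""
    columns = []
    for rid in net.reactions:
        if rid in net.closed:
            continue
        columns.append((rid, +1))
        if net.reversible.get(rid, False):
            columns.append((rid, -1))
    A = np.zeros((len(net.metabolites), len(columns)))
    midx = {m: i for i, m in enumerate(net.metabolites)}
    for j, (rid, sign) in enumerate(columns):
        for met, coeff in net.stoichiometry[rid].items():
            A[midx[met], j] = float(coeff) * sign
    return A, columns


def brute_force_efms(net, forbid_biomass=True):
    """All elementary flux modes by exhaustive minimal-support search."""
    blocked = set()
    if forbid_biomass and net.biomass_reaction is not None:
        blocked.add(net.biomass_reaction)
        for rxn, met in net.exchanges.items():
            if met == "biomass" or rxn.lower() in ("ex_biomass", "ex_x"):
                blocked.add(rxn)
    A, columns = split_matrix(net)
    usable = [j for j, (rid, _) in enumerate(columns) if rid not in blocked]
    rank_full = np.linalg.matrix_rank(A) if A.size else 0
    efms = []
    supports: list[frozenset] = []
    max_size = min(len(usable), rank_full + 1)
    for k in range(1, max_size + 1):
        for subset in itertools.combinations(usable, k):
            s = frozenset(subset)
            if any(sup <= s for sup in supports):
                continue
            sub = A[:, subset]
            if np.linalg.matrix_rank(sub) != k - 1:
                continue  # nullity != 1
            _, _, vt = np.linalg.svd(sub)
            v = vt[-1]
            if np.min(np.abs(v)) < 1e-10:
                continue  # support smaller than the subset
            if np.all(v > 0) or np.all(v < 0):
                v = np.abs(v)
                full = np.zeros(len(columns))
                full[list(subset)] = v
                efms.append(full)
                supports.append(s)
    return efms, columns


def project_conversion(flux, columns, net):
    conv: dict[str, float] = {}
    for x, (rid, sign) in zip(flux, columns):
        if rid in net.exchanges and x:
            met = net.exchanges[rid]
            if met in net.hidden:
                continue
            conv[met] = conv.get(met, 0.0) + sign * x
    return {m: c for m, c in conv.items() if abs(c) > 1e-9}


def canonical(conv: dict[str, float], ndigits: int = 9):
    scale = sum(abs(c) for c in conv.values())
    return tuple(sorted((m, round(c / scale, ndigits)) for m, c in conv.items()))


def is_nonneg_combo(target, generators, tol=1e-9):
    if len(generators) == 0:
        return np.allclose(target, 0.0, atol=tol)
    G = np.array(generators)
    res = linprog(np.zeros(len(generators)), A_eq=G.T, b_eq=target,
                  bounds=[(0, None)] * len(generators), method="highs")
    return res.status == 0


def brute_force_conversions(net, forbid_biomass=True):
    """The ECM set: project EFMs, dedupe, drop non-extreme conversions."""
    efms, columns = brute_force_efms(net, forbid_biomass=forbid_biomass)
    seen: dict[tuple, dict[str, float]] = {}
    for flux in efms:
        conv = project_conversion(flux, columns, net)
        if conv:
            seen.setdefault(canonical(conv), conv)
    keys = sorted(seen)
    compounds = sorted({m for c in seen.values() for m in c})
    vecs = []
    for k in keys:
        conv = seen[k]
        scale = sum(abs(c) for c in conv.values())
        vecs.append(np.array([conv.get(m, 0.0) / scale for m in compounds]))
    extreme = []
    for i, k in enumerate(keys):
        others = [v for j, v in enumerate(vecs) if j != i]
        if not is_nonneg_combo(vecs[i], others):
            extreme.append(seen[k])
    return extreme


def combustion_oxygen_demand(comp) -> float:
    """Electron-balance oracle: O2 per C-mol for combustion to CO2/H2O/NH3.

    Solves the element balances of ``CHhOoNn + a O2 -> CO2 + w H2O + n NH3``
    directly; ``4 a`` is then an independent value for the degree of
    reduction.
    """
    h, o, n = comp["H"], comp["O"], comp["N"]
    w = (h - 3.0 * n) / 2.0          # hydrogen balance
    a = (2.0 + w - o) / 2.0          # oxygen balance
    return a
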