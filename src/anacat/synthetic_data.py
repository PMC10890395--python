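"""Ground-truth generators: toy networks and chemostat series.

Every input the pipeline consumes can be generated here with its exact truth
attached: small metabolic networks whose conversion modes, ATP yields and LP
optima are known by construction (and re-verifiable by brute force), and
steady-state chemostat series built from an ideal anabolic equation plus a
respiration/fermentation mixture with a configurable overflow switch at a
critical dilution rate, optional Gaussian measurement noise and an
unmeasured-carbon fraction.  Zero-noise series are exactly carbon-, redox-
and water-balanced, so the analysis pipeline must invert them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .composition import (
    ElementalComposition,
    degree_of_reduction,
    ideal_anabolic_stoichiometry,
    parse_formula,
)
from .chemostat_split import DEFAULT_COMPOUNDS, ChemostatRecord
from .network_io import MetabolicNetwork
from .thermo import ConversionStoichiometry

__all__ = ["make_toy_network", "TOY_KINDS", "ChemostatSimSpec", "simulate_chemostat",
           "simulate_linear_converter", "write_truth_json",
           "respiration_mode", "ethanol_fermentation_mode", "acetate_overflow_mode"]

F = Fraction


def _net(reactions, reversible, exchanges, compositions, biomass=None, atpm=None):
    mets = sorted({m for st in reactions.values() for m in st})
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=list(reactions),
        stoichiometry={r: dict(s) for r, s in reactions.items()},
        reversible=dict(reversible),
        exchanges=dict(exchanges),
        biomass_reaction=biomass,
        atpm_reaction=atpm,
        compositions={c: parse_formula(f, label=c) for c, f in compositions.items()},
    )
    net.validate()
    return net


def _chain_toy():
    reactions = {
        "EX_s": {"s": F(-1)}, "EX_p": {"p": F(-1)},
        "R1": {"s": F(-1), "a": F(1)}, "R2": {"a": F(-1), "p": F(1)},
    }
    net = _net(reactions,
               {"EX_s": True, "EX_p": True, "R1": False, "R2": False},
               {"EX_s": "s", "EX_p": "p"},
               {"s": "CH2O", "p": "CH2O"})
    truth = {
        "ecms": [{"s": -1.0, "p": 1.0}],
        "atp_yields": {},
        "description": "linear chain: exactly one conversion -1 S -> +1 P, no ATP",
    }
    return net, truth


def _ferm_resp_toy():
    """Glucose catabolism with four fates of pyruvate.

    Respiration (26 ATP/glucose via 12 reducing equivalents at P/O = 2 plus 2
    substrate-level ATP), ethanol and lactate fermentation (2 ATP/glucose),
    and aerobic acetate overflow (12 ATP/glucose).  Exactly four elementary
    conversions with ATP yields 26/6, 2/6, 2/6 and 12/6 mol per C-mol.
    """
    reactions = {
        "EX_glc": {"glc": F(-1)}, "EX_o2": {"o2": F(-1)}, "EX_co2": {"co2": F(-1)},
        "EX_etoh": {"etoh": F(-1)}, "EX_lac": {"lac": F(-1)}, "EX_ac": {"ac": F(-1)},
        "EX_h2o": {"h2o": F(-1)},
        "GLYC": {"glc": F(-1), "adp": F(-2), "pi": F(-2), "nad": F(-2),
                 "pyr": F(2), "atp": F(2), "nadh": F(2)},
        "TCA": {"pyr": F(-1), "h2o": F(-3), "nad": F(-5), "co2": F(3), "nadh": F(5)},
        "OX": {"nadh": F(-1), "o2": F(-1, 2), "adp": F(-2), "pi": F(-2),
               "nad": F(1), "h2o": F(1), "atp": F(2)},
        "FERM": {"pyr": F(-1), "nadh": F(-1), "etoh": F(1), "co2": F(1), "nad": F(1)},
        "LACF": {"pyr": F(-1), "nadh": F(-1), "lac": F(1), "nad": F(1)},
        "ACEF": {"pyr": F(-1), "h2o": F(-1), "nad": F(-1), "adp": F(-1), "pi": F(-1),
                 "ac": F(1), "co2": F(1), "nadh": F(1), "atp": F(1)},
        "ATPM": {"atp": F(-1), "adp": F(1), "pi": F(1)},
    }
    reversible = {r: False for r in reactions}
    reversible.update({"EX_glc": True, "EX_o2": True, "EX_co2": True, "EX_h2o": True})
    net = _net(
        reactions, reversible,
        {r: next(iter(reactions[r])) for r in reactions if r.startswith("EX_")},
        {"glc": "C6H12O6", "o2": "O2", "co2": "CO2", "etoh": "C2H6O",
         "lac": "C3H6O3", "ac": "C2H4O2", "h2o": "H2O"},
        atpm="ATPM",
    )
    sixth = 1.0 / 6.0
    truth = {
        "ecms": [
            {"glc": -sixth, "o2": -1.0, "co2": 1.0, "h2o": 1.0},                     # respiration
            {"glc": -sixth, "etoh": 1.0 / 3.0, "co2": 1.0 / 3.0},                     # ethanol
            {"glc": -sixth, "lac": 1.0 / 3.0},                                        # lactate
            {"glc": -sixth, "o2": -1.0 / 3.0, "ac": 1.0 / 3.0, "co2": 1.0 / 3.0,
             "h2o": 1.0 / 3.0},                                                       # acetate
        ],
        "atp_yields": {"respiration": 26.0 / 6.0, "ethanol": 2.0 / 6.0,
                       "lactate": 2.0 / 6.0, "acetate": 12.0 / 6.0},
        "description": "glucose catabolism toy: 4 elementary conversions",
    }
    return net, truth


def _biomass_toy():
    """Substrate polymerization into biomass at 2 ATP per C-mol, no redox change."""
    reactions = {
        "EX_glc": {"glc": F(-1)}, "EX_x": {"x": F(-1)},
        "UPT": {"glc": F(-1), "prec": F(6)},
        "BIO": {"prec": F(-1), "atp": F(-2), "x": F(1), "adp": F(2), "pi": F(2)},
        "ATPM": {"atp": F(-1), "adp": F(1), "pi": F(1)},
    }
    net = _net(reactions,
               {"EX_glc": True, "EX_x": False, "UPT": False, "BIO": False, "ATPM": False},
               {"EX_glc": "glc", "EX_x": "x"},
               {"glc": "C6H12O6", "prec": "CH2O"},
               biomass="BIO", atpm="ATPM")
    truth = {
        "ecms": [],
        "min_substrate_cmol": 1.0,
        "min_atp": 2.0,
        "y_sim": 1.0,
        "description": "biomass toy: gamma_S = gamma_X, Y = 1, a_ATP = 2",
    }
    return net, truth


def _parallel_toy():
    reactions = {
        "EX_s": {"s": F(-1)}, "EX_p": {"p": F(-1)},
        "R1": {"s": F(-1), "a": F(1)}, "R2": {"a": F(-1), "p": F(1)},
        "R3": {"s": F(-1), "b": F(1)}, "R4": {"b": F(-1), "p": F(1)},
    }
    net = _net(reactions,
               {r: r == "EX_s" or r == "EX_p" for r in reactions},
               {"EX_s": "s", "EX_p": "p"},
               {"s": "CH2O", "p": "CH2O"})
    truth = {
        "ecms": [{"s": -1.0, "p": 1.0}],
        "atp_yields": {},
        "description": "two parallel routes collapse to one conversion",
    }
    return net, truth


def _two_substrate_toy():
    reactions = {
        "EX_s1": {"s1": F(-1)}, "EX_s2": {"s2": F(-1)}, "EX_p": {"p": F(-1)},
        "R1": {"s1": F(-1), "p": F(1)}, "R2": {"s2": F(-1), "p": F(2)},
    }
    net = _net(reactions,
               {"EX_s1": True, "EX_s2": True, "EX_p": False, "R1": False, "R2": False},
               {"EX_s1": "s1", "EX_s2": "s2", "EX_p": "p"},
               {"s1": "CH2O", "s2": "C2H4O2", "p": "CH2O"})
    truth = {
        "ecms": [{"s1": -1.0, "p": 1.0}, {"s2": -0.5, "p": 1.0}],
        "atp_yields": {},
        "description": "two independent substrates, one conversion each (per C-mol)",
    }
    return net, truth


TOY_KINDS = {
    "chain": _chain_toy,
    "fermentation-respiration": _ferm_resp_toy,
    "biomass-toy": _biomass_toy,
    "parallel": _parallel_toy,
    "two-substrate": _two_substrate_toy,
}


def make_toy_network(kind: str) -> tuple[MetabolicNetwork, dict]:
    """A toy network plus the exact truth it was constructed to have.

    ``truth["ecms"]`` lists the elementary conversions normalized per C-mol
    of carbon source; further keys depend on the kind (ATP yields, LP
    optima).  Kinds: chain, fermentation-respiration, biomass-toy, parallel,
    two-substrate.
    """
    if kind not in TOY_KINDS:
        raise ValueError(f"unknown toy kind {kind!r}; choose from {sorted(TOY_KINDS)}")
    return TOY_KINDS[kind]()


# ---------------------------------------------------------------------------
# Catabolic modes (per C-mol substrate, mol coefficients, secretion positive)
# ---------------------------------------------------------------------------

def respiration_mode(substrate: ElementalComposition, substrate_id: str = "glc") -> ConversionStoichiometry:
    """Full combustion of a CHxOy substrate: O2 demand = gamma/4 per C-mol."""
    sub = substrate.normalize_per_cmol() if not substrate.is_cmol_normalized else substrate
    gamma = degree_of_reduction(sub)
    return ConversionStoichiometry(
        {substrate_id: -1.0 / substrate["C"] if substrate["C"] > 1 else -1.0,
         "o2": -gamma / 4.0, "co2": 1.0, "h2o": sub["H"] / 2.0},
        basis="per_cmol_substrate", label="respiration",
    )


def ethanol_fermentation_mode() -> ConversionStoichiometry:
    """Glucose -> 2 ethanol + 2 CO2, per C-mol glucose."""
    return ConversionStoichiometry(
        {"glc": -1.0 / 6.0, "etoh": 1.0 / 3.0, "co2": 1.0 / 3.0},
        basis="per_cmol_substrate", label="ethanol fermentation",
    )


def acetate_overflow_mode() -> ConversionStoichiometry:
    """Glucose + 2 O2 -> 2 acetate + 2 CO2 + 2 H2O, per C-mol glucose."""
    return ConversionStoichiometry(
        {"glc": -1.0 / 6.0, "o2": -1.0 / 3.0, "ac": 1.0 / 3.0, "co2": 1.0 / 3.0,
         "h2o": 1.0 / 3.0},
        basis="per_cmol_substrate", label="acetate overflow",
    )


@dataclass
class ChemostatSimSpec:
    """Study conditions for a simulated chemostat series.

    The overflow switch turns on fermentation above ``D_crit`` (around
    0.3/h for baker's yeast and 0.4/h for E. coli); below it catabolism is
    pure respiration and the biomass yield ``alpha2`` is constant at
    ``yield_low``, above it the yield declines linearly with slope
    ``yield_slope`` and the fermentation fraction of catabolized substrate
    rises as ``phi_slope * (D - D_crit)`` (capped at 1).  ``noise_sd`` is the
    relative standard deviation of multiplicative Gaussian noise on every
    measured rate; ``unmeasured_carbon_fraction`` diverts that share of
    substrate carbon into a product the measurements miss.
    """

    D_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.4501, 0.025), 4))
    D_crit: float = 0.3
    substrate: str = "glc"
    product: str = "etoh"
    biomass_formula: str = "CH1.79O0.57N0.15"
    biomass_cmol_mass: float | None = None
    respiration: ConversionStoichiometry | None = None
    fermentation: ConversionStoichiometry | None = None
    atp_yield_respiration: float = 26.0 / 6.0
    atp_yield_fermentation: float = 2.0 / 6.0
    yield_low: float = 0.55
    yield_slope: float = 2.5
    phi_slope: float = 4.0
    noise_sd: float = 0.0
    unmeasured_carbon_fraction: float = 0.0
    seed: int = 0

    @classmethod
    def yeast(cls, **kw) -> "ChemostatSimSpec":
        return cls(**kw)

    @classmethod
    def ecoli(cls, **kw) -> "ChemostatSimSpec":
        defaults = dict(
            D_grid=tuple(np.round(np.arange(0.05, 0.6501, 0.04), 4)),
            D_crit=0.4,
            product="ac",
            biomass_formula="CH1.77O0.49N0.24",
            biomass_cmol_mass=26.11,
            fermentation=acetate_overflow_mode(),
            atp_yield_fermentation=12.0 / 6.0,
        )
        defaults.update(kw)
        return cls(**defaults)

    def phi(self, D: float) -> float:
        if D <= self.D_crit:
            return 0.0
        return min(1.0, self.phi_slope * (D - self.D_crit))

    def alpha2(self, D: float) -> float:
        if D <= self.D_crit:
            return self.yield_low
        return max(0.05, self.yield_low - self.yield_slope * (D - self.D_crit))


def _mode_balance_residuals(mode: ConversionStoichiometry, compounds) -> dict[str, float]:
    res = {"C": 0.0, "H": 0.0, "O": 0.0}
    for cid, nu in mode.items():
        comp = compounds[cid]
        for el in res:
            res[el] += nu * comp[el]
    return res


def simulate_chemostat(spec: ChemostatSimSpec) -> tuple[list[ChemostatRecord], list[dict]]:
    """Generate one record per dilution rate plus the hidden truth.

    Per D the macrochemical equation is assembled as ``alpha2 * anabolism +
    (1 - alpha2 b1) * [(1 - phi) respiration + phi fermentation]`` and turned
    into specific exchange rates (q = alpha * D / alpha2).  Truth entries
    carry phi, the exact alphas and the exact normalized catabolic mode.
    """
    rng = np.random.default_rng(spec.seed)
    substrate_mol = DEFAULT_COMPOUNDS[spec.substrate]
    sub = substrate_mol.normalize_per_cmol()
    biomass = parse_formula(spec.biomass_formula, label="biomass")
    if not biomass.is_cmol_normalized:
        biomass = biomass.normalize_per_cmol()
    ana = ideal_anabolic_stoichiometry(sub, biomass)
    resp = spec.respiration or respiration_mode(substrate_mol, spec.substrate)
    ferm = spec.fermentation or ethanol_fermentation_mode()
    for name, mode in (("respiration", resp), ("fermentation", ferm)):
        res = _mode_balance_residuals(mode, DEFAULT_COMPOUNDS)
        if any(abs(v) > 1e-9 for v in res.values()):
            raise ValueError(f"{name} mode is not elementally balanced: residuals {res}")
    prod_carbons = DEFAULT_COMPOUNDS[spec.product]["C"]

    records, truths = [], []
    for D in spec.D_grid:
        a2 = spec.alpha2(D)
        phi = spec.phi(D)
        if a2 * ana.b1 >= 1.0:
            raise ValueError(
                f"yield alpha2 = {a2:.3f} at D = {D} exceeds the theoretical maximum "
                f"{ana.y_max:.3f}; lower yield_low"
            )
        f_cat = 1.0 - a2 * ana.b1
        mix = {c: (1.0 - phi) * resp[c] + phi * ferm[c]
               for c in set(resp.coefficients) | set(ferm.coefficients)}
        alpha1 = -f_cat * mix.get("o2", 0.0)
        alpha3 = f_cat * mix.get(spec.product, 0.0) * prod_carbons
        alpha4 = a2 * ana.b3 + f_cat * mix.get("co2", 0.0)
        alpha5 = a2 * ana.b4 + f_cat * mix.get("h2o", 0.0)
        alpha4_measured = alpha4 - spec.unmeasured_carbon_fraction

        q_s = D / a2
        noisy = lambda v: v * (1.0 + spec.noise_sd * rng.standard_normal()) if spec.noise_sd else v
        values = {
            "substrate": noisy(q_s),
            "o2": noisy(alpha1 * q_s),
            "co2": noisy(alpha4_measured * q_s),
            "product": noisy(alpha3 * q_s),
            "biomass": None,  # alpha2 follows from D / q_substrate
        }
        units = {k: "specific_cmol" for k in values if values[k] is not None}
        records.append(ChemostatRecord(
            D=float(D), values=values, units=units,
            substrate=spec.substrate, product=spec.product,
            biomass_composition=biomass,
            biomass_cmol_mass=spec.biomass_cmol_mass,
            meta={"seed": spec.seed},
        ))
        cat_norm = ConversionStoichiometry(
            {c: v for c, v in mix.items()}, basis="per_cmol_substrate",
            label="true catabolic mode",
        )
        truths.append({
            "D": float(D), "phi": phi, "alpha1": alpha1, "alpha2": a2,
            "alpha3": alpha3, "alpha4": alpha4, "alpha5": alpha5,
            "f_cat": f_cat,
            "c_atp": (1.0 - phi) * spec.atp_yield_respiration + phi * spec.atp_yield_fermentation,
            "catabolic": dict(cat_norm.items()),
        })
    return records, truths


def simulate_linear_converter(
    L: np.ndarray,
    forces: Sequence[tuple[float, float]],
):
    """Converter points that satisfy J = L X exactly (ground truth for fits)."""
    from .chemostat_split import ConverterPoint

    L = np.asarray(L, dtype=float)
    points = []
    for fcat, fana in forces:
        j = L @ np.array([fcat, fana])
        dcat, dana = -fcat, -fana
        points.append(ConverterPoint(
            D=float(j[1]), j_cat=float(j[0]), j_ana=float(j[1]),
            delta_cat_g=dcat, delta_ana_g=dana,
            force_ratio=dcat / dana,
            p_cat=float(-j[0] * dcat), p_ana=float(-j[1] * dana),
        ))
    return points


def write_truth_json(truths: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(truths, fh, indent=1, default=float)
        fh.write("\n")
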