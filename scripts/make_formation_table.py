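"""Regenerate the vendored transformed formation-energy table.

Writes ``src/anacat/data/formation_energies.tsv`` (+ conditions sidecar) with
transformed standard Gibbs energies of formation at 298.15 K, pH 7.4, pMg 3.0,
I = 0.25 M for the compounds the pipeline needs.  Chemical-standard aqueous
species energies (kJ/mol at I = 0) are taken from Alberty's compilation
(Thermodynamics of Biochemical Reactions, 2003) and Legendre-transformed per
species, then protonation states are merged as pseudoisomers.  Mg-bound
species of ATP/ADP are not included (pMg enters only through the conditions
record); the affected entries are tagged in the source column.

Run from the repository root::

    python scripts/make_formation_table.py
"""

from __future__ import annotations

import json
import pathlib

from anacat.thermo import ThermoConditions, legendre_transform, pseudoisomer_energy

CONDITIONS = ThermoConditions(temperature=298.15, pH=7.4, pMg=3.0, ionic_strength=0.25)

# compound_id -> (name, [(dfG_chemical kJ/mol, N_H, charge), ...], source tag)
SPECIES: dict[str, tuple[str, list[tuple[float, float, float]], str]] = {
    "glc": ("D-glucose", [(-915.90, 12, 0)], "alberty2003"),
    "xyl": ("D-xylose", [(-750.49, 10, 0)], "alberty2003"),
    "pyr": ("pyruvate", [(-472.27, 3, -1)], "alberty2003"),
    "akg": ("2-oxoglutarate", [(-793.41, 4, -2)], "alberty2003"),
    "o2": ("O2 (aq)", [(16.40, 0, 0)], "alberty2003"),
    "co2": ("CO2 (aq)", [(-385.99, 0, 0)], "alberty2003"),
    "h2o": ("H2O", [(-237.19, 2, 0)], "alberty2003"),
    "nh3": ("ammonia (NH4+/NH3)", [(-79.31, 4, 1), (-26.50, 3, 0)], "alberty2003"),
    "etoh": ("ethanol", [(-181.64, 6, 0)], "alberty2003"),
    "ac": ("acetate (acetate-/acetic acid)", [(-369.31, 3, -1), (-396.45, 4, 0)], "alberty2003"),
    "lac": ("L-lactate", [(-516.72, 5, -1)], "alberty2003"),
    "for": ("formate", [(-351.04, 1, -1)], "alberty2003"),
    "pi": ("phosphate (HPO4 2-/H2PO4 -)", [(-1096.10, 1, -2), (-1137.30, 2, -1)], "alberty2003"),
    "so4": ("sulfate", [(-744.53, 0, -2)], "alberty2003"),
    "atp": ("ATP (ATP 4-/HATP 3-)", [(-2768.10, 12, -4), (-2811.48, 13, -3)], "alberty2003;no-Mg-species"),
    "adp": ("ADP (ADP 3-/HADP 2-)", [(-1906.13, 12, -3), (-1947.10, 13, -2)], "alberty2003;no-Mg-species"),
}


def build_rows() -> list[tuple[str, str, float, str]]:
    rows = []
    for cid, (name, species, source) in SPECIES.items():
        g = pseudoisomer_energy(
            (legendre_transform(dfg, n_h, z, CONDITIONS) for dfg, n_h, z in species),
            CONDITIONS,
        )
        rows.append((cid, name, g, source))
    return rows


def main() -> None:
    out_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "anacat" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "formation_energies.tsv"
    with open(tsv, "w") as fh:
        fh.write("compound_id\tname\tdfg_prime_kj_mol\tsource\n")
        for cid, name, g, source in build_rows():
            fh.write(f"{cid}\t{name}\t{g:.4f}\t{source}\n")
    with open(out_dir / "formation_energies.conditions.json", "w") as fh:
        json.dump(
            {
                "temperature": CONDITIONS.temperature,
                "pH": CONDITIONS.pH,
                "pMg": CONDITIONS.pMg,
                "ionic_strength": CONDITIONS.ionic_strength,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    print(f"wrote {tsv}")


if __name__ == "__main__":
    main()
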