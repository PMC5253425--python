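"""Plain-text formats: pedigree/roster CSV, genotype CSV, COLONY interop.

All writers are deterministic (fixed column order, fixed float formatting) so
that write -> read -> write round-trips byte-identically.
"""
from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, Pedigree


def write_pedigree(pedigree: Pedigree, offspring_path, roster_path) -> None:
    rows = [
        {"offspring_id": oid, "sire_id": s, "dam_id": d}
        for oid, (s, d) in pedigree.offspring.items()
    ]
    pd.DataFrame(rows, columns=["offspring_id", "sire_id", "dam_id"]).to_csv(
        offspring_path, index=False
    )
    roster = [{"parent_id": p, "sex": sex} for p, sex in pedigree.parents.items()]
    pd.DataFrame(roster, columns=["parent_id", "sex"]).to_csv(roster_path, index=False)


def read_pedigree(offspring_path, roster_path) -> Pedigree:
    off = pd.read_csv(offspring_path, dtype=str)
    roster = pd.read_csv(roster_path, dtype=str)
    parents = dict(zip(roster["parent_id"], roster["sex"]))
    offspring = {
        r.offspring_id: (r.sire_id, r.dam_id) for r in off.itertuples(index=False)
    }
    crosses = sorted({((s,), (d,)) for s, d in offspring.values()})
    ped = Pedigree(parents=parents, crosses=list(crosses), offspring=offspring)
    ped.validate()
    return ped


def write_genotypes(genotypes: GenotypeTable, path) -> None:
    df = pd.DataFrame(genotypes.codes.astype(object), columns=genotypes.loci)
    df = df.mask(df == MISSING, "NA")
    df.insert(0, "individual_id", genotypes.ids)
    df.to_csv(path, index=False)


def read_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, na_values=["NA"])
    df.columns = ["individual_id"] + [str(c) for c in df.columns[1:]]
    return GenotypeTable.from_frame(df)


def write_colony_genotypes(genotypes: GenotypeTable, path) -> None:
    """COLONY-style offspring genotype file: two columns per locus, alleles
    coded 1/2, 0 for missing."""
    allele_pairs = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), MISSING: ("0", "0")}
    with open(path, "w") as fh:
        for i, oid in enumerate(genotypes.ids):
            fields = [oid]
            for g in genotypes.codes[i].tolist():
                fields.extend(allele_pairs[g])
            fh.write(" ".join(fields) + "\n")


def write_truth_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def jsonable(value):
    """Replace inf/nan with strings so json round-trips cleanly."""
    if isinstance(value, dict):
        return {k: jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [jsonable(v) for v in value]
    if isinstance(value, (np.floating, float)):
        f = float(value)
        if math.isinf(f):
            return "inf"
        if math.isnan(f):
            return "NA"
        return f
    if isinstance(value, np.integer):
        return int(value)
    return value
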