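"""Readers and writers for decomposition artifacts.

All artifacts are plain text: a barriers-style minima table, a directed
transitions CSV, a per-basin memory CSV, a barrier-tree JSON and a run
metadata JSON. A complete machine-readable model JSON allows exact
round-tripping of a :class:`~basinflood.global_flood.MacroModel`. Floats
are serialized with 12 significant digits throughout.
"""

from __future__ import annotations

import hashlib
import json
import math

import pandas as pd

from .global_flood import Basin, BarrierTree, MacroModel
from .rna_model import RnaSequence

__all__ = [
    "write_minima_table", "read_minima_table",
    "write_transitions_csv", "read_transitions_csv",
    "write_memory_csv",
    "model_to_json", "write_model_json", "read_model_json",
    "write_tree_json", "read_tree_json",
    "write_metadata", "read_metadata", "config_hash",
    "write_basin_csv",
    "read_fasta", "write_fasta",
]


def _fmt(x: float) -> str:
    return format(x, ".12g")


def write_minima_table(model: MacroModel, path, energy_fmt: str = "%.4f") -> None:
    """Barriers-like text table: ``index structure energy basin_size Z degree``.

    Index is 1-based in the total order of minima. Use ``energy_fmt="%.2f"``
    for nearest-neighbor (kcal/mol) energies.
    """
    with open(path, "w") as fh:
        fh.write("index structure energy basin_size Z degree\n")
        for i, b in enumerate(model.basins, start=1):
            fh.write(
                f"{i} {b.minimum} {energy_fmt % b.e_min} {b.size} "
                f"{_fmt(b.Z)} {model.degree(b.minimum)}\n"
            )


def read_minima_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")


def write_transitions_csv(model: MacroModel, path) -> None:
    """Directed CSV ``from_index,to_index,Z_trans,q`` — both rows per pair."""
    idx = {m: i + 1 for i, m in enumerate(model.minima)}
    Z = {b.minimum: b.Z for b in model.basins}
    rows = []
    for (a, b), z in model.transitions.items():
        rows.append((idx[a], idx[b], z, z / Z[a]))
        rows.append((idx[b], idx[a], z, z / Z[b]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("from_index,to_index,Z_trans,q\n")
        for fa, ta, z, q in rows:
            fh.write(f"{fa},{ta},{_fmt(z)},{_fmt(q)}\n")


def read_transitions_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_memory_csv(flood_results, model: MacroModel, path) -> None:
    """Per-basin memory accounting: ``index,members,contacts,mem_ratio``."""
    idx = {m: i + 1 for i, m in enumerate(model.minima)}
    total = model.total_states
    with open(path, "w") as fh:
        fh.write("index,members,contacts,mem_ratio\n")
        for m in model.minima:
            r = flood_results[m]
            fh.write(
                f"{idx[m]},{r.members_count},{r.contacts_count},"
                f"{_fmt(r.mem_local / total)}\n"
            )


def write_basin_csv(report, path) -> None:
    """Per-basin stats CSV: ``index,structure,e_min,e_max,size,Z,degree,mem_ratio``."""
    t = report.table
    with open(path, "w") as fh:
        fh.write("index,structure,e_min,e_max,size,Z,degree,mem_ratio\n")
        for i, row in enumerate(t.itertuples(index=False), start=1):
            mr = "" if (isinstance(row.mem_ratio, float) and math.isnan(row.mem_ratio)) \
                else _fmt(row.mem_ratio)
            fh.write(
                f"{i},{row.minimum},{_fmt(row.e_min)},{_fmt(row.e_max)},"
                f"{row.size},{_fmt(row.Z)},{row.degree},{mr}\n"
            )


# -- model / tree JSON -------------------------------------------------------

def model_to_json(model: MacroModel) -> str:
    obj = {
        "delta": model.delta,
        "beta": float(_fmt(model.beta)),
        "total_states": model.total_states,
        "basins": [
            {"minimum": str(b.minimum), "size": b.size,
             "Z": float(_fmt(b.Z)),
             "e_min": float(_fmt(b.e_min)), "e_max": float(_fmt(b.e_max))}
            for b in model.basins
        ],
        "transitions": [
            [str(a), str(b), float(_fmt(z))]
            for (a, b), z in sorted(
                model.transitions.items(),
                key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
            )
        ],
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def write_model_json(model: MacroModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))
        fh.write("\n")


def read_model_json(path) -> MacroModel:
    with open(path) as fh:
        obj = json.load(fh)
    basins = [
        Basin(minimum=d["minimum"], size=d["size"], Z=d["Z"],
              e_min=d["e_min"], e_max=d["e_max"])
        for d in obj["basins"]
    ]
    pos = {b.minimum: i for i, b in enumerate(basins)}
    transitions = {}
    for a, b, z in obj["transitions"]:
        key = (a, b) if pos[a] < pos[b] else (b, a)
        transitions[key] = z
    return MacroModel(
        basins=basins, transitions=transitions, delta=obj["delta"],
        beta=obj["beta"], total_states=obj["total_states"],
    )


def write_tree_json(tree: BarrierTree, path) -> None:
    obj = {
        "minima": [str(m) for m in tree.minima],
        "energies": {str(m): float(_fmt(e)) for m, e in tree.energies.items()},
        "merge_events": [
            [float(_fmt(e)), str(a), str(b)] for e, a, b in tree.merge_events
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tree_json(path) -> BarrierTree:
    with open(path) as fh:
        obj = json.load(fh)
    return BarrierTree(
        minima=obj["minima"],
        energies=obj["energies"],
        merge_events=[(e, a, b) for e, a, b in obj["merge_events"]],
    )


# -- run metadata ------------------------------------------------------------

def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_metadata(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- FASTA -------------------------------------------------------------------

def read_fasta(path, all_records: bool = False) -> list:
    """Sequences from a FASTA file; by default only the first record."""
    from Bio import SeqIO

    seqs = [RnaSequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs if all_records else seqs[:1]


def write_fasta(seqs, path, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, start=1):
            fh.write(f">{prefix}{i}\n{s}\n")
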