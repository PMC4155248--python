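"""Gradient-basin property analyses: sizes, energy ranges, connectivity.

Summaries follow the questions one asks of a decomposed folding landscape:
how large are basins and how does size relate to the depth of their
minimum, how sparse is the basin adjacency relative to all possible pairs,
how special is the basin of the open (unfolded) chain, and how much memory
does per-basin local flooding need relative to global enumeration.
Energies are also reported on the relative scale
e_rel(x) = (E(x) − E_min) / (E_max − E_min) over the whole landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["BasinReport", "basin_report", "summary_statistics"]


@dataclass
class BasinReport:
    """Per-basin table plus landscape-level aggregates.

    ``table`` columns: minimum, e_min, e_max, size, Z, degree, mem_ratio
    (NaN when local flooding was not run), e_rel_min, e_rel_max.
    """

    table: pd.DataFrame
    E_min: float
    E_max: float
    total_states: int
    n_basins: int
    open_basin: object = None      # minimum of the basin holding the open chain
    open_share: float = float("nan")
    degenerate_energy_range: bool = False
    meta: dict = field(default_factory=dict)


def basin_report(model, L, flood_results=None) -> BasinReport:
    """Assemble the per-basin property table for a full decomposition."""
    E_min = min(b.e_min for b in model.basins)
    E_max = max(b.e_max for b in model.basins)
    span = E_max - E_min
    degenerate = span == 0

    def e_rel(e):
        return float("nan") if degenerate else (e - E_min) / span

    mem = {}
    if flood_results:
        for m, r in flood_results.items():
            mem[m] = r.mem_local / model.total_states
    rows = []
    for b in model.basins:
        rows.append({
            "minimum": str(b.minimum),
            "e_min": b.e_min,
            "e_max": b.e_max,
            "size": b.size,
            "Z": b.Z,
            "degree": model.degree(b.minimum),
            "mem_ratio": mem.get(b.minimum, float("nan")),
            "e_rel_min": e_rel(b.e_min),
            "e_rel_max": e_rel(b.e_max),
        })
    open_basin = None
    open_share = float("nan")
    start = getattr(L, "open_chain", None)
    if start is not None:
        open_basin = L.assign(start)
        open_share = model.basin(open_basin).size / model.total_states
    return BasinReport(
        table=pd.DataFrame(rows),
        E_min=E_min, E_max=E_max,
        total_states=model.total_states,
        n_basins=len(model.basins),
        open_basin=open_basin,
        open_share=open_share,
        degenerate_energy_range=degenerate,
        meta=dict(model.meta),
    )


def _spearman_or_nan(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) < 2 or np.all(u == u[0]) or np.all(v == v[0]):
        return float("nan")
    return float(scipy.stats.spearmanr(u, v).statistic)


def summary_statistics(report: BasinReport, model) -> dict:
    """Landscape-level numbers: sparsity, correlations, connectivity shares.

    Correlations on degenerate inputs (fewer than two basins, or zero
    variance) are reported as NaN rather than raised.
    """
    t = report.table
    nb = report.n_basins
    possible_pairs = nb * (nb - 1) // 2
    realized = len(model.transitions)
    out = {
        "n_basins": nb,
        "total_states": report.total_states,
        "n_transitions": realized,
        "realized_transition_fraction": (
            realized / possible_pairs if possible_pairs else 0.0
        ),
        "spearman_size_emin": _spearman_or_nan(t["size"], t["e_min"]),
        "spearman_degree_size": _spearman_or_nan(t["degree"], t["size"]),
        "spearman_degree_emin": _spearman_or_nan(t["degree"], t["e_min"]),
        "fraction_negative_minima": float((t["e_min"] < 0).mean()),
        "fraction_degree_lt_10": float((t["degree"] < 10).mean()),
        "fraction_degree_lt_2pct": float((t["degree"] < 0.02 * nb).mean()),
        "open_basin_share_of_states": report.open_share,
    }
    if report.open_basin is not None and nb > 1:
        out["open_basin_degree_share"] = model.degree(report.open_basin) / (nb - 1)
    else:
        out["open_basin_degree_share"] = float("nan")
    mem = t["mem_ratio"].dropna()
    if len(mem):
        out["mem_ratio_mean"] = float(mem.mean())
        out["mem_ratio_median"] = float(mem.median())
    else:
        out["mem_ratio_mean"] = out["mem_ratio_median"] = float("nan")
    for k, v in out.items():
        if isinstance(v, float) and math.isnan(v):
            out[k] = v  # keep NaN markers explicit
    return out
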