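"""Exhaustive gradient-basin decomposition by global enumeration.

Two routes to the same macro-state model:

* :func:`brute_force_macromodel` — enumerate X, gradient-walk every state,
  accumulate basin partition functions Z_b and transition-state partition
  functions Z{b,c}; the simplest possible oracle.
* :func:`barriers_flood` — process states in ascending (energy, encoding)
  order; each non-minimum state inherits the basin of its steepest-descent
  neighbor by a hash lookup, and states adjacent to several previously
  disconnected basin components record saddle points, yielding the barrier
  tree as a by-product.

Z{b,c} sums Δ⁻¹ w(x) over boundary micro-edges, where x is the higher
endpoint under the total order; it is direction independent and already
contains the Δ⁻¹ Metropolis normalization, so the exact macro transition
probability is simply q(b→c) = Z{b,c} / Z_b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Basin",
    "MacroModel",
    "BarrierTree",
    "brute_force_macromodel",
    "barriers_flood",
]


@dataclass
class Basin:
    """A gradient-basin macro-state, represented by its local minimum."""

    minimum: object
    size: int
    Z: float
    e_min: float
    e_max: float

    def __post_init__(self):
        if self.size < 1 or self.Z <= 0 or self.e_min > self.e_max:
            raise ValueError(f"inconsistent basin {self}")


@dataclass
class MacroModel:
    """All basins of (part of) a landscape plus Z{b,c} for adjacent pairs.

    ``basins`` is ordered by the total order of the minima; ``transitions``
    maps the unordered pair (earlier_min, later_min) to Z{b,c} (Δ⁻¹
    included). ``total_states`` is the number of enumerated micro-states.
    """

    basins: list
    transitions: dict
    delta: int
    beta: float
    total_states: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._by_min = {b.minimum: b for b in self.basins}

    @property
    def minima(self) -> list:
        return [b.minimum for b in self.basins]

    def basin(self, minimum) -> Basin:
        return self._by_min[minimum]

    def pair_key(self, a, b):
        order = {m: i for i, m in enumerate(self.minima)}
        return (a, b) if order[a] < order[b] else (b, a)

    def z_total(self) -> float:
        return sum(b.Z for b in self.basins)

    def degree(self, minimum) -> int:
        return sum(1 for (a, b) in self.transitions if minimum in (a, b))

    def adjacency(self) -> dict:
        adj = {m: [] for m in self.minima}
        for a, b in self.transitions:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass
class BarrierTree:
    """Merge hierarchy of local minima at saddle energies.

    ``merge_events`` lists (saddle_energy, rep_a, rep_b) in ascending flood
    order, where each rep is the total-order-lowest minimum of a component
    at the time of merging. The saddle energy E(b,c) of two minima is the
    lowest flood level at which their components join — the min-max path
    energy between them.
    """

    minima: list                 # ordered by the total order
    energies: dict               # minimum -> E(minimum)
    merge_events: list           # [(energy, rep_a, rep_b), ...] ascending

    def __post_init__(self):
        self._index = {m: i for i, m in enumerate(self.minima)}
        self._saddle = None

    def saddle_matrix(self):
        """Dense symmetric matrix of pairwise saddle energies (inf across components)."""
        import numpy as np

        if self._saddle is not None:
            return self._saddle
        n = len(self.minima)
        S = np.full((n, n), math.inf)
        for m, i in self._index.items():
            S[i, i] = self.energies[m]
        comp_of = {m: i for i, m in enumerate(self.minima)}
        members = {i: [i] for i in range(n)}
        for e, a, b in self.merge_events:
            ca, cb = comp_of[a], comp_of[b]
            if ca == cb:
                raise ValueError(f"merge event joins already-connected pair {a!r},{b!r}")
            ia = np.array(members[ca])
            ib = np.array(members[cb])
            S[np.ix_(ia, ib)] = e
            S[np.ix_(ib, ia)] = e
            # fold the smaller member list into the larger
            if len(members[ca]) < len(members[cb]):
                ca, cb = cb, ca
            for j in members[cb]:
                comp_of[self.minima[j]] = ca
            members[ca].extend(members.pop(cb))
        self._saddle = S
        return S

    def saddle_energy(self, b, c) -> float:
        """Lowest path maximum between minima ``b`` and ``c``; E(b) for b == c."""
        S = self.saddle_matrix()
        val = S[self._index[b], self._index[c]]
        if math.isinf(val):
            raise ValueError(f"minima {b!r} and {c!r} are in different components")
        return float(val)

    @property
    def n_components(self) -> int:
        return len(self.minima) - len(self.merge_events)


def _finalize(L, Zb, sizes, emin, emax, trans, total, meta=None) -> MacroModel:
    order = sorted(Zb, key=L.order_key)
    pos = {m: i for i, m in enumerate(order)}
    basins = [
        Basin(minimum=m, size=sizes[m], Z=Zb[m], e_min=emin[m], e_max=emax[m])
        for m in order
    ]
    transitions = {}
    for (a, b), z in trans.items():
        key = (a, b) if pos[a] < pos[b] else (b, a)
        transitions[key] = z
    return MacroModel(
        basins=basins,
        transitions=transitions,
        delta=L.delta,
        beta=L.beta,
        total_states=total,
        meta=meta or {},
    )


def brute_force_macromodel(L) -> MacroModel:
    """Reference decomposition by full enumeration and per-state gradient walks.

    Every enumerated micro-state x contributes w(x) to Z_{F(x)}; every
    boundary micro-edge contributes Δ⁻¹ w(higher endpoint) to Z{F(x),F(y)},
    counted exactly once from the higher side.
    """
    Zb: dict = {}
    sizes: dict = {}
    emin: dict = {}
    emax: dict = {}
    trans: dict = {}
    total = 0
    for x in L.enumerate_states():
        total += 1
        m = L.assign(x)
        w = L.weight(x)
        e = L.energy(x)
        if m in Zb:
            Zb[m] += w
            sizes[m] += 1
            emin[m] = min(emin[m], e)
            emax[m] = max(emax[m], e)
        else:
            Zb[m] = w
            sizes[m] = 1
            emin[m] = emax[m] = e
        kx = L.order_key(x)
        for y in L.neighbors(x):
            if L.order_key(y) < kx:       # count each micro-edge once, from above
                my = L.assign(y)
                if my != m:
                    key = (m, my) if str(m) < str(my) else (my, m)
                    trans[key] = trans.get(key, 0.0) + w / L.delta
    return _finalize(L, Zb, sizes, emin, emax, trans, total)


def barriers_flood(L, energy_bound: float | None = None):
    """Energy-sorted bottom-up flooding with saddle detection.

    Returns ``(MacroModel, BarrierTree)``. States are processed in
    ascending total order, so a state's steepest-descent neighbor is always
    already assigned and one dictionary lookup gives its basin. A state
    whose lower neighborhood touches k >= 2 previously disconnected basin
    components emits k-1 merge events at its energy.

    With ``energy_bound``, only states with E <= bound are processed (for
    RNA landscapes additionally restricted to bound-respecting reachability
    from the open chain); basins connected only above the bound stay
    unmerged and the tree is a forest.
    """
    states = sorted(L.enumerate_states(energy_bound), key=L.order_key)
    universe = set(states) if energy_bound is not None else None
    assign: dict = {}
    Zb: dict = {}
    sizes: dict = {}
    emin: dict = {}
    emax: dict = {}
    trans: dict = {}
    # union-find over basin minima, with the total-order-lowest minimum as rep
    parent: dict = {}
    merge_events: list = []

    def find(m):
        root = m
        while parent[root] != root:
            root = parent[root]
        while parent[m] != root:
            parent[m], m = root, parent[m]
        return root

    for x in states:
        nbs = L.neighbors(x)
        if universe is not None:
            nbs = [y for y in nbs if y in universe]
        kx = L.order_key(x)
        lower = [y for y in nbs if L.order_key(y) < kx]
        if lower:
            sdn = min(lower, key=L.order_key)
            m = assign[sdn]
        else:
            m = x                       # new local minimum (within the universe)
            parent[m] = m
        assign[x] = m
        w = L.weight(x)
        e = L.energy(x)
        if m in Zb:
            Zb[m] += w
            sizes[m] += 1
            emax[m] = max(emax[m], e)
        else:
            Zb[m] = w
            sizes[m] = 1
            emin[m] = emax[m] = e
        touched = {find(m)}
        for y in lower:
            my = assign[y]
            if my != m:
                key = (m, my) if str(m) < str(my) else (my, m)
                trans[key] = trans.get(key, 0.0) + w / L.delta
            touched.add(find(my))
        if len(touched) > 1:
            reps = sorted(touched, key=L.order_key)
            base = reps[0]
            for other in reps[1:]:
                merge_events.append((e, base, other))
                parent[other] = base
    model = _finalize(
        L, Zb, sizes, emin, emax, trans, len(states),
        meta={"energy_bound": energy_bound},
    )
    tree = BarrierTree(
        minima=model.minima,
        energies={b.minimum: b.e_min for b in model.basins},
        merge_events=merge_events,
    )
    return model, tree
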