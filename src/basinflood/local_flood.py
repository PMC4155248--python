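"""Memory-efficient per-basin local flooding.

Local flooding enumerates a single gradient basin b from its local minimum
outward, in ascending (energy, encoding) order, keeping only the member set
D and an ordered candidate set T. It yields the basin partition function
Z_b and every transition-state partition function Z{b,c} to adjacent basins
without ever hashing the whole landscape — the memory footprint is
|F⁻¹(b)| + |T(b)| instead of |X|.

A popped candidate x is a member iff its steepest-descent neighbor is
already in D. Members push their higher-ordered neighbors into T and
account for boundary edges to lower non-members (transitions leaving b);
non-members account for boundary edges down into D (transitions entering
b). The basin assignment F of any non-member is obtained by an explicit
gradient walk (optionally memoized; the cache never changes results).

:func:`discover_landscape` turns this into whole-landscape exploration:
each flood reports the neighboring, still unexplored minima, which are
floods in turn until the basin adjacency graph is exhausted. Because every
Z{b,c} is computed independently from both sides, their agreement is a
built-in consistency check on the whole machinery.
"""

from __future__ import annotations

import heapq
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .global_flood import Basin, MacroModel

__all__ = [
    "FloodResult",
    "FloodInconsistencyError",
    "local_flood",
    "discover_landscape",
    "memory_ratio",
]

#: relative tolerance for the two-sided Z{b,c} agreement check
TWO_SIDED_RTOL = 1e-6


class FloodInconsistencyError(RuntimeError):
    """Two-sided transition partition functions disagree."""


@dataclass
class FloodResult:
    """Outcome of flooding one gradient basin.

    ``boundary`` maps each adjacent local minimum to the full Z{b,·}
    contribution (Δ⁻¹ included). ``contacts_count`` counts the distinct
    non-member states the flood had to hold — candidates popped from T
    that turned out to lie outside b, plus boundary partners of members —
    so the local memory footprint is ``members_count + contacts_count``.
    """

    basin: Basin
    boundary: dict = field(default_factory=dict)
    members_count: int = 0
    contacts_count: int = 0

    @property
    def mem_local(self) -> int:
        return self.members_count + self.contacts_count


def local_flood(L, m, debug: bool = False) -> FloodResult:
    """Flood the gradient basin of local minimum ``m``.

    Raises ``ValueError`` if ``m`` is not a local minimum. With ``debug``
    the non-decreasing pop order of T is asserted. Results match the global
    oracle exactly (up to float round-off).
    """
    if L.steepest_descent_neighbor(m) is not None:
        raise ValueError(f"{m!r} is not a local minimum")
    delta = L.delta
    key = L.order_key
    D = {m}
    Z = L.weight(m)
    e_min = e_max = L.energy(m)
    boundary: dict = {}
    heap: list = []
    seen = set()
    for nb in L.neighbors(m):
        seen.add(nb)
        heapq.heappush(heap, (key(nb), nb))
    members = 1
    contacts: set = set()
    last_key = None
    while heap:
        kx, x = heapq.heappop(heap)
        if debug:
            assert last_key is None or kx >= last_key, "pop order must be non-decreasing"
            last_key = kx
        nbs = L.neighbors(x)
        sdn = min(nbs, key=key)          # x came from T, so it has neighbors
        w = L.weight(x)
        if sdn in D:                     # member of b
            D.add(x)
            contacts.discard(x)
            members += 1
            Z += w
            e_max = max(e_max, L.energy(x))
            for nb in nbs:
                kn = key(nb)
                if kn > kx:
                    if nb not in seen:
                        seen.add(nb)
                        heapq.heappush(heap, (kn, nb))
                elif nb not in D:        # descending edge leaving b
                    contacts.add(nb)
                    t = L.assign(nb)
                    boundary[t] = boundary.get(t, 0.0) + w / delta
        else:                            # contact state outside b
            contacts.add(x)
            fx = L.assign(x)
            for nb in nbs:
                if key(nb) < kx and nb in D:   # descending edge entering b
                    boundary[fx] = boundary.get(fx, 0.0) + w / delta
    basin = Basin(minimum=m, size=members, Z=Z, e_min=e_min, e_max=e_max)
    return FloodResult(
        basin=basin, boundary=boundary,
        members_count=members, contacts_count=len(contacts),
    )


def memory_ratio(result: FloodResult, total_states: int) -> float:
    """mem(L)/mem(G) = (members + contacts) / |X| for one basin."""
    if total_states <= 0:
        raise ValueError("total_states must be positive")
    if total_states < result.members_count:
        raise ValueError("total_states smaller than the basin itself")
    return result.mem_local / total_states


def discover_landscape(L, seed_state, workers: int = 1, debug: bool = False):
    """Explore a whole landscape component by chained local floods.

    ``seed_state`` may be any state; it is gradient-walked to its minimum
    first. Each flood's boundary reveals adjacent minima, which are queued
    until no unexplored basin remains. Every Z{b,c} is computed from both
    sides and must agree within ``TWO_SIDED_RTOL`` relative (the stored
    value is the one from the basin earlier in the total order). The result
    is independent of ``workers`` and of exploration order.

    Returns ``(MacroModel, {minimum: FloodResult})``.
    """
    seed = L.assign(seed_state)
    results: dict = {}
    pending = {seed}
    queued = {seed}

    def flood_batch(batch):
        if workers > 1 and len(batch) > 1:
            with ThreadPoolExecutor(max_workers=workers) as ex:
                return list(ex.map(lambda mm: local_flood(L, mm, debug=debug), batch))
        return [local_flood(L, mm, debug=debug) for mm in batch]

    while pending:
        batch = sorted(pending, key=L.order_key)
        pending = set()
        for res in flood_batch(batch):
            results[res.basin.minimum] = res
            for adj in res.boundary:
                if adj not in queued:
                    queued.add(adj)
                    pending.add(adj)

    order = sorted(results, key=L.order_key)
    pos = {m: i for i, m in enumerate(order)}
    transitions: dict = {}
    for m in order:
        for c, z_here in results[m].boundary.items():
            other = results.get(c)
            if other is None or m not in other.boundary:
                raise FloodInconsistencyError(
                    f"transition {m!r}<->{c!r} seen from one side only"
                )
            z_there = other.boundary[m]
            if abs(z_here - z_there) > TWO_SIDED_RTOL * max(abs(z_here), abs(z_there)):
                raise FloodInconsistencyError(
                    f"Z{{b,c}} mismatch for pair ({m!r}, {c!r}): "
                    f"{z_here!r} vs {z_there!r}"
                )
            if pos[m] < pos[c]:
                transitions[(m, c)] = z_here
    basins = [results[m].basin for m in order]
    model = MacroModel(
        basins=basins,
        transitions=transitions,
        delta=L.delta,
        beta=L.beta,
        total_states=sum(b.size for b in basins),
        meta={"method": "local-flooding", "workers": workers},
    )
    return model, results
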