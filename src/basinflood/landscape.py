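"""Discrete energy landscapes: the triple (X, E, M) with Metropolis dynamics.

A :class:`Landscape` bundles a state space X, an energy function E, a
symmetric move set M, the Metropolis normalization Δ and the inverse
temperature β. Two concrete flavors exist:

* :class:`RnaLandscape` — secondary structures of one sequence under the
  single base-pair add/remove move set (states are dot-bracket strings);
* :class:`ToyLandscape` — an explicit small graph with per-state energies,
  the hand-checkable substrate for all oracle tests.

Both expose the same protocol: ``energy``, ``neighbors``, ``order_key``
(the strict total order breaking energy degeneracy by string encoding),
``weight``, ``metropolis_probability``, steepest-descent walks and state
enumeration. All flooding and kinetics code is written against this
protocol only.
"""

from __future__ import annotations

import math
from collections import deque

from . import rna_model
from .rna_model import RnaSequence, SimplePairEnergy, StructureError

__all__ = [
    "Landscape",
    "RnaLandscape",
    "ToyLandscape",
    "LandscapeOverflowError",
    "boltzmann_weight",
    "read_toy_tsv",
    "write_toy_tsv",
    "KT37_KCAL",
]

#: kT at 37 C in kcal/mol (Boltzmann gas constant 1.9872e-3 kcal/mol/K x 310.15 K)
KT37_KCAL = 0.61633

#: default cap on exhaustive state enumeration
DEFAULT_STATE_CAP = 5_000_000


class LandscapeOverflowError(RuntimeError):
    """State enumeration exceeded the configured cap."""

    def __init__(self, cap: int, count: int):
        super().__init__(
            f"state space exceeds cap of {cap} states ({count} enumerated so far)"
        )
        self.cap = cap
        self.count = count


def boltzmann_weight(energy: float, beta: float) -> float:
    """w(x) = exp(-beta * E(x)); beta = 0 yields the flat weight 1."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return math.exp(-beta * energy)


class Landscape:
    """Common machinery shared by RNA and explicit toy landscapes."""

    beta: float
    delta: int

    def __init__(self, beta: float, f_cache_size: int = 10**6):
        if beta < 0:
            raise ValueError("beta must be non-negative")
        self.beta = beta
        self._energy_cache: dict = {}
        self._f_cache: dict = {}
        self._f_cache_size = f_cache_size

    # -- subclass responsibilities ------------------------------------
    def _energy_uncached(self, state) -> float:
        raise NotImplementedError

    def neighbors(self, state) -> list:
        raise NotImplementedError

    def enumerate_states(self, energy_bound: float | None = None):
        raise NotImplementedError

    # -- shared protocol ----------------------------------------------
    def energy(self, state) -> float:
        e = self._energy_cache.get(state)
        if e is None:
            e = self._energy_uncached(state)
            self._energy_cache[state] = e
        return e

    def weight(self, state) -> float:
        return boltzmann_weight(self.energy(state), self.beta)

    def order_key(self, state):
        """Strict total order: energy first, then the string encoding."""
        return (self.energy(state), state)

    def metropolis_probability(self, x, y) -> float:
        """p(x->y) = Δ⁻¹ min{exp(-β[E(y)-E(x)]), 1}, defined for y ∈ M(x)."""
        if y not in self.neighbors(x):
            raise ValueError(
                "transition probability only defined for neighboring states"
            )
        de = self.energy(y) - self.energy(x)
        return min(math.exp(-self.beta * de), 1.0) / self.delta

    def steepest_descent_neighbor(self, state):
        """The minimal neighbor under the total order, or None at a local minimum.

        Degenerate (equal-energy) plateaus are resolved by the encoding
        tie-break, so the result — and hence the gradient-basin map — is
        single valued.
        """
        nbs = self.neighbors(state)
        if not nbs:
            return None
        best = min(nbs, key=self.order_key)
        return best if self.order_key(best) < self.order_key(state) else None

    def is_local_minimum(self, state) -> bool:
        return self.steepest_descent_neighbor(state) is None

    def gradient_walk(self, state):
        """Follow steepest descent to the fixed point; returns (minimum, steps)."""
        steps = 0
        x = state
        while True:
            y = self.steepest_descent_neighbor(x)
            if y is None:
                return x, steps
            x = y
            steps += 1

    def assign(self, state):
        """Gradient-basin representative F(x), memoized (bounded cache).

        The cache is a pure speed device: results are identical with the
        cache disabled.
        """
        path = []
        x = state
        memo = self._f_cache
        while x not in memo:
            y = self.steepest_descent_neighbor(x)
            if y is None:
                break
            path.append(x)
            x = y
        m = memo.get(x, x)
        if len(memo) < self._f_cache_size:
            for s in path:
                memo[s] = m
            memo[state] = m
        return m


class RnaLandscape(Landscape):
    """All secondary structures of one sequence under one energy backend.

    States are dot-bracket strings (the canonical encoding doubles as the
    degeneracy tie-break). Δ is the number of admissible pairs of the
    sequence. The default β is 1 for the built-in backend (arbitrary
    units) and 1/kT at 37 C for the nearest-neighbor backend (kcal/mol).
    """

    def __init__(
        self,
        seq,
        backend=None,
        beta: float | None = None,
        min_loop: int = rna_model.MIN_LOOP,
        state_cap: int = DEFAULT_STATE_CAP,
        f_cache_size: int = 10**6,
    ):
        self.seq = seq if isinstance(seq, RnaSequence) else RnaSequence(seq)
        self.backend = backend if backend is not None else SimplePairEnergy()
        if beta is None:
            beta = 1.0 / KT37_KCAL if getattr(self.backend, "units", "") == "kcal/mol" else 1.0
        super().__init__(beta, f_cache_size)
        self.min_loop = min_loop
        self.state_cap = state_cap
        self._apairs = rna_model.admissible_pairs(self.seq, min_loop)
        self.delta = len(self._apairs)
        self.open_chain = "." * len(self.seq)
        self._bases = self.seq.bases

    @property
    def start_state(self) -> str:
        return self.open_chain

    def _energy_uncached(self, state) -> float:
        return self.backend.evaluate_db(self._bases, state)

    def neighbors(self, state) -> list:
        return rna_model._db_neighbors(state, self._apairs)

    def enumerate_states(self, energy_bound: float | None = None):
        """Breadth-first enumeration of X from the open chain.

        With ``energy_bound`` set, yields exactly the states with
        E <= bound reachable from the open chain through states obeying
        the bound. Raises :class:`LandscapeOverflowError` past the cap.
        """
        start = self.open_chain
        if energy_bound is not None and self.energy(start) > energy_bound:
            return
        seen = {start}
        queue = deque([start])
        count = 0
        while queue:
            x = queue.popleft()
            count += 1
            if count > self.state_cap:
                raise LandscapeOverflowError(self.state_cap, count)
            yield x
            for y in self.neighbors(x):
                if y in seen:
                    continue
                if energy_bound is not None and self.energy(y) > energy_bound:
                    continue
                seen.add(y)
                queue.append(y)

    def describe(self) -> dict:
        d = {"sequence": self._bases, "n": len(self.seq), "beta": self.beta,
             "delta": self.delta, "min_loop": self.min_loop}
        d.update(self.backend.describe())
        return d


class ToyLandscape(Landscape):
    """An explicit landscape graph: states with energies, undirected edges.

    Δ is the maximum vertex degree (the exact maximal neighborhood size).
    The graph need not be connected, but flooding only covers the component
    of its start state.
    """

    def __init__(self, states, edges, beta: float = 1.0):
        super().__init__(beta)
        self._energies = {}
        for sid, e in states:
            if sid in self._energies:
                raise ValueError(f"duplicate state id {sid!r}")
            self._energies[sid] = float(e)
        self._adj = {sid: [] for sid in self._energies}
        edge_set = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-edge at {a!r}")
            if a not in self._energies or b not in self._energies:
                raise ValueError(f"edge ({a!r},{b!r}) references unknown state")
            key = (a, b) if a <= b else (b, a)
            if key in edge_set:
                continue
            edge_set.add(key)
            self._adj[a].append(b)
            self._adj[b].append(a)
        self.edges = sorted(edge_set)
        self.delta = max((len(v) for v in self._adj.values()), default=0) or 1
        self.states = sorted(self._energies, key=self.order_key)

    @property
    def start_state(self):
        return self.states[0]

    def _energy_uncached(self, state) -> float:
        try:
            return self._energies[state]
        except KeyError:
            raise KeyError(f"unknown state {state!r}") from None

    def neighbors(self, state) -> list:
        return self._adj[state]

    def enumerate_states(self, energy_bound: float | None = None):
        for s in self.states:
            if energy_bound is None or self._energies[s] <= energy_bound:
                yield s

    def describe(self) -> dict:
        return {"kind": "toy", "n_states": len(self.states),
                "n_edges": len(self.edges), "beta": self.beta,
                "delta": self.delta}


# ---------------------------------------------------------------------------
# toy landscape TSV: '#' comments; 'S<TAB>id<TAB>energy'; 'E<TAB>id1<TAB>id2'

def read_toy_tsv(path, beta: float = 1.0) -> ToyLandscape:
    states, edges = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "S" and len(parts) == 3:
                states.append((parts[1], float(parts[2])))
            elif parts[0] == "E" and len(parts) == 3:
                edges.append((parts[1], parts[2]))
            else:
                raise ValueError(f"{path}:{ln}: malformed toy landscape line {line!r}")
    return ToyLandscape(states, edges, beta=beta)


def write_toy_tsv(landscape: ToyLandscape, path) -> None:
    """States are written sorted by (energy, id); edges sorted by id pair."""
    with open(path, "w") as fh:
        fh.write("# basinflood toy landscape\n")
        for sid in sorted(landscape._energies, key=lambda s: (landscape._energies[s], s)):
            fh.write(f"S\t{sid}\t{landscape._energies[sid]:.12g}\n")
        for a, b in landscape.edges:
            fh.write(f"E\t{a}\t{b}\n")
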