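"""Deterministic synthetic inputs: toy landscapes and random RNA sets.

The chain landscapes are the hand-checkable substrates used throughout the
test suite; the random graph generator stress-tests the flooding machinery
on arbitrary connected topologies; ``random_rna_set`` regenerates
uniform-composition random sequence panels (10 sequences per length,
25–35 nt by default) of the kind used to study landscape statistics at
exhaustive-enumeration scale. All random generation is seeded.
"""

from __future__ import annotations

import numpy as np

from .landscape import ToyLandscape
from .rna_model import RnaSequence

__all__ = [
    "chain_landscape",
    "random_toy_landscape",
    "random_rna_set",
    "L1_ENERGIES",
    "L2_ENERGIES",
]

#: the two canonical worked examples: a 3-state and a 5-state energy path
L1_ENERGIES = [0.0, 2.0, 1.0]
L2_ENERGIES = [0.0, 3.0, 1.0, 2.0, 0.5]


def chain_landscape(energies, beta: float = 1.0) -> ToyLandscape:
    """Path graph s0–s1–…–s{n-1} with the given per-state energies."""
    if not energies:
        raise ValueError("need at least one energy")
    states = [(f"s{i}", float(e)) for i, e in enumerate(energies)]
    edges = [(f"s{i}", f"s{i + 1}") for i in range(len(energies) - 1)]
    return ToyLandscape(states, edges, beta=beta)


def random_toy_landscape(
    n: int,
    mean_degree: float,
    e_low: float,
    e_high: float,
    seed: int,
    beta: float = 1.0,
) -> ToyLandscape:
    """Connected random graph with uniform energies, reproducible from ``seed``.

    A random spanning tree guarantees connectivity; extra random edges are
    added until the target mean degree is met. Energy ties are nudged
    apart at the 1e-9 level so oracle tests exercise non-degenerate
    landscapes by default.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_degree >= n:
        raise ValueError("mean_degree must be < n")
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((ids[j], ids[i]))
    target = max(n - 1, round(mean_degree * n / 2))
    max_edges = n * (n - 1) // 2
    if target > max_edges:
        raise ValueError("mean_degree infeasible for this n")
    attempts = 0
    while len(edges) < target and attempts < 50 * target + 100:
        a, b = rng.integers(0, n, size=2)
        attempts += 1
        if a == b:
            continue
        if a > b:
            a, b = b, a
        edges.add((ids[a], ids[b]))
    energies = rng.uniform(e_low, e_high, size=n)
    order = np.argsort(energies, kind="stable")
    for prev, cur in zip(order, order[1:]):
        if energies[cur] <= energies[prev]:
            energies[cur] = energies[prev] + 1e-9
    states = list(zip(ids, energies.tolist()))
    return ToyLandscape(states, sorted(edges), beta=beta)


def random_rna_set(
    per_length: int, len_min: int, len_max: int, seed: int
) -> list:
    """``per_length`` sequences per length in [len_min, len_max], bases i.i.d.
    uniform over {A,C,G,U}."""
    if per_length < 1 or len_min > len_max:
        raise ValueError("invalid sequence set parameters")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    out = []
    for length in range(len_min, len_max + 1):
        for _ in range(per_length):
            seq = "".join(rng.choice(alphabet, size=length))
            out.append(RnaSequence(seq))
    return out
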