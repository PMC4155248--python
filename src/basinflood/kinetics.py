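"""Coarse-grained Markov chains over gradient basins and first-passage times.

Three discrete-time macro-state transition models are built over the same
basin set:

* **exact** — q(b→c) = Z{b,c} / Z_b from the flooded transition-state
  partition functions; satisfies detailed balance Z_b q(b→c) = Z_c q(c→b).
* **barrier** — Arrhenius-like, a(b→c) = A exp(-β (E(b,c) − E(b))) with
  E(b,c) the saddle energy from the barrier tree; defined for *all* pairs
  of minima, i.e. it discards the adjacency topology.
* **merged** — Arrhenius probabilities restricted to the exact adjacency
  (zero where the exact chain has no transition), separating the barrier
  model's loss of precision from its loss of topology.

First-passage times τ(b,t) — the expected number of chain steps from b to
first reach t, with τ(t,t) = 0 — solve the linear recursion
τ(b,t) = 1 + Σ_c q(b→c) τ(c,t) with the target made absorbing. Model
quality is compared by the Spearman rank correlation of FPT vectors from
the unfolded (open-chain) basin, which cancels the unknown Arrhenius
prefactor A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

__all__ = [
    "MacroChain",
    "FptVector",
    "ModelComparison",
    "exact_macro_chain",
    "arrhenius_chain",
    "merged_chain",
    "first_passage_times",
    "fpt_from_start",
    "spearman_rank_correlation",
    "compare_models",
]

_ROW_SUM_TOL = 1e-12


@dataclass
class MacroChain:
    """Row-stochastic one-step transition matrix over an ordered basin list."""

    minima: list
    matrix: np.ndarray
    model_tag: str               # "exact" | "barrier" | "merged"
    prefactor: float | None = None

    def __post_init__(self):
        n = len(self.minima)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match basin count")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.model_tag} chain has negative entries")
        rows = self.matrix.sum(axis=1)
        if np.abs(rows - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError(
                f"{self.model_tag} chain rows deviate from 1 by "
                f"{np.abs(rows - 1.0).max():.3e}"
            )
        self.index = {m: i for i, m in enumerate(self.minima)}


@dataclass
class FptVector:
    """Expected steps to first reach ``target`` from every basin (inf if unreachable)."""

    target: object
    values: dict = field(default_factory=dict)

    def as_array(self, minima) -> np.ndarray:
        return np.array([self.values[m] for m in minima])


def _complete_rows(off: np.ndarray, tag: str) -> np.ndarray:
    """Fill diagonals so rows sum to 1. Mutates ``off`` in place."""
    np.fill_diagonal(off, 0.0)
    diag = 1.0 - off.sum(axis=1)
    if (diag < -_ROW_SUM_TOL).any():
        raise ValueError(
            f"{tag} chain: off-diagonal row sum exceeds 1 "
            f"(min diagonal {diag.min():.3e})"
        )
    np.fill_diagonal(off, np.maximum(diag, 0.0))
    return off


def exact_macro_chain(model) -> MacroChain:
    """The exact chain q(b→c) = Z{b,c}/Z_b from a :class:`MacroModel`."""
    minima = model.minima
    idx = {m: i for i, m in enumerate(minima)}
    n = len(minima)
    off = np.zeros((n, n))
    Z = np.array([b.Z for b in model.basins])
    for (a, b), z in model.transitions.items():
        off[idx[a], idx[b]] = z / Z[idx[a]]
        off[idx[b], idx[a]] = z / Z[idx[b]]
    return MacroChain(minima=minima, matrix=_complete_rows(off, "exact"),
                      model_tag="exact")


def arrhenius_chain(tree, beta: float, A="auto") -> MacroChain:
    """Barrier-tree chain a(b→c) = A exp(-β(E(b,c) − E(b))) for all pairs b ≠ c.

    The model does not enforce adjacency: every pair of minima in the tree
    component gets a positive probability. With ``A="auto"`` the prefactor
    is set to 0.99 / (largest off-diagonal row sum at A = 1) so that every
    diagonal stays positive; FPT *ranks* are invariant to this choice.
    """
    minima = tree.minima
    n = len(minima)
    if tree.n_components != 1:
        raise ValueError("Arrhenius chain requires all minima in one tree component")
    S = tree.saddle_matrix()
    E = np.array([tree.energies[m] for m in minima])
    off = np.exp(-beta * (S - E[:, None]))
    np.fill_diagonal(off, 0.0)
    if A == "auto":
        A = 0.99 / off.sum(axis=1).max()
    if not (A > 0):
        raise ValueError("Arrhenius prefactor must be positive")
    off *= A
    return MacroChain(minima=minima, matrix=_complete_rows(off, "barrier"),
                      model_tag="barrier", prefactor=float(A))


def _merged_from_mask(adjacency: np.ndarray, arrhenius: MacroChain) -> MacroChain:
    off = arrhenius.matrix.copy()
    off[~adjacency] = 0.0
    return MacroChain(minima=arrhenius.minima,
                      matrix=_complete_rows(off, "merged"),
                      model_tag="merged", prefactor=arrhenius.prefactor)


def merged_chain(exact: MacroChain, arrhenius: MacroChain) -> MacroChain:
    """Arrhenius probabilities masked to the exact chain's adjacency."""
    if exact.minima != arrhenius.minima:
        raise ValueError("chains are indexed over different basin lists")
    adjacency = exact.matrix > 0.0
    np.fill_diagonal(adjacency, False)
    return _merged_from_mask(adjacency, arrhenius)


def first_passage_times(chain: MacroChain, target) -> FptVector:
    """Solve τ = 1 + Q_restricted τ with ``target`` absorbing.

    Basins that cannot reach the target get τ = inf; τ(target) = 0.
    """
    if target not in chain.index:
        raise ValueError(f"unknown target basin {target!r}")
    t = chain.index[target]
    n = len(chain.minima)
    # reachability: which basins can reach the target through positive steps
    adj = chain.matrix > 0.0
    reach = np.zeros(n, dtype=bool)
    reach[t] = True
    frontier = [t]
    while frontier:
        j = frontier.pop()
        for i in np.nonzero(adj[:, j])[0]:
            if not reach[i]:
                reach[i] = True
                frontier.append(int(i))
    sub = [i for i in range(n) if reach[i] and i != t]
    values = {m: math.inf for m in chain.minima}
    values[target] = 0.0
    if sub:
        Q = chain.matrix[np.ix_(sub, sub)]
        try:
            tau = scipy.linalg.solve(np.eye(len(sub)) - Q, np.ones(len(sub)))
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - diagnostics
            raise RuntimeError(
                f"singular FPT system for target {target!r} "
                f"({len(sub)} transient basins)"
            ) from exc
        for i, idx in enumerate(sub):
            values[chain.minima[idx]] = float(tau[i])
    return FptVector(target=target, values=values)


def fpt_from_start(chain: MacroChain, start, pi=None) -> dict:
    """τ(start, t) for every basin t of a *reversible* irreducible chain.

    Uses the fundamental matrix Z = (I − P + 1πᵀ)⁻¹ and the identity
    τ(b,t) = (Z_tt − Z_bt)/π_t, so all targets come from a single
    symmetric factorization instead of one absorbing solve per target.
    With π the stationary distribution and D = diag(√π), the similarity
    transform D(I − P + 1πᵀ)D⁻¹ = I − S + ssᵀ (s = √π) is symmetric
    positive definite for reversible P, and one Cholesky factorization
    yields both diag(Z) and the start row.

    ``pi`` is the stationary distribution; if omitted it is computed from
    the detailed-balance structure check. Agreement with the per-target
    absorbing-chain solver :func:`first_passage_times` is part of the test
    contract.
    """
    P = chain.matrix
    n = len(chain.minima)
    if start not in chain.index:
        raise ValueError(f"unknown start basin {start!r}")
    if n == 1:
        return {chain.minima[0]: 0.0}
    if pi is None:
        # left Perron vector via one LU solve on the bordered system
        A = np.eye(n) - P.T
        A[-1, :] = 1.0
        rhs = np.zeros(n)
        rhs[-1] = 1.0
        pi = scipy.linalg.solve(A, rhs)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    if (pi <= 0).any():
        raise ValueError("stationary distribution must be strictly positive")
    s = np.sqrt(pi)
    # S_ij = s_i P_ij / s_j is symmetric iff pi P satisfies detailed balance;
    # build Asym = I - S + s sᵀ in chunks to avoid full-size temporaries
    Asym = P / s[None, :]
    Asym *= -s[:, None]                  # now -S
    chunk = max(1, (1 << 22) // n)
    worst = 0.0
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        block = Asym[i0:i1, :]
        d = np.abs(block - Asym[:, i0:i1].T).max()
        worst = max(worst, float(d))
    if worst > 1e-8:
        raise ValueError(
            f"chain is not reversible w.r.t. the given pi (asymmetry {worst:.2e}); "
            "use first_passage_times per target instead"
        )
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        Asym[i0:i1, :] += s[i0:i1, None] * s[None, :]
    Asym[np.diag_indices(n)] += 1.0
    # Asym is symmetric, so its transpose is an equal Fortran-ordered view;
    # LAPACK can then factor and invert in place instead of copying
    c, low = scipy.linalg.cho_factor(Asym.T, lower=True, overwrite_a=True)
    b = chain.index[start]
    eb = np.zeros(n)
    eb[b] = 1.0
    wrow = scipy.linalg.cho_solve((c, low), eb)          # W e_b (W symmetric)
    linv, info = scipy.linalg.lapack.dtrtri(c, lower=1, overwrite_c=1)
    if info != 0:
        raise RuntimeError(f"triangular inversion failed (info={info})")
    del c, Asym
    for j in range(1, n):                # dtrtri leaves garbage above the diagonal
        linv[:j, j] = 0.0
    diag_w = np.einsum("ij,ij->j", linv, linv)           # diag(L⁻ᵀ L⁻¹)
    del linv
    tau = (diag_w - (s / s[b]) * wrow) / pi
    tau[b] = 0.0
    return {m: float(tau[i]) for i, m in enumerate(chain.minima)}


def spearman_rank_correlation(u, v) -> float:
    """Spearman's ρ (average ranks for ties) over paired finite entries.

    Pairs with a non-finite value in either vector are dropped; fewer than
    two usable pairs or zero rank variance raise ``ValueError``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(u) & np.isfinite(v)
    u, v = u[keep], v[keep]
    if len(u) < 2:
        raise ValueError("fewer than 2 finite pairs; correlation undefined")
    if np.all(u == u[0]) or np.all(v == v[0]):
        raise ValueError("zero rank variance; correlation undefined")
    rho = scipy.stats.spearmanr(u, v).statistic
    return float(rho)


@dataclass
class ModelComparison:
    """FPT tables from the unfolded basin and model-vs-model rank correlations."""

    start: object
    targets: list
    fpt_exact: dict
    fpt_barrier: dict
    fpt_merged: dict
    spearman_exact_barrier: float
    spearman_exact_merged: float
    excluded_barrier: int
    excluded_merged: int
    prefactor: float

    def to_dict(self) -> dict:
        return {
            "start_basin": str(self.start),
            "prefactor_A": self.prefactor,
            "spearman_exact_barrier": self.spearman_exact_barrier,
            "spearman_exact_merged": self.spearman_exact_merged,
            "excluded_pairs": {"barrier": self.excluded_barrier,
                               "merged": self.excluded_merged},
            "fpt": [
                {"target": str(t),
                 "exact": self.fpt_exact[t],
                 "barrier": self.fpt_barrier[t],
                 "merged": self.fpt_merged[t]}
                for t in self.targets
            ],
        }


def _fpt_absorbing_row(chain: MacroChain, start, targets) -> dict:
    return {t: first_passage_times(chain, t).values[start] for t in targets}


def compare_models(
    L, A="auto", start_state=None, dense_threshold: int = 400
) -> ModelComparison:
    """Decompose a landscape and compare exact, barrier and merged kinetics.

    FPTs are computed from the basin of the open chain (or of
    ``start_state``) to every other basin under each model. Targets where
    a model yields an infinite FPT are excluded from that model's
    correlation (counts are reported). Above ``dense_threshold`` basins
    the per-target absorbing solves are replaced by the fundamental-matrix
    route of :func:`fpt_from_start` (all three chains are reversible, with
    stationary weights Z_b for the exact chain and exp(-βE(b)) for the
    barrier and merged chains); both routes agree on small landscapes.
    """
    from .global_flood import barriers_flood

    model, tree = barriers_flood(L)
    if start_state is None:
        start_state = L.start_state
    start = L.assign(start_state)
    targets = [m for m in model.minima if m != start]
    if not targets:
        raise ValueError("landscape has a single basin; nothing to compare")
    dense = len(model.minima) > dense_threshold

    def row(chain, pi):
        if dense:
            full = fpt_from_start(chain, start, pi=pi)
            return {t: full[t] for t in targets}
        return _fpt_absorbing_row(chain, start, targets)

    # chains are built and released one at a time: at n basins each dense
    # matrix is n^2 floats, and the fundamental-matrix solve needs one more
    exact = exact_macro_chain(model)
    fpt_e = row(exact, np.array([b.Z for b in model.basins]))
    adjacency = exact.matrix > 0.0
    np.fill_diagonal(adjacency, False)
    del exact
    barrier = arrhenius_chain(tree, beta=L.beta, A=A)
    tree._saddle = None                  # drop the n^2 saddle cache
    prefactor = barrier.prefactor
    merged = _merged_from_mask(adjacency, barrier)
    del adjacency
    E = np.array([tree.energies[m] for m in model.minima])
    pi_barrier = np.exp(-L.beta * (E - E.min()))
    fpt_b = row(barrier, pi_barrier)
    del barrier
    fpt_m = row(merged, pi_barrier)
    del merged

    ue = np.array([fpt_e[t] for t in targets])
    ub = np.array([fpt_b[t] for t in targets])
    um = np.array([fpt_m[t] for t in targets])
    excl_b = int(np.sum(~(np.isfinite(ue) & np.isfinite(ub))))
    excl_m = int(np.sum(~(np.isfinite(ue) & np.isfinite(um))))
    rho_b = spearman_rank_correlation(ue, ub)
    rho_m = spearman_rank_correlation(ue, um)
    return ModelComparison(
        start=start, targets=targets,
        fpt_exact=fpt_e, fpt_barrier=fpt_b, fpt_merged=fpt_m,
        spearman_exact_barrier=rho_b, spearman_exact_merged=rho_m,
        excluded_barrier=excl_b, excluded_merged=excl_m,
        prefactor=prefactor,
    )
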