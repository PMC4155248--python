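"""RNA secondary structures, the base-pair move set, and energy backends.

Micro-states of an RNA folding landscape are secondary structures: nested
sets of canonical base pairs (A-U, G-C, G-U) on a fixed sequence. Two
structures are neighbors when they differ by exactly one base pair (single
add/remove move set). Energies come from a pluggable backend: a built-in
additive pair-energy table (arbitrary units, dependency free) or the full
nearest-neighbor model through the ViennaRNA bindings (kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureError",
    "BackendUnavailableError",
    "ValidationReport",
    "parse_dotbracket",
    "validate_structure",
    "neighbors",
    "admissible_pairs",
    "delta_max_neighbors",
    "structure_order_key",
    "simple_pair_energy",
    "external_energy",
    "SimplePairEnergy",
    "ViennaBackend",
    "MIN_LOOP",
    "SIMPLE_PAIR_TABLE",
]

#: default minimum hairpin-loop length (unpaired bases enclosed by a pair)
MIN_LOOP = 3

#: canonical pair set (both orientations)
_CANONICAL = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: built-in additive pair energies, arbitrary units; NOT the Turner model
SIMPLE_PAIR_TABLE = {
    frozenset({"G", "C"}): -3.0,
    frozenset({"A", "U"}): -2.0,
    frozenset({"G", "U"}): -1.0,
}


class StructureError(ValueError):
    """Invalid sequence, structure or dot-bracket input."""


class BackendUnavailableError(RuntimeError):
    """Requested energy backend cannot be loaded."""


class RnaSequence:
    """An RNA sequence over {A,C,G,U}.

    Input is normalized: lowercase is uppercased and T becomes U (DNA/FASTA
    tolerance). Any other character rejects the sequence.
    """

    __slots__ = ("bases",)

    def __init__(self, bases: str):
        norm = bases.strip().upper().replace("T", "U")
        if not norm:
            raise StructureError("empty sequence")
        bad = set(norm) - {"A", "C", "G", "U"}
        if bad:
            raise StructureError(f"invalid bases {sorted(bad)} in sequence")
        self.bases = norm

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __repr__(self) -> str:
        return f"RnaSequence({self.bases!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, RnaSequence) and self.bases == other.bases

    def __hash__(self) -> int:
        return hash(self.bases)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs with its dot-bracket encoding.

    ``pairs`` holds 1-based (i, j) tuples with i < j; ``length`` is the
    sequence length the structure lives on. Structural invariants (pair
    disjointness and balanced nesting) are enforced at construction; pair
    admissibility against a concrete sequence is checked separately by
    :func:`validate_structure`.
    """

    pairs: frozenset
    length: int

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i},{j}) out of range 1..{self.length}")
            if i in seen or j in seen:
                raise StructureError(f"base in more than one pair at ({i},{j})")
            seen.update((i, j))
        sp = sorted(self.pairs)
        for a in range(len(sp)):
            i, j = sp[a]
            for k, l in sp[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"crossing pairs ({i},{j}) and ({k},{l})"
                    )

    @cached_property
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, text: str) -> "SecondaryStructure":
        return parse_dotbracket(text)

    @property
    def open_chain(self) -> bool:
        return not self.pairs

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return self.dot_bracket


@dataclass
class ValidationReport:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a structure by stack matching.

    Raises :class:`StructureError` naming the offending 1-based position for
    unbalanced brackets or foreign characters.
    """
    stack = []
    pairs = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(frozenset(pairs), len(text))


def _pair_ok(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def admissible_pairs(seq: RnaSequence, min_loop: int = MIN_LOOP) -> list:
    """All (i, j), 1-based, with a canonical pairing and j - i >= min_loop + 1."""
    b = seq.bases
    n = len(b)
    out = []
    for i in range(1, n + 1):
        for j in range(i + min_loop + 1, n + 1):
            if _pair_ok(b[i - 1], b[j - 1]):
                out.append((i, j))
    return out


def validate_structure(
    seq: RnaSequence, s: SecondaryStructure, min_loop: int = MIN_LOOP
) -> ValidationReport:
    """Check a structure against a sequence: admissible pairs and loop size.

    Disjointness and nestedness are already guaranteed by the
    :class:`SecondaryStructure` constructor.
    """
    if len(s) != len(seq):
        raise StructureError(
            f"structure length {len(s)} != sequence length {len(seq)}"
        )
    violations = []
    b = seq.bases
    for i, j in sorted(s.pairs):
        if not _pair_ok(b[i - 1], b[j - 1]):
            violations.append(
                f"inadmissible pair ({i},{j}): {b[i - 1]}-{b[j - 1]}"
            )
        if j - i < min_loop + 1:
            violations.append(f"hairpin loop < {min_loop} for pair ({i},{j})")
    return ValidationReport(ok=not violations, violations=violations)


# -- fast dot-bracket-level primitives (used by the landscape machinery) -----

def _db_pairs(db: str):
    stack = []
    pairs = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.append((stack.pop(), pos))
    return pairs


def _db_neighbors(db: str, apairs: list) -> list:
    """All dot-bracket strings one base-pair move away from ``db``.

    An unpaired pair of positions (i, j) can be added without crossing iff
    both positions sit in the same loop, i.e. share the same nearest
    enclosing base pair; this is an O(1) test per candidate after one pass.
    """
    n = len(db)
    enclosing = [0] * (n + 1)  # nearest enclosing '(' position, 0 for exterior
    stack = []
    pairs = []
    for pos in range(1, n + 1):
        ch = db[pos - 1]
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            stack.pop()
        else:
            enclosing[pos] = stack[-1] if stack else 0
        if ch == ")":
            pairs.append(pos)
    out = []
    # removals
    stack = []
    for pos in range(1, n + 1):
        if db[pos - 1] == "(":
            stack.append(pos)
        elif db[pos - 1] == ")":
            i = stack.pop()
            out.append(db[: i - 1] + "." + db[i: pos - 1] + "." + db[pos:])
    # additions
    for i, j in apairs:
        if db[i - 1] == "." and db[j - 1] == "." and enclosing[i] == enclosing[j]:
            out.append(
                db[: i - 1] + "(" + db[i: j - 1] + ")" + db[j:]
            )
    return out


def neighbors(
    seq: RnaSequence, s: SecondaryStructure, min_loop: int = MIN_LOOP
) -> list:
    """Every structure reachable by removing or adding exactly one pair.

    The move set is symmetric and duplicate free. Raises on structures that
    are invalid for the sequence.
    """
    rep = validate_structure(seq, s, min_loop)
    if not rep.ok:
        raise StructureError("; ".join(rep.violations))
    dbs = _db_neighbors(s.dot_bracket, admissible_pairs(seq, min_loop))
    return [parse_dotbracket(db) for db in dbs]


def delta_max_neighbors(seq: RnaSequence, min_loop: int = MIN_LOOP) -> int:
    """The normalization constant Δ = max_x |M(x)|.

    For the single add/remove move set this equals the number of admissible
    pairs: the open chain attains it, and any structure's neighbor count is
    bounded by it (each move corresponds to one admissible pair).
    """
    return len(admissible_pairs(seq, min_loop))


def structure_order_key(s, energy: float):
    """Total ordering key (energy, string encoding).

    Energy compares first; ties break byte-wise on the dot-bracket string
    ('(' < ')' < '.' in ASCII), giving a strict total order on distinct
    structures and a deterministic resolution of energy degeneracy.
    """
    enc = s.dot_bracket if isinstance(s, SecondaryStructure) else str(s)
    return (energy, enc)


# ---------------------------------------------------------------------------
# energy backends

class SimplePairEnergy:
    """Additive pair-energy model in arbitrary units.

    E(s) is the sum over base pairs of -3 (G-C), -2 (A-U), -1 (G-U); the
    open chain scores exactly 0. Deterministic and dependency free; this is
    deliberately NOT the nearest-neighbor (Turner) model and full-scale
    thermodynamic numbers require :class:`ViennaBackend`.
    """

    name = "simple"
    units = "arbitrary"
    parameters = SIMPLE_PAIR_TABLE

    def evaluate(self, seq: RnaSequence, s: SecondaryStructure) -> float:
        rep = validate_structure(seq, s)
        if not rep.ok:
            raise StructureError("; ".join(rep.violations))
        return self.evaluate_db(seq.bases, s.dot_bracket)

    @staticmethod
    def evaluate_db(bases: str, db: str) -> float:
        e = 0.0
        for i, j in _db_pairs(db):
            e += SIMPLE_PAIR_TABLE[frozenset({bases[i - 1], bases[j - 1]})]
        return e

    def describe(self) -> dict:
        return {"backend": self.name, "units": self.units,
                "parameters": {"GC": -3.0, "AU": -2.0, "GU": -1.0}}


class ViennaBackend:
    """Nearest-neighbor free-energy backend via the ViennaRNA bindings.

    Energies are full loop-decomposition free energies in kcal/mol at the
    model temperature (default 37 C). The binding version is recorded so
    outputs carry their parameter provenance.
    """

    name = "vienna-nn"
    units = "kcal/mol"

    def __init__(self, temperature: float = 37.0):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - depends on env
            raise BackendUnavailableError(
                "ViennaRNA python bindings ('RNA') not importable; "
                "the nearest-neighbor backend is unavailable"
            ) from exc
        self._RNA = RNA
        self.temperature = temperature
        md = RNA.md()
        md.temperature = temperature
        self._md = md
        self.version = RNA.__version__
        self._fc_cache = {}

    def _fc(self, bases: str):
        fc = self._fc_cache.get(bases)
        if fc is None:
            fc = self._RNA.fold_compound(bases, self._md)
            self._fc_cache[bases] = fc
        return fc

    def evaluate(self, seq: RnaSequence, s: SecondaryStructure) -> float:
        return self.evaluate_db(seq.bases, s.dot_bracket)

    def evaluate_db(self, bases: str, db: str) -> float:
        if "(" not in db:
            return 0.0  # open-chain convention shared by both backends
        return round(self._fc(bases).eval_structure(db), 2)

    def describe(self) -> dict:
        return {"backend": self.name, "units": self.units,
                "viennarna_version": self.version,
                "temperature_C": self.temperature}


def simple_pair_energy(seq: RnaSequence, s: SecondaryStructure) -> float:
    """Energy of ``s`` under the built-in additive pair table."""
    return SimplePairEnergy().evaluate(seq, s)


def external_energy(
    seq: RnaSequence, s: SecondaryStructure, temperature: float = 37.0
) -> float:
    """Nearest-neighbor free energy (kcal/mol) via the ViennaRNA backend.

    Raises :class:`BackendUnavailableError` when the bindings are missing;
    there is no silent fallback to the built-in model.
    """
    return ViennaBackend(temperature=temperature).evaluate(seq, s)
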