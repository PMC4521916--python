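"""Minimum-free-energy folding behind a pluggable engine contract.

Two engines are provided:

* ``builtin`` -- a Nussinov-style dynamic program with simple pair scores
  (GC -3, AU -2, GU -1, arbitrary energy units reported as dG) and a
  minimum hairpin loop of 3 unpaired nucleotides.  Fully deterministic and
  small enough to verify against exhaustive enumeration, which makes it the
  engine of choice for tests and toy problems.
* ``vienna`` -- the ViennaRNA thermodynamic model (RNAfold), used for
  biological runs when the Python bindings are importable.

Both return a structure whose length equals the sequence length, and both
are deterministic for a fixed input, which the design and vetting stages
rely on.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

from .structures import (
    RnaSequence,
    SecondaryStructure,
    base_pair_distance,
    parse_dotbracket,
)

#: Pair scores of the built-in engine (arbitrary energy units).
PAIR_SCORES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

#: Minimum number of unpaired nucleotides enclosed by any pair.
MIN_HAIRPIN = 3


@runtime_checkable
class FoldEngine(Protocol):
    name: str

    def fold(self, seq: RnaSequence) -> tuple[SecondaryStructure, float]:
        ...


class NussinovEngine:
    """Deterministic base-pair-maximization folding with weighted pairs.

    Recurrence over intervals [i, j]:

        E(i, j) = min( E(i+1, j),
                       min_k  s(i, k) + E(i+1, k-1) + E(k+1, j) )

    with pairing of i to k allowed only for k - i > MIN_HAIRPIN.  The
    traceback prefers pairing the 5'-most position whenever pairing attains
    the optimum, taking the smallest such partner -- one deterministic
    optimal structure among possible ties.

    A per-instance cache keyed by the residue string makes repeated folds of
    the same sequence (ubiquitous during annealing) free.
    """

    name = "builtin"

    def __init__(self, cache_size: int = 50000):
        self._cache: dict[str, tuple[str, float]] = {}
        self._cache_size = cache_size

    def fold(self, seq: RnaSequence) -> tuple[SecondaryStructure, float]:
        s = seq.residues
        hit = self._cache.get(s)
        if hit is not None:
            db, dg = hit
            return parse_dotbracket(db), dg
        db, dg = self._fold_string(s)
        if len(self._cache) >= self._cache_size:
            self._cache.clear()
        self._cache[s] = (db, dg)
        return parse_dotbracket(db), dg

    @staticmethod
    def _fold_string(s: str) -> tuple[str, float]:
        n = len(s)
        if n <= MIN_HAIRPIN + 1:
            return "." * n, 0.0
        E = [[0.0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i + 1][j]
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    sc = PAIR_SCORES.get((s[i], s[k]))
                    if sc is None:
                        continue
                    inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                    right = E[k + 1][j] if k + 1 <= j else 0.0
                    cand = sc + inner + right
                    if cand < best:
                        best = cand
                E[i][j] = best

        chars = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            paired = False
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                sc = PAIR_SCORES.get((s[i], s[k]))
                if sc is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                right = E[k + 1][j] if k + 1 <= j else 0.0
                if sc + inner + right == E[i][j]:
                    chars[i], chars[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    paired = True
                    break
            if not paired:
                stack.append((i + 1, j))
        return "".join(chars), E[0][n - 1]

    @staticmethod
    def score_structure(seq: RnaSequence, structure: SecondaryStructure) -> float:
        """Recompute the built-in energy of a given structure."""
        s = seq.residues
        total = 0.0
        for i, j in structure.pairs:
            sc = PAIR_SCORES.get((s[i], s[j]))
            if sc is None:
                raise ValueError(f"non-canonical pair {s[i]}-{s[j]} at ({i}, {j})")
            total += sc
        return total


class ViennaEngine:
    """MFE folding with the ViennaRNA thermodynamic model (kcal/mol)."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "ViennaRNA Python bindings not importable; "
                "install the viennarna package or use engine='builtin'"
            ) from exc
        self._RNA = RNA
        self._cache: dict[str, tuple[str, float]] = {}

    def fold(self, seq: RnaSequence) -> tuple[SecondaryStructure, float]:
        s = seq.residues
        hit = self._cache.get(s)
        if hit is None:
            db, dg = self._RNA.fold(s)
            if len(self._cache) >= 50000:
                self._cache.clear()
            self._cache[s] = hit = (db, float(dg))
        return parse_dotbracket(hit[0]), hit[1]


_ENGINES = {"builtin": NussinovEngine, "vienna": ViennaEngine}


def get_engine(name: str) -> FoldEngine:
    """Instantiate an engine by name (``builtin`` or ``vienna``)."""
    try:
        cls = _ENGINES[name]
    except KeyError:
        raise ValueError(
            f"unknown engine {name!r}; choose from {sorted(_ENGINES)}"
        ) from None
    return cls()


def fold_mfe(seq: RnaSequence, engine: FoldEngine) -> tuple[SecondaryStructure, float]:
    """The engine's MFE structure and free energy for ``seq``."""
    structure, dg = engine.fold(seq)
    if len(structure) != len(seq):
        raise RuntimeError(
            f"engine {engine.name!r} returned structure of wrong length"
        )
    return structure, dg


def structure_preserved(
    seq: RnaSequence,
    reference: SecondaryStructure,
    engine: FoldEngine,
    tol_bp: int = 0,
) -> bool:
    """True iff the sequence refolds to within ``tol_bp`` base pairs of
    the reference structure."""
    if len(seq) != len(reference):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(reference)}"
        )
    predicted, _ = fold_mfe(seq, engine)
    return base_pair_distance(predicted, reference) <= tol_bp
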