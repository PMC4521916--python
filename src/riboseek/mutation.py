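"""Escape-the-well mutation operators.

A known aptamer sits at the bottom of a similarity "well": any database
search returns its own loci.  To sample sequence space beyond that well,
the sequence is mutated until the search returns nothing, and the inverse
folding solver (or, in the structure-strict special case, compensatory
mutations alone) then walks back toward sequences that restore the
aptamer's structure.

Two escape operators are provided: unconstrained single-point mutation
(``random_escape``, general mode) and structure-preserving covariant
mutation (``covariant_escape``, special-case mode).  ``covariant_mutate``
performs one verified structure-preserving move: either a base pair is
rewritten as a different canonical pair (compensatory change) or an
unpaired position is substituted, and the mutant is kept only if its
refold is base-pair identical to the reference structure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .folding import FoldEngine, fold_mfe
from .search import SearchDatabase, SearchParams, count_hits
from .structures import (
    CANONICAL_PAIRS,
    WATSON_CRICK_PAIRS,
    RnaSequence,
    SecondaryStructure,
    base_pair_distance,
    hamming_distance,
)

NUCLEOTIDES = "ACGU"


@dataclass
class EscapeTrace:
    """The mutation path from a hit-producing start to a zero-hit end."""

    start: RnaSequence
    end: RnaSequence
    mutation_path: list = field(default_factory=list)  # (position, from, to)
    hits_at_each_step: list = field(default_factory=list)
    #: substitutions per accepted move: a covariant pair rewrite is one move
    #: spanning two path entries; plain escapes have all-ones
    move_lengths: list = field(default_factory=list)

    def intermediates(self) -> list[str]:
        """Residue strings after each substitution (excluding the start)."""
        chars = list(self.start.residues)
        out = []
        for pos, _frm, to in self.mutation_path:
            chars[pos] = to
            out.append("".join(chars))
        return out

    def move_intermediates(self) -> list[str]:
        """Residue strings after each complete move.

        For covariant traces these are the structure-preserving waypoints
        (both halves of a pair rewrite applied); for plain traces this
        equals :meth:`intermediates`.
        """
        per_sub = self.intermediates()
        if not self.move_lengths:
            return per_sub
        out = []
        idx = -1
        for n in self.move_lengths:
            idx += n
            out.append(per_sub[idx])
        return out

    def verify(self) -> bool:
        """Path replay consistency: applying the path to start yields end."""
        seqs = self.intermediates()
        final = seqs[-1] if seqs else self.start.residues
        return final == self.end.residues and hamming_distance(
            self.start, self.end
        ) <= len(self.mutation_path)


class EscapeBudgetError(RuntimeError):
    """Mutation budget exhausted while the database still returns hits."""

    def __init__(self, message: str, trace: EscapeTrace):
        super().__init__(message)
        self.trace = trace


def random_escape(
    seq: RnaSequence,
    db: SearchDatabase,
    params: SearchParams,
    rng: random.Random,
    max_mutations: int | None = None,
) -> EscapeTrace:
    """Mutate single positions uniformly at random until zero hits.

    Each step changes one uniformly chosen position to a uniformly chosen
    different nucleotide, then re-queries the database.  The default budget
    is 3L mutations.  A query that already has no hits returns a length-0
    trace.
    """
    if not db.records:
        raise ValueError("cannot escape from an empty database")
    if max_mutations is None:
        max_mutations = 3 * len(seq)

    def step_fn(chars: list[str], r: random.Random):
        pos = r.randrange(len(chars))
        old = chars[pos]
        new = r.choice([n for n in NUCLEOTIDES if n != old])
        chars[pos] = new
        return pos, old, new

    return _escape_loop(seq, db, params, rng, max_mutations, step_fn)


def covariant_escape(
    seq: RnaSequence,
    structure: SecondaryStructure,
    db: SearchDatabase,
    params: SearchParams,
    rng: random.Random,
    engine: FoldEngine,
    max_mutations: int | None = None,
    allow_wobble: bool = True,
) -> EscapeTrace:
    """Escape using only structure-preserving (covariant) mutations.

    Every intermediate along the trace refolds exactly to ``structure``.
    Pair rewrites contribute one or two path entries (one per changed
    position) so the trace remains a plain substitution list.
    """
    if not db.records:
        raise ValueError("cannot escape from an empty database")
    if max_mutations is None:
        max_mutations = 3 * len(seq)

    def step_fn(chars: list[str], r: random.Random):
        before = "".join(chars)
        mutant = covariant_mutate(
            seq.with_residues(before),
            structure,
            r,
            engine,
            allow_wobble=allow_wobble,
        )
        edits = []
        for pos, (old, new) in enumerate(zip(before, mutant.residues)):
            if old != new:
                chars[pos] = new
                edits.append((pos, old, new))
        return edits

    return _escape_loop(seq, db, params, rng, max_mutations, step_fn)


def _escape_loop(seq, db, params, rng, max_mutations, step_fn):
    hits = count_hits(seq, db, params)
    trace = EscapeTrace(start=seq, end=seq)
    chars = list(seq.residues)
    mutations = 0
    while hits > 0:
        if mutations >= max_mutations:
            raise EscapeBudgetError(
                f"still {hits} hit(s) after {mutations} mutations",
                trace,
            )
        out = step_fn(chars, rng)
        edits = out if isinstance(out, list) else [out]
        trace.mutation_path.extend(edits)
        trace.move_lengths.append(len(edits))
        mutations += len(edits)
        current = seq.with_residues("".join(chars))
        hits = count_hits(current, db, params)
        trace.hits_at_each_step.extend(
            [trace.hits_at_each_step[-1] if trace.hits_at_each_step else hits]
            * (len(edits) - 1)
            + [hits]
        )
        trace.end = current
    return trace


class CovariantMoveError(RuntimeError):
    """No structure-preserving mutation found within the retry budget."""


def covariant_mutate(
    seq: RnaSequence,
    structure: SecondaryStructure,
    rng: random.Random,
    engine: FoldEngine,
    max_retries: int = 60,
    allow_wobble: bool = True,
) -> RnaSequence:
    """One verified structure-preserving mutation of ``seq``.

    A mutation site is drawn uniformly over all sites (each base pair of
    ``structure`` counts as one site, each unpaired position as one); pairs
    are rewritten as a different pair from the canonical set (GU/UG wobble
    included unless ``allow_wobble`` is false), unpaired positions as a
    different nucleotide.  The move is re-drawn until the mutant's refold
    under ``engine`` has base-pair distance 0 to ``structure``.
    """
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    pair_set = sorted(CANONICAL_PAIRS if allow_wobble else WATSON_CRICK_PAIRS)
    partner = structure.partner
    pair_sites = sorted(structure.pairs)
    loop_sites = [i for i in range(len(seq)) if i not in partner]
    sites = [("p", s) for s in pair_sites] + [("u", s) for s in loop_sites]
    if not sites:
        raise CovariantMoveError("sequence has no mutable site")

    for _ in range(max_retries):
        kind, site = rng.choice(sites)
        chars = list(seq.residues)
        if kind == "p":
            i, j = site
            old = (chars[i], chars[j])
            options = [p for p in pair_set if p != old]
            if not options:
                continue
            chars[i], chars[j] = rng.choice(options)
        else:
            old_nt = chars[site]
            chars[site] = rng.choice([n for n in NUCLEOTIDES if n != old_nt])
        mutant = seq.with_residues("".join(chars))
        folded, _ = fold_mfe(mutant, engine)
        if base_pair_distance(folded, structure) == 0:
            return mutant
    raise CovariantMoveError(
        f"no structure-preserving mutation found in {max_retries} tries"
    )


def restore_region(
    mutated: RnaSequence, original: RnaSequence, region: tuple[int, int]
) -> RnaSequence:
    """Splice the original residues back over ``region`` (0-based half-open).

    Used to walk a fully escaped sequence back to the borderline of the
    similarity well by restoring a chosen segment toward the wild type.
    """
    if len(mutated) != len(original):
        raise ValueError("sequence lengths differ")
    start, end = region
    if not (0 <= start <= end <= len(mutated)):
        raise ValueError(f"invalid region {region} for length {len(mutated)}")
    residues = (
        mutated.residues[:start]
        + original.residues[start:end]
        + mutated.residues[end:]
    )
    return mutated.with_residues(residues, suffix="|restored")
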