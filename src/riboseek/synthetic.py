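"""Synthetic genomes with planted aptamer homologs.

The fixture generator emulates the search scenario the pipeline is built
for: genomes (uniform-random nucleotide background) carrying aptamer
homologs that are *sequence-diverged but structure-preserved*, produced by
chains of verified covariant mutations, embedded at known coordinates on
either strand.  A truth table records every planted interval, so recall
and specificity of the full pipeline are measurable.

Defaults reflect the regime in which real distant homologs of a ~70-nt
aptamer are found: 12 covariant steps give roughly 75-85% sequence
identity to the query, comparable to the identities of genuine
cross-species aptamer matches, while leaving the predicted structure
exactly intact.  Scrambled decoys (same composition, shuffled order) can
be planted alongside to measure false acceptance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .folding import FoldEngine, fold_mfe, structure_preserved
from .mutation import covariant_mutate
from .search import revcomp
from .structures import RnaSequence, SecondaryStructure, hamming_distance, parse_dotbracket


@dataclass
class PlantedTruth:
    """Ground truth for one planted sequence."""

    record_id: str
    start: int  # 0-based half-open, plus strand
    end: int
    strand: str
    kind: str  # "homolog" or "scrambled"
    hamming_to_query: int
    planted_sequence: str  # RNA letters, reading orientation


def diverge_covariant(
    aptamer: RnaSequence,
    structure: SecondaryStructure,
    steps: int,
    rng: random.Random,
    engine: FoldEngine,
) -> RnaSequence:
    """A homolog ``steps`` verified covariant mutations away.

    Every step is re-checked by refolding, so the result's predicted
    structure is base-pair identical to ``structure``.  ``steps`` counts
    accepted moves (a pair rewrite is one move even when it changes two
    residues), so the Hamming distance is at most ``2 * steps``.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    current = aptamer
    for _ in range(steps):
        current = covariant_mutate(current, structure, rng, engine)
    return current


def scramble(aptamer: RnaSequence, rng: random.Random) -> RnaSequence:
    """Same nucleotide composition, shuffled order (negative control)."""
    chars = list(aptamer.residues)
    rng.shuffle(chars)
    return aptamer.with_residues("".join(chars), suffix="|scrambled")


def generate_fixture(
    aptamer: RnaSequence,
    structure: SecondaryStructure,
    n_records: int = 3,
    record_length: int = 2000,
    n_planted: int = 1,
    n_scrambled: int = 0,
    divergence_steps: int = 12,
    rng_seed: int = 0,
    engine: FoldEngine | None = None,
) -> tuple[list[tuple[str, str]], list[PlantedTruth]]:
    """Random-background records with planted homologs at known coordinates.

    Returns ``(records, truth)`` where records are ``(id, DNA sequence)``
    and the truth table lists every planted interval, strand and kind.
    Homologs are covariant-diverged (structure verified by refolding);
    scrambled plants share composition only.  Plants never overlap.
    """
    if engine is None:
        from .folding import ViennaEngine

        engine = ViennaEngine()
    L = len(aptamer)
    if record_length < L:
        raise ValueError(
            f"record_length {record_length} shorter than aptamer length {L}"
        )
    rng = random.Random(rng_seed)
    backgrounds = [
        "".join(rng.choice("ACGT") for _ in range(record_length))
        for _ in range(n_records)
    ]
    plants: list[tuple[str, str]] = []  # (kind, rna residues)
    for _ in range(n_planted):
        hom = diverge_covariant(aptamer, structure, divergence_steps, rng, engine)
        assert structure_preserved(hom, structure, engine, tol_bp=0)
        plants.append(("homolog", hom.residues))
    for _ in range(n_scrambled):
        plants.append(("scrambled", scramble(aptamer, rng).residues))

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_records)}
    truth: list[PlantedTruth] = []
    records = [list(bg) for bg in backgrounds]
    for kind, residues in plants:
        placed = False
        for _attempt in range(200):
            ri = rng.randrange(n_records)
            start = rng.randrange(0, record_length - L + 1)
            if any(start < e and start + L > s for s, e in occupied[ri]):
                continue
            strand = rng.choice("+-")
            dna = residues.replace("U", "T")
            insert = dna if strand == "+" else revcomp(dna)
            records[ri][start : start + L] = insert
            occupied[ri].append((start, start + L))
            truth.append(
                PlantedTruth(
                    record_id=f"rec{ri + 1}",
                    start=start,
                    end=start + L,
                    strand=strand,
                    kind=kind,
                    hamming_to_query=hamming_distance(residues, aptamer.residues),
                    planted_sequence=residues,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place plant without overlap")
    out = [(f"rec{i + 1}", "".join(r)) for i, r in enumerate(records)]
    return out, truth


# ---------------------------------------------------------------------------
# random nested structures (design-benchmark targets)
# ---------------------------------------------------------------------------


def random_nested_structure(
    length: int, rng: random.Random, min_hairpin: int = 3
) -> SecondaryStructure:
    """A random valid nested structure with stem-loop architecture.

    Helices are 2-4 pairs, hairpin loops at least ``min_hairpin``
    nucleotides, with optional external tails, internal loops and (for
    long enough spans) two-branch multiloops.  Short spans come out
    unpaired.
    """
    return parse_dotbracket(_gen(length, rng, 0))


def _gen(n: int, rng: random.Random, depth: int) -> str:
    if n < 9:
        return "." * n
    if depth > 0 and rng.random() < 0.2:
        return "." * n
    pad5 = rng.randint(0, min(3, n - 9))
    pad3 = rng.randint(0, min(3, n - 9 - pad5))
    core = n - pad5 - pad3
    stem = rng.randint(2, min(4, (core - 3) // 2))
    loop = core - 2 * stem
    if loop >= 18 and rng.random() < 0.5:
        k = rng.randint(9, loop - 9)
        inside = _gen(k, rng, depth + 1) + _gen(loop - k, rng, depth + 1)
    elif loop >= 9 and rng.random() < 0.6:
        inside = _gen(loop, rng, depth + 1)
    else:
        inside = "." * loop
    return "." * pad5 + "(" * stem + inside + ")" * stem + "." * pad3
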