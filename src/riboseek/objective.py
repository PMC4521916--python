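"""The five-term design objective driving flexible inverse folding.

For a candidate sequence evaluated against the target (the original
aptamer sequence and structure), the cost is

    f = |neutrality_t - neutrality_c| * 100   (optional, default off)
      + |dG_t - dG_c| * 1                     (optional, default off)
      + motif_missing(candidate) * 1000
      + shapiro_tree_distance(t, c) * 100
      + base_pair_distance(t, c) * 0.01

The weights are fixed by design: the protected-motif term dominates
everything (a hard constraint in soft clothing), shape preservation via the
coarse-grained tree distance is the primary structural signal, and the
fine-grained base-pair term acts only as a tie-breaker so that solutions
are not over-dominated by shape.  Mutational-robustness (neutrality) and
thermodynamic-stability (dG) terms exist but default to disabled, since
homologs with different nucleotide composition may legitimately differ in
both.
"""

from __future__ import annotations

from dataclasses import dataclass

from .folding import FoldEngine, fold_mfe
from .shapiro import shapiro_distance
from .structures import (
    MotifConstraint,
    RnaSequence,
    SecondaryStructure,
    base_pair_distance,
)

NUCLEOTIDES = "ACGU"


@dataclass(frozen=True)
class ObjectiveWeights:
    """Fixed term weights plus enable flags for the optional terms."""

    w_neutrality: float = 100.0
    w_dG: float = 1.0
    w_motif: float = 1000.0
    w_shapiro: float = 100.0
    w_bp: float = 0.01
    enable_neutrality: bool = False
    enable_dG: bool = False


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Per-term contributions; ``total`` is their sum."""

    neutrality_term: float
    dG_term: float
    motif_term: float
    shapiro_term: float
    bp_term: float

    @property
    def total(self) -> float:
        return (
            self.neutrality_term
            + self.dG_term
            + self.motif_term
            + self.shapiro_term
            + self.bp_term
        )


def neutrality(seq: RnaSequence, engine: FoldEngine) -> float:
    """Mutational robustness in [0, 1].

    The mean over all 3L single-point mutants m of
    ``1 - bp_distance(fold(m), fold(seq)) / L``: 1 when every mutant folds
    identically, lower the more fragile the structure is.
    """
    wild, _ = fold_mfe(seq, engine)
    L = len(seq)
    total = 0.0
    count = 0
    for pos in range(L):
        for nt in NUCLEOTIDES:
            if nt == seq.residues[pos]:
                continue
            mutant = seq.with_residues(
                seq.residues[:pos] + nt + seq.residues[pos + 1 :]
            )
            folded, _ = fold_mfe(mutant, engine)
            total += 1.0 - base_pair_distance(folded, wild) / L
            count += 1
    value = total / count
    return min(1.0, max(0.0, value))


def motif_missing(candidate: SecondaryStructure, c: MotifConstraint | None) -> int:
    """Penalty indicator: 0 iff the candidate reproduces the protected
    fragment's dot-bracket exactly over the constraint region, else 1.

    No constraint (None or empty region) counts as satisfied.
    """
    if c is None or c.region[0] == c.region[1]:
        return 0
    start, end = c.region
    if end > len(candidate):
        raise ValueError(
            f"constraint region {c.region} out of range for length {len(candidate)}"
        )
    return 0 if candidate.dotbracket[start:end] == c.required_substructure else 1


def evaluate_objective(
    candidate: tuple[RnaSequence, SecondaryStructure, float],
    target: tuple[RnaSequence, SecondaryStructure, float],
    c: MotifConstraint | None = None,
    w: ObjectiveWeights = ObjectiveWeights(),
    engine: FoldEngine | None = None,
    target_neutrality: float | None = None,
) -> ObjectiveBreakdown:
    """Evaluate the full objective for a (sequence, structure, dG) candidate
    against the target triple.

    ``engine`` is only needed when the neutrality term is enabled (the
    neutrality of both sequences is computed with it; ``target_neutrality``
    may be supplied to avoid recomputing the target's value).
    """
    cand_seq, cand_struct, cand_dg = candidate
    targ_seq, targ_struct, targ_dg = target
    if len(cand_struct) != len(targ_struct):
        raise ValueError(
            f"candidate/target lengths differ "
            f"({len(cand_struct)} vs {len(targ_struct)})"
        )

    neut_term = 0.0
    if w.enable_neutrality:
        if engine is None:
            raise ValueError("neutrality term enabled but no engine supplied")
        nt_t = (
            target_neutrality
            if target_neutrality is not None
            else neutrality(targ_seq, engine)
        )
        nt_c = neutrality(cand_seq, engine)
        neut_term = abs(nt_t - nt_c) * w.w_neutrality

    dg_term = abs(targ_dg - cand_dg) * w.w_dG if w.enable_dG else 0.0
    motif_term = motif_missing(cand_struct, c) * w.w_motif
    shapiro_term = shapiro_distance(targ_struct, cand_struct) * w.w_shapiro
    bp_term = base_pair_distance(targ_struct, cand_struct) * w.w_bp
    return ObjectiveBreakdown(
        neutrality_term=neut_term,
        dG_term=dg_term,
        motif_term=motif_term,
        shapiro_term=shapiro_term,
        bp_term=bp_term,
    )
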