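"""Flexible inverse folding by simulated annealing.

Given a target structure (and the aptamer sequence it came from), the
solver mutates a seed sequence to minimize the five-term objective of
:mod:`riboseek.objective`: reproduce the coarse-grained shape, keep the
protected fragment's secondary structure exactly, and respect fixed
nucleotides.

Move set
--------
Elementary moves are biased toward the target's pairing pattern: positions
unpaired in the target receive single-nucleotide substitutions, while
positions paired in the target are rewritten as whole pairs drawn from
{AU, UA, GC, CG, GU, UG}.  Fixed positions are never touched (a fixed
nucleotide inside a target pair restricts that pair's legal rewrites).

Look-ahead
----------
Each iteration samples up to ``lookahead_width`` (default 4) elementary
moves at distinct sites and evaluates the nested bundles move[:1],
move[:2], ... -- a greedy beam over 1..4-site joint mutations.  The best
bundle is then accepted or rejected by the Metropolis rule at the current
temperature; temperature follows a geometric cooling schedule.  The search
stops early once the objective reaches zero, and always returns the best
sequence visited.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .folding import FoldEngine, fold_mfe
from .objective import (
    NUCLEOTIDES,
    ObjectiveBreakdown,
    ObjectiveWeights,
    evaluate_objective,
    neutrality,
)
from .structures import (
    CANONICAL_PAIRS,
    MotifConstraint,
    RnaSequence,
    SecondaryStructure,
)

_PAIR_CHOICES = sorted(CANONICAL_PAIRS)


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing control parameters.

    ``max_iterations`` bounds the number of objective evaluations (each
    bundle member evaluated counts as one).
    """

    initial_temperature: float = 0.05
    cooling_factor: float = 0.95
    steps_per_temperature: int = 50
    max_iterations: int = 10_000
    lookahead_width: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.lookahead_width < 1:
            raise ValueError("lookahead_width must be >= 1")
        if self.max_iterations < 1 or self.steps_per_temperature < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class DesignResult:
    """A designed sequence with its refolded structure and objective."""

    sequence: RnaSequence
    structure: SecondaryStructure
    dG: float
    breakdown: ObjectiveBreakdown
    iterations_used: int
    seed_sequence_id: str
    converged: bool
    budget_exhausted: bool = False
    multiplicity: int = 1

    @property
    def objective(self) -> float:
        return self.breakdown.total


def _legal_sites(
    target: SecondaryStructure, c: MotifConstraint | None
) -> tuple[list[int], list[tuple[int, int]]]:
    """Mutable unpaired positions and mutable target pairs."""
    fixed = set(c.fixed_positions) if c else set()
    partner = target.partner
    unpaired = [
        i for i in range(len(target)) if i not in partner and i not in fixed
    ]
    pairs = []
    for i, j in sorted(target.pairs):
        if i in fixed and j in fixed:
            continue
        pairs.append((i, j))
    return unpaired, pairs


def _apply_fixed(residues: str, c: MotifConstraint | None) -> str:
    if not c or not c.fixed_positions:
        return residues
    chars = list(residues)
    for pos, nt in c.fixed_positions.items():
        if pos >= len(chars):
            raise ValueError(f"fixed position {pos} outside sequence")
        chars[pos] = nt.upper().replace("T", "U")
    return "".join(chars)


def _pair_options(i: int, j: int, fixed: dict) -> list[tuple[str, str]]:
    opts = _PAIR_CHOICES
    fi = fixed.get(i)
    fj = fixed.get(j)
    if fi is not None:
        opts = [p for p in opts if p[0] == fi]
    if fj is not None:
        opts = [p for p in opts if p[1] == fj]
    return opts


def inverse_fold(
    target_structure: SecondaryStructure,
    target_sequence: RnaSequence,
    seed: RnaSequence,
    constraint: MotifConstraint | None,
    sched: AnnealSchedule,
    engine: FoldEngine,
    weights: ObjectiveWeights = ObjectiveWeights(),
) -> DesignResult:
    """Anneal ``seed`` toward sequences that restore the target structure.

    Deterministic for a fixed ``sched.rng_seed``.  Fixed positions are
    overridden in the seed before the first iteration and never mutated.
    Returns the best-objective sequence visited (refolded), flagging
    whether it reached objective zero and whether the evaluation budget
    ran out first.
    """
    if len(seed) != len(target_structure):
        raise ValueError(
            f"seed length {len(seed)} != target structure length "
            f"{len(target_structure)}"
        )
    if constraint is not None:
        constraint.validate_against(target_structure, len(seed))
    fixed = dict(constraint.fixed_positions) if constraint else {}
    for pos, nt in fixed.items():
        fixed[pos] = nt.upper().replace("T", "U")
    # a fixed pair must have at least one legal rewrite left
    for i, j in target_structure.pairs:
        if i in fixed or j in fixed:
            if not _pair_options(i, j, fixed):
                raise ValueError(
                    f"fixed nucleotides at pair ({i}, {j}) admit no canonical pair"
                )

    rng = random.Random(sched.rng_seed)
    targ_dg = fold_mfe(target_sequence, engine)[1] if weights.enable_dG else 0.0
    targ_neut = (
        neutrality(target_sequence, engine) if weights.enable_neutrality else None
    )
    target_triple = (target_sequence, target_structure, targ_dg)

    def evaluate(residues: str) -> tuple[ObjectiveBreakdown, SecondaryStructure, float]:
        seq = seed.with_residues(residues)
        structure, dg = fold_mfe(seq, engine)
        bd = evaluate_objective(
            (seq, structure, dg),
            target_triple,
            constraint,
            weights,
            engine=engine,
            target_neutrality=targ_neut,
        )
        return bd, structure, dg

    unpaired_sites, pair_sites = _legal_sites(target_structure, constraint)
    sites = [("u", p) for p in unpaired_sites] + [("p", p) for p in pair_sites]

    start_residues = _apply_fixed(seed.residues, constraint)

    def seed_hamming(residues: str) -> int:
        return sum(a != b for a, b in zip(residues, start_residues))

    current = start_residues
    evals = 0
    bd, structure, dg = evaluate(current)
    evals += 1
    current_f = bd.total
    best = (current, bd, structure, dg)

    temperature = sched.initial_temperature
    step = 0
    while best[1].total > 0 and evals < sched.max_iterations and sites:
        k = min(sched.lookahead_width, len(sites))
        chosen = rng.sample(sites, k)
        # realize one elementary mutation per chosen site
        edits: list[list[tuple[int, str]]] = []
        for kind, site in chosen:
            if kind == "u":
                old = current[site]
                edits.append(
                    [(site, rng.choice([n for n in NUCLEOTIDES if n != old]))]
                )
            else:
                i, j = site
                old_pair = (current[i], current[j])
                opts = [
                    p for p in _pair_options(i, j, fixed) if p != old_pair
                ] or _pair_options(i, j, fixed)
                # half the time restrict to minimal-edit rewrites (repair one
                # broken side of a pair and keep the other) -- the solver's
                # job is a minimal set of directed mutations, not a
                # resampling of the helix
                if rng.random() < 0.5:
                    min_edits = min(
                        (p[0] != current[i]) + (p[1] != current[j]) for p in opts
                    )
                    opts = [
                        p
                        for p in opts
                        if (p[0] != current[i]) + (p[1] != current[j]) == min_edits
                    ]
                a, b = rng.choice(opts)
                edits.append([(i, a), (j, b)])

        def apply_edits(base: str, edit_lists) -> str:
            chars = list(base)
            for el in edit_lists:
                for pos, nt in el:
                    chars[pos] = nt
            return "".join(chars)

        def rank_key(item):
            # (objective, distance to seed): clean moves beat junk riders
            return (item[1].total, seed_hamming(item[0]))

        # stage 1: each elementary move alone -- accept a clean improvement
        best_bundle = None
        for el in edits:
            if evals >= sched.max_iterations:
                break
            cand = apply_edits(current, [el])
            cbd, cstruct, cdg = evaluate(cand)
            evals += 1
            item = (cand, cbd, cstruct, cdg)
            if best_bundle is None or rank_key(item) < rank_key(best_bundle):
                best_bundle = item
        # stage 2: no single move improves -> joint bundles (the look-ahead
        # proper), composing 2..k moves to step across objective plateaus
        if (
            best_bundle is not None
            and best_bundle[1].total >= current_f
            and len(edits) > 1
        ):
            for depth in range(2, len(edits) + 1):
                if evals >= sched.max_iterations:
                    break
                cand = apply_edits(current, edits[:depth])
                cbd, cstruct, cdg = evaluate(cand)
                evals += 1
                item = (cand, cbd, cstruct, cdg)
                if rank_key(item) < rank_key(best_bundle):
                    best_bundle = item
        if best_bundle is None:
            break

        delta = best_bundle[1].total - current_f
        if delta == 0:
            # objective plateaus are huge (any sequence with the right
            # structure ties); free neutral drift would diffuse away from
            # the seed, so neutral moves may not increase seed distance
            accept = seed_hamming(best_bundle[0]) <= seed_hamming(current)
        else:
            accept = delta < 0 or rng.random() < _safe_exp(-delta / temperature)
        if accept:
            current = best_bundle[0]
            current_f = best_bundle[1].total
            # prefer strictly better objectives; on ties keep the candidate
            # closest to the seed -- the solver's purpose is a *minimal*
            # set of directed mutations restoring the structure
            if current_f < best[1].total or (
                current_f == best[1].total
                and seed_hamming(current) < seed_hamming(best[0])
            ):
                best = best_bundle
        step += 1
        if step % sched.steps_per_temperature == 0:
            temperature *= sched.cooling_factor

    best_res, best_bd, best_struct, best_dg = best
    return DesignResult(
        sequence=seed.with_residues(best_res),
        structure=best_struct,
        dG=best_dg,
        breakdown=best_bd,
        iterations_used=evals,
        seed_sequence_id=seed.id,
        converged=best_bd.total == 0,
        budget_exhausted=evals >= sched.max_iterations and best_bd.total > 0,
    )


def _safe_exp(x: float) -> float:
    import math

    if x < -700:
        return 0.0
    return math.exp(x)


def run_rng_seed(base_seed: int, seed_index: int, run_index: int) -> int:
    """Deterministic per-run RNG seed below 2^31."""
    return (base_seed * 2_654_435_761 + seed_index * 9_973 + run_index) % (2**31 - 1)


def design_batch(
    target_structure: SecondaryStructure,
    target_sequence: RnaSequence,
    seeds: list[RnaSequence],
    runs_per_seed: int,
    constraint: MotifConstraint | None,
    sched: AnnealSchedule,
    engine: FoldEngine,
    weights: ObjectiveWeights = ObjectiveWeights(),
) -> list[DesignResult]:
    """Run the solver ``runs_per_seed`` times from every seed.

    Each run gets an independent RNG seed derived deterministically from
    (schedule seed, seed index, run index).  Results identical in sequence
    are collapsed; ``multiplicity`` records how many runs produced each,
    so multiplicities sum to ``len(seeds) * runs_per_seed``.
    """
    if not seeds:
        raise ValueError("design_batch requires at least one seed sequence")
    if runs_per_seed < 1:
        raise ValueError("runs_per_seed must be >= 1")
    collapsed: dict[str, DesignResult] = {}
    order: list[str] = []
    for si, seed in enumerate(seeds):
        for ri in range(runs_per_seed):
            run_sched = replace(
                sched, rng_seed=run_rng_seed(sched.rng_seed, si, ri)
            )
            res = inverse_fold(
                target_structure,
                target_sequence,
                seed,
                constraint,
                run_sched,
                engine,
                weights,
            )
            key = res.sequence.residues
            if key in collapsed:
                collapsed[key].multiplicity += 1
            else:
                collapsed[key] = res
                order.append(key)
    return [collapsed[k] for k in order]
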