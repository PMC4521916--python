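"""End-to-end orchestration: escape, design, search, vet, report.

Two modes mirror the two arms of the method:

* **general** -- random single-point escape mutations followed by the
  flexible inverse-folding solver, which restores the aptamer's shape
  while leaving fine structure free to drift.  Samples the widest region
  of sequence space.
* **covariant** -- the structure-strict special case: escape and return
  both use verified compensatory mutations only, so every designed
  sequence folds *exactly* to the query structure.  Much cheaper, covers a
  smaller neighbourhood; the designed set is the escape endpoint plus the
  restoration walk back to the borderline where database similarity
  reappears.

Both modes then search every unique designed sequence against the
database, cut aptamer-sized windows around the hits, fold and vet them
structurally, and return ranked candidate reports.  Windows identical to
the query sequence are reported as "known" rather than novel candidates.
All randomness flows from one seed; identical config + seed reproduces
identical reports.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .candidates import (
    CandidateReport,
    assess,
    extract_window,
    rank_candidates,
    write_report_tsv,
)
from .design import AnnealSchedule, design_batch, run_rng_seed
from .folding import FoldEngine, fold_mfe, get_engine
from .io import write_fasta
from .mutation import EscapeBudgetError, covariant_escape, random_escape
from .objective import ObjectiveWeights
from .search import SearchDatabase, SearchParams, search, write_tabular
from .shapiro import shapiro_distance
from .structures import (
    MotifConstraint,
    RnaSequence,
    SecondaryStructure,
    base_pair_distance,
)
from .synthetic import generate_fixture  # re-exported: fixture generation is a pipeline service

__all__ = [
    "PipelineConfig",
    "PreflightReport",
    "StageError",
    "preflight",
    "run",
    "run_general",
    "run_covariant",
    "generate_fixture",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and replay seed."""

    def __init__(self, stage: str, seed: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed (replay seed {seed}): {cause}")
        self.stage = stage
        self.seed = seed
        self.cause = cause


@dataclass
class PipelineConfig:
    query: RnaSequence
    reference_structure: SecondaryStructure
    database: SearchDatabase
    constraint: MotifConstraint | None = None
    mode: str = "general"
    n_escape_sequences: int = 500
    runs_per_seed: int = 20
    search_params: SearchParams = field(default_factory=SearchParams)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    engine_name: str = "vienna"
    rng_seed: int = 0
    max_shapiro: int = 2
    escape_budget: int | None = None
    output_dir: Path | None = None

    def __post_init__(self):
        if self.n_escape_sequences < 1:
            raise ValueError("n_escape_sequences must be >= 1")
        if self.runs_per_seed < 1:
            raise ValueError("runs_per_seed must be >= 1")
        if self.mode not in ("general", "covariant"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.query) != len(self.reference_structure):
            raise ValueError("query and reference structure lengths differ")
        if self.constraint is not None:
            self.constraint.validate_against(
                self.reference_structure, len(self.query)
            )


@dataclass
class PreflightReport:
    bp_distance: int
    shapiro_distance: int
    query_hits: int
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.warnings


def preflight(config: PipelineConfig, engine: FoldEngine | None = None) -> PreflightReport:
    """Sanity checks before a run: does the query refold to its reference
    structure, and does it have known locations in the database?

    Failures warn rather than abort -- a poor fold or an empty hit list
    degrades the search but does not make it meaningless.
    """
    engine = engine or get_engine(config.engine_name)
    predicted, _ = fold_mfe(config.query, engine)
    bp = base_pair_distance(predicted, config.reference_structure)
    shap = shapiro_distance(predicted, config.reference_structure)
    n_hits = len(search(config.query, config.database, config.search_params))
    warnings = []
    if shap > config.max_shapiro:
        warnings.append(
            f"query fold deviates from reference (shapiro {shap} > {config.max_shapiro})"
        )
    if n_hits == 0:
        warnings.append("query has no database hits (nothing to escape from)")
    return PreflightReport(bp, shap, n_hits, warnings)


def run(config: PipelineConfig) -> list[CandidateReport]:
    """Dispatch on ``config.mode``."""
    if config.mode == "covariant":
        return run_covariant(config)
    return run_general(config)


def run_general(config: PipelineConfig) -> list[CandidateReport]:
    """Random escape, inverse-folding restoration, search and vetting."""
    engine = get_engine(config.engine_name)
    seeds: list[RnaSequence] = []
    for k in range(config.n_escape_sequences):
        seed_k = run_rng_seed(config.rng_seed, k, 0)
        rng = random.Random(seed_k)
        try:
            trace = random_escape(
                config.query,
                config.database,
                config.search_params,
                rng,
                max_mutations=config.escape_budget,
            )
        except EscapeBudgetError as exc:
            raise StageError("escape", seed_k, exc) from exc
        seeds.append(trace.end.with_residues(trace.end.residues, f"|esc{k}"))

    try:
        designs = design_batch(
            config.reference_structure,
            config.query,
            seeds,
            config.runs_per_seed,
            config.constraint,
            replace(config.schedule, rng_seed=config.rng_seed),
            engine,
            config.weights,
        )
    except Exception as exc:
        raise StageError("design", config.rng_seed, exc) from exc

    design_seqs = [d.sequence for d in designs]
    return _screen(design_seqs, config, engine)


def run_covariant(config: PipelineConfig) -> list[CandidateReport]:
    """Structure-strict mode: covariant escape plus restoration walk.

    Every designed sequence refolds exactly to the query structure by
    construction.  The restoration walk undoes escape mutations from the
    most recent backwards and emits the first sequences for which database
    similarity reappears (the borderline of the similarity well).
    """
    engine = get_engine(config.engine_name)
    designs: list[RnaSequence] = []
    for k in range(config.n_escape_sequences):
        seed_k = run_rng_seed(config.rng_seed, k, 1)
        rng = random.Random(seed_k)
        try:
            trace = covariant_escape(
                config.query,
                config.reference_structure,
                config.database,
                config.search_params,
                rng,
                engine,
                max_mutations=config.escape_budget,
            )
        except EscapeBudgetError as exc:
            raise StageError("covariant-escape", seed_k, exc) from exc
        designs.append(trace.end.with_residues(trace.end.residues, f"|esc{k}"))
        designs.extend(_restoration_walk(trace, config, k))
    return _screen(designs, config, engine)


def _restoration_walk(trace, config: PipelineConfig, k: int) -> list[RnaSequence]:
    """Undo escape moves (most recent first) until hits reappear; return
    the borderline sequence and its flanking steps.  Whole moves are
    undone, so covariant traces stay structure-preserving throughout."""
    seqs = trace.move_intermediates()
    if not seqs:
        return []
    out: list[RnaSequence] = []
    # walking j from the end toward the start of the path
    for j in range(len(seqs) - 2, -1, -1):
        seq = config.query.with_residues(seqs[j], f"|esc{k}r{j}")
        n = len(search(seq, config.database, config.search_params))
        out.append(seq)
        if n > 0:
            # include one step further back toward the query, then stop
            if j > 0:
                out.append(
                    config.query.with_residues(seqs[j - 1], f"|esc{k}r{j - 1}")
                )
            break
    else:
        return out
    return out


def _screen(
    design_seqs: list[RnaSequence], config: PipelineConfig, engine: FoldEngine
) -> list[CandidateReport]:
    """Search every unique design, window and vet every hit locus."""
    unique: dict[str, RnaSequence] = {}
    for s in design_seqs:
        unique.setdefault(s.residues, s)
    all_hits = []
    windows: dict[tuple, float] = {}  # locus -> best e-value
    for s in unique.values():
        try:
            hits = search(s, config.database, config.search_params)
        except Exception as exc:
            raise StageError("search", config.rng_seed, exc) from exc
        all_hits.extend(hits)
        for h in hits:
            rec_seq = config.database.get(h.record_id)
            (lo, hi), _window = extract_window(rec_seq, h, len(config.query))
            key = (h.record_id, lo, hi, h.strand)
            if key not in windows or h.e_value < windows[key]:
                windows[key] = h.e_value

    reports = []
    for (rid, lo, hi, strand), ev in sorted(windows.items()):
        rec_seq = config.database.get(rid)
        window_dna = rec_seq[lo:hi]
        if strand == "-":
            from .search import revcomp

            window_dna = revcomp(window_dna)
        window = RnaSequence(f"{rid}:{lo + 1}-{hi}({strand})", window_dna)
        try:
            report = assess(
                window,
                config.query,
                config.reference_structure,
                engine,
                constraint=config.constraint,
                max_shapiro=config.max_shapiro,
                location=(rid, lo, hi, strand),
                e_value=ev,
            )
        except Exception as exc:
            raise StageError("assess", config.rng_seed, exc) from exc
        reports.append(report)

    ranked = rank_candidates(reports)
    if config.output_dir is not None:
        _persist(config, list(unique.values()), all_hits, ranked)
    return ranked


def _persist(config, designs, hits, reports):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(designs, out / "designs.fasta")
    write_tabular(hits, out / "hits.tsv")
    write_report_tsv(reports, out / "candidates.tsv")
    log = {
        "mode": config.mode,
        "rng_seed": config.rng_seed,
        "engine": config.engine_name,
        "n_escape_sequences": config.n_escape_sequences,
        "runs_per_seed": config.runs_per_seed,
        "n_unique_designs": len(designs),
        "n_hits": len(hits),
        "n_candidates": len(reports),
        "n_accepted": sum(1 for r in reports if r.verdict and not r.is_known),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
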