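"""Structural vetting of similarity hits into riboswitch candidates.

A hit on a designed sequence only locates a stretch of database sequence;
whether that stretch is a plausible aptamer is decided structurally: an
aptamer-sized window is cut around the hit, folded, and compared to the
query aptamer by base-pair distance and coarse-grained (Shapiro) tree
distance.  The verdict keys on the Shapiro distance and on the protected
motif region -- raw base-pair distance may legitimately be large for a
true homolog, since small shifts in the connections between coarse-grained
motifs move many individual pairs while leaving the shape intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .folding import FoldEngine, fold_mfe
from .search import SimilarityHit, revcomp
from .shapiro import element_string, shapiro_distance
from .structures import (
    MotifConstraint,
    RnaSequence,
    SecondaryStructure,
    base_pair_distance,
)


@dataclass
class CandidateReport:
    """A vetted database window with its structural assessment.

    ``start``/``end`` are 0-based half-open plus-strand coordinates of the
    window; reports print 1-based inclusive via :attr:`location_1based`.
    """

    record_id: str
    start: int
    end: int
    strand: str
    window_sequence: RnaSequence
    predicted_structure: SecondaryStructure
    bp_distance_to_query: int
    shapiro_distance_to_query: int
    preserved_positions: frozenset
    verdict: bool
    e_value: float | None = None
    is_known: bool = False

    @property
    def location_1based(self) -> tuple[int, int]:
        return (self.start + 1, self.end)

    @property
    def verdict_label(self) -> str:
        return "accepted" if self.verdict else "rejected"


def extract_window(
    record_sequence: str, hit: SimilarityHit, aptamer_len: int
) -> tuple[tuple[int, int], str]:
    """Cut an aptamer-sized window around a hit.

    The hit's query offset anchors the window: as many positions as
    precede the aligned query segment are added upstream of the subject
    interval (in the hit's orientation) and the remainder downstream, so
    the window corresponds position-by-position to the full query.  At
    record edges the window is shifted toward the interior to preserve its
    length.

    Returns the plus-strand half-open interval and the window sequence in
    the hit's reading orientation (reverse-complemented for minus-strand
    hits).
    """
    rec = record_sequence.upper().replace("U", "T")
    n = len(rec)
    if n < aptamer_len:
        raise ValueError(
            f"record length {n} shorter than aptamer length {aptamer_len}"
        )
    if hit.subject_end - hit.subject_start > aptamer_len:
        # a gapped alignment may span slightly more subject than query;
        # centre the window on the subject interval instead
        centre = (hit.subject_start + hit.subject_end) // 2
        lo = centre - aptamer_len // 2
    elif hit.strand == "+":
        lo = hit.subject_start - hit.query_start
    else:
        # on the minus strand the query's 5' flank lies downstream in
        # plus coordinates
        lo = hit.subject_end + hit.query_start - aptamer_len
    lo = max(0, min(lo, n - aptamer_len))
    hi = lo + aptamer_len
    window = rec[lo:hi]
    if hit.strand == "-":
        window = revcomp(window)
    return (lo, hi), window


def assess(
    window: RnaSequence,
    query_sequence: RnaSequence,
    query_structure: SecondaryStructure,
    engine: FoldEngine,
    constraint: MotifConstraint | None = None,
    max_shapiro: int = 2,
    location: tuple[str, int, int, str] = ("window", 0, 0, "+"),
    e_value: float | None = None,
) -> CandidateReport:
    """Fold a window and compare it structurally to the query aptamer.

    Accepted iff the Shapiro tree distance is at most ``max_shapiro`` and,
    when a motif constraint is given, the window's coarse motif labels over
    the constraint region match the query's (i.e. the protected element --
    typically the ligand-binding multibranch loop -- is present in kind).
    Raw base-pair distance is reported but never rejects on its own.
    """
    if len(window) != len(query_structure):
        raise ValueError(
            f"window length {len(window)} != query length {len(query_structure)}"
        )
    predicted, _ = fold_mfe(window, engine)
    bp = base_pair_distance(predicted, query_structure)
    shapiro = shapiro_distance(predicted, query_structure)
    preserved = frozenset(
        i
        for i, (a, b) in enumerate(zip(window.residues, query_sequence.residues))
        if a == b
    )
    verdict = shapiro <= max_shapiro
    if verdict and constraint is not None and not constraint.is_empty:
        lo, hi = constraint.region
        q_labels = _rle(element_string(query_structure)[lo:hi])
        w_labels = _rle(element_string(predicted)[lo:hi])
        verdict = q_labels == w_labels
    rid, start, end, strand = location
    return CandidateReport(
        record_id=rid,
        start=start,
        end=end,
        strand=strand,
        window_sequence=window,
        predicted_structure=predicted,
        bp_distance_to_query=bp,
        shapiro_distance_to_query=shapiro,
        preserved_positions=preserved,
        verdict=verdict,
        e_value=e_value,
        is_known=window.residues == query_sequence.residues,
    )


def _rle(labels: str) -> tuple:
    """Run-length-compressed label sequence (order preserved)."""
    out = []
    for c in labels:
        if not out or out[-1] != c:
            out.append(c)
    return tuple(out)


def rank_candidates(reports: list[CandidateReport]) -> list[CandidateReport]:
    """Stable ordering: accepted first, then ascending Shapiro distance,
    base-pair distance and E-value."""
    return sorted(
        reports,
        key=lambda r: (
            not r.verdict,
            r.shapiro_distance_to_query,
            r.bp_distance_to_query,
            r.e_value if r.e_value is not None else float("inf"),
        ),
    )


def write_report_tsv(reports: list[CandidateReport], path) -> None:
    """Table-style report: one row per candidate, 1-based locations."""
    cols = [
        "record_id",
        "location",
        "strand",
        "verdict",
        "bp_distance",
        "shapiro_distance",
        "e_value",
        "preserved",
        "known",
        "window_sequence",
        "predicted_structure",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            lo, hi = r.location_1based
            fh.write(
                "\t".join(
                    [
                        r.record_id,
                        f"{lo}-{hi}",
                        r.strand,
                        r.verdict_label,
                        str(r.bp_distance_to_query),
                        str(r.shapiro_distance_to_query),
                        "NA" if r.e_value is None else f"{r.e_value:.2e}",
                        f"{len(r.preserved_positions)}/{len(r.window_sequence)}",
                        "yes" if r.is_known else "no",
                        r.window_sequence.residues,
                        r.predicted_structure.dotbracket,
                    ]
                )
                + "\n"
            )
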