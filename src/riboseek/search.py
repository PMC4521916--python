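"""Self-contained seed-and-extend nucleotide similarity search.

A miniature blastn-style engine so the escape and screening stages run
against local FASTA databases with no network or external binary: exact
word seeding on both strands, ungapped x-drop extension, gapped refinement
of promising seeds, and Karlin-Altschul E-values.  Hits can be exported to
(and ingested from) BLAST outfmt-6 tabular text, so a genuine blastn run
can be substituted anywhere downstream.

Sequences are handled in DNA letters internally (U -> T on ingest); the
query may be RNA.  Subject coordinates are reported on the plus strand,
0-based half-open, with a strand flag -- the tabular writer converts to
the 1-based inclusive convention (reversed coordinates on minus-strand
hits) that outfmt 6 uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .structures import RnaSequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SearchParams:
    """Scoring and reporting parameters.

    The defaults mimic the NCBI "somewhat similar sequences (blastn)"
    task: +2/-3 match/mismatch, small word size, permissive E-cutoff.
    ``gap_open`` is the extra cost of opening a gap, on top of
    ``gap_extend`` per gapped position (a length-L gap costs
    ``|gap_open| + L * |gap_extend|``).  ``karlin_lambda`` and ``karlin_K``
    are the published ungapped Karlin-Altschul constants for the +2/-3
    scheme -- calibration values, not fitted.
    """

    word_size: int = 7
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    x_drop: int = 16
    e_cutoff: float = 10.0
    karlin_lambda: float = 0.625
    karlin_K: float = 0.41
    gapped_trigger: int = 22

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")

    def e_value(self, raw_score: float, query_len: int, db_len: int) -> float:
        return (
            self.karlin_K
            * query_len
            * db_len
            * math.exp(-self.karlin_lambda * raw_score)
        )

    def bit_score(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_K)) / math.log(2)


@dataclass
class SimilarityHit:
    """One local alignment between the query and a database record.

    Intervals are 0-based half-open; ``subject_start``/``subject_end`` are
    plus-strand coordinates regardless of ``strand``.
    """

    record_id: str
    query_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # "+" or "-"
    raw_score: float
    bit_score: float
    e_value: float
    identities: int
    alignment_length: int
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.identities > self.alignment_length:
            raise ValueError("identities exceed alignment length")

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.alignment_length


class SearchDatabase:
    """An indexed nucleotide database built from (id, sequence) records.

    Every k-mer of every record is indexed on both strands; minus-strand
    offsets refer to the reverse complement of the record and are mapped
    back to plus-strand coordinates at reporting time.  Rebuilding from the
    same FASTA gives a byte-identical index.
    """

    def __init__(self, records: list[tuple[str, str]], word_size: int = 7):
        if not records:
            raise ValueError("database has no records")
        seen = set()
        self.records: list[tuple[str, str]] = []
        for rid, seq in records:
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
            norm = seq.upper().replace("U", "T")
            bad = set(norm) - set("ACGT")
            if bad:
                raise ValueError(
                    f"record {rid!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            self.records.append((rid, norm))
        self.word_size = word_size
        self.word_index: dict[str, list[tuple[int, int, str]]] = {}
        for ri, (_rid, seq) in enumerate(self.records):
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for off in range(len(s) - word_size + 1):
                    self.word_index.setdefault(s[off : off + word_size], []).append(
                        (ri, off, strand)
                    )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)

    def record_seq(self, index: int, strand: str = "+") -> str:
        seq = self.records[index][1]
        return seq if strand == "+" else revcomp(seq)

    def get(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(record_id)


def build_db(source, word_size: int = 7) -> SearchDatabase:
    """Build a :class:`SearchDatabase` from a FASTA path or records.

    ``source`` may be a path to a multi-FASTA file, a list of
    ``(id, sequence)`` tuples, or a list of Biopython ``SeqRecord``.
    """
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(source), "fasta")]
    else:
        records = []
        for item in source:
            if isinstance(item, tuple):
                records.append(item)
            elif isinstance(item, RnaSequence):
                records.append((item.id, item.to_dna()))
            else:  # SeqRecord
                records.append((item.id, str(item.seq)))
    return SearchDatabase(records, word_size=word_size)


def _xdrop_ungapped(q, s, qpos, spos, wlen, p: SearchParams):
    """Extend an exact word hit without gaps; x-drop termination.

    Returns (score, q_start, q_end, s_start, s_end) in local coordinates.
    """
    # right of the word
    score = 0
    best_r = 0
    qi, si = qpos + wlen, spos + wlen
    ext_r = 0
    i = 0
    while qi + i < len(q) and si + i < len(s):
        score += p.match if q[qi + i] == s[si + i] else p.mismatch
        i += 1
        if score > best_r:
            best_r, ext_r = score, i
        elif best_r - score > p.x_drop:
            break
    # left of the word
    score = 0
    best_l = 0
    ext_l = 0
    i = 0
    while qpos - i > 0 and spos - i > 0:
        i += 1
        score += p.match if q[qpos - i] == s[spos - i] else p.mismatch
        if score > best_l:
            best_l, ext_l = score, i
        elif best_l - score > p.x_drop:
            break
    total = wlen * p.match + best_l + best_r
    return total, qpos - ext_l, qpos + wlen + ext_r, spos - ext_l, spos + wlen + ext_r


def _make_aligner(p: SearchParams):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open + p.gap_extend
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _alignment_stats(aln, q, s):
    """identities, mismatches, gap opens and length from aligned blocks."""
    qblocks, sblocks = aln.aligned
    ident = mism = 0
    block_len = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        block_len += qb - qa
        for k in range(qb - qa):
            if q[qa + k] == s[sa + k]:
                ident += 1
            else:
                mism += 1
    gaps = 0
    gap_opens = 0
    for k in range(1, len(qblocks)):
        qgap = qblocks[k][0] - qblocks[k - 1][1]
        sgap = sblocks[k][0] - sblocks[k - 1][1]
        if qgap:
            gap_opens += 1
            gaps += qgap
        if sgap:
            gap_opens += 1
            gaps += sgap
    return ident, mism, gap_opens, block_len + gaps


def search(
    query: RnaSequence | str, db: SearchDatabase, p: SearchParams = SearchParams()
) -> list[SimilarityHit]:
    """All database hits of ``query`` with E-value <= ``p.e_cutoff``.

    Seeds are exact ``word_size``-mers on either strand; each seed is
    extended without gaps under x-drop termination, and extensions scoring
    at least ``gapped_trigger`` are refined by a local gapped alignment of
    the full query against a subject window around the seed.  Hits are
    deduplicated (overlapping alignments of the same locus keep the best
    score) and sorted by ascending E-value.
    """
    qid = query.id if isinstance(query, RnaSequence) else "query"
    q = (
        query.to_dna()
        if isinstance(query, RnaSequence)
        else query.upper().replace("U", "T")
    )
    if len(q) < db.word_size:
        raise ValueError(
            f"query length {len(q)} shorter than word size {db.word_size}"
        )
    n_db = db.total_length
    aligner = None
    hits: list[SimilarityHit] = []
    # covered regions per (record, strand): list of (qs, qe, ss, se)
    covered: dict[tuple[int, str], list[tuple[int, int, int, int]]] = {}

    w = db.word_size
    for qpos in range(len(q) - w + 1):
        postings = db.word_index.get(q[qpos : qpos + w])
        if not postings:
            continue
        for ri, spos, strand in postings:
            key = (ri, strand)
            skip = False
            for qs, qe, ss, se in covered.get(key, ()):
                if qs <= qpos < qe and ss <= spos < se:
                    skip = True
                    break
            if skip:
                continue
            s = db.record_seq(ri, strand)
            score, qs, qe, ss, se = _xdrop_ungapped(q, s, qpos, spos, w, p)
            ident = sum(1 for k in range(qe - qs) if q[qs + k] == s[ss + k])
            mism = (qe - qs) - ident
            gapo = 0
            length = qe - qs
            if score >= p.gapped_trigger:
                if aligner is None:
                    aligner = _make_aligner(p)
                pad = len(q)
                win_lo = max(0, ss - pad)
                win_hi = min(len(s), se + pad)
                window = s[win_lo:win_hi]
                alns = aligner.align(q, window)
                if len(alns) > 0 and alns.score > score:
                    aln = alns[0]
                    score = int(alns.score)
                    qblocks, sblocks = aln.aligned
                    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
                    ss = win_lo + int(sblocks[0][0])
                    se = win_lo + int(sblocks[-1][1])
                    ident, mism, gapo, length = _alignment_stats(aln, q, window)
            evalue = p.e_value(score, len(q), n_db)
            if evalue > p.e_cutoff:
                continue
            covered.setdefault(key, []).append((qs, qe, ss, se))
            rec_len = len(db.records[ri][1])
            if strand == "+":
                sb_start, sb_end = ss, se
            else:
                sb_start, sb_end = rec_len - se, rec_len - ss
            hits.append(
                SimilarityHit(
                    record_id=db.records[ri][0],
                    query_id=qid,
                    query_start=qs,
                    query_end=qe,
                    subject_start=sb_start,
                    subject_end=sb_end,
                    strand=strand,
                    raw_score=float(score),
                    bit_score=p.bit_score(score),
                    e_value=evalue,
                    identities=ident,
                    alignment_length=length,
                    mismatches=mism,
                    gap_opens=gapo,
                )
            )

    hits = _dedupe(hits)
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.record_id, h.subject_start))
    return hits


def _dedupe(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Keep the best-scoring hit per overlapping subject locus."""
    kept: list[SimilarityHit] = []
    for h in sorted(hits, key=lambda h: (-h.raw_score, h.e_value)):
        redundant = False
        for k in kept:
            if k.record_id != h.record_id or k.strand != h.strand:
                continue
            overlap = min(k.subject_end, h.subject_end) - max(
                k.subject_start, h.subject_start
            )
            span = min(
                k.subject_end - k.subject_start, h.subject_end - h.subject_start
            )
            if span > 0 and overlap >= 0.5 * span:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def has_hits(query, db: SearchDatabase, p: SearchParams = SearchParams()) -> bool:
    """True iff the query has at least one hit at the E-cutoff."""
    return bool(search(query, db, p))


def count_hits(query, db: SearchDatabase, p: SearchParams = SearchParams()) -> int:
    return len(search(query, db, p))


# ---------------------------------------------------------------------------
# outfmt-6 tabular interchange
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_tabular(hits: list[SimilarityHit], path) -> None:
    """Write hits as BLAST outfmt-6 TSV (1-based inclusive coordinates;
    minus-strand hits have sstart > send)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.subject_start + 1, h.subject_end
            else:
                sstart, send = h.subject_end, h.subject_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.record_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(sstart),
                        str(send),
                        f"{h.e_value:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_tabular(path, params: SearchParams = SearchParams()) -> list[SimilarityHit]:
    """Ingest outfmt-6 TSV (e.g. from a real blastn run) into hits.

    The raw score is reconstructed from the bit score with the configured
    Karlin-Altschul constants, so scores from scoring schemes other than
    ``params`` are approximate.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected 12 outfmt-6 columns, got {len(f)}")
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            length = int(f[3])
            bit = float(f[11])
            raw = (bit * math.log(2) + math.log(params.karlin_K)) / params.karlin_lambda
            hits.append(
                SimilarityHit(
                    record_id=f[1],
                    query_id=f[0],
                    query_start=int(f[6]) - 1,
                    query_end=int(f[7]),
                    subject_start=lo - 1,
                    subject_end=hi,
                    strand=strand,
                    raw_score=raw,
                    bit_score=bit,
                    e_value=float(f[10]),
                    identities=round(float(f[2]) * length / 100.0),
                    alignment_length=length,
                    mismatches=int(f[4]),
                    gap_opens=int(f[5]),
                )
            )
    return hits
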