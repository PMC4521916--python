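"""Readers and writers for the small text formats the tool exchanges.

FASTA goes through Biopython.  "Vienna" structure files are the two-line
convention of the RNA folding tools: a FASTA-style header, the sequence,
then the dot-bracket line (an optional trailing ``(dG)`` energy is ignored
on read).  Constraint files are plain text::

    # fixed nucleotides, 1-based
    25 G
    47 C
    # protected fragment: 1-based inclusive region, then its dot-bracket
    motif 20 33
    ((....))......

Positions are 1-based in files (the convention of the surrounding
ecosystem) and converted to the package's 0-based coordinates on read.
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import MotifConstraint, RnaSequence, SecondaryStructure, parse_dotbracket


def read_fasta(path) -> list[RnaSequence]:
    """All records of a (multi-)FASTA file as :class:`RnaSequence`."""
    records = [
        RnaSequence(r.id, str(r.seq), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences, path, as_dna: bool = False) -> None:
    """Write sequences (RnaSequence or (id, seq) tuples) as FASTA."""
    records = []
    for s in sequences:
        if isinstance(s, RnaSequence):
            rid, seq, desc = s.id, s.residues, s.description
        else:
            rid, seq = s
            desc = ""
        if as_dna:
            seq = seq.replace("U", "T")
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


_ENERGY_SUFFIX = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def read_vienna(path) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a Vienna-style structure file (header, sequence, dot-bracket)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty structure file {path}")
    if lines[0].startswith(">"):
        header = lines[0][1:].strip()
        rid = header.split()[0] if header else "structure"
        lines = lines[1:]
    else:
        rid = "structure"
    if len(lines) < 2:
        raise ValueError(f"structure file {path} lacks a dot-bracket line")
    seq = RnaSequence(rid, lines[0])
    structure = parse_dotbracket(_ENERGY_SUFFIX.sub("", lines[1]))
    if len(structure) != len(seq):
        raise ValueError(
            f"sequence and structure lengths differ in {path} "
            f"({len(seq)} vs {len(structure)})"
        )
    return seq, structure


def write_vienna(seq: RnaSequence, structure: SecondaryStructure, path, dG=None):
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n{seq.residues}\n{structure.dotbracket}")
        if dG is not None:
            fh.write(f" ({dG:.2f})")
        fh.write("\n")


def read_constraint(path, target: SecondaryStructure | None = None) -> MotifConstraint:
    """Parse a constraint file (see module docstring for the format)."""
    fixed: dict[int, str] = {}
    region = (0, 0)
    required = ""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts[0].lower() == "motif":
            if len(parts) != 3:
                raise ValueError(f"bad motif line: {lines[i]!r}")
            start, end = int(parts[1]) - 1, int(parts[2])  # 1-based inclusive
            if i + 1 >= len(lines):
                raise ValueError("motif line lacks its dot-bracket line")
            required = lines[i + 1]
            region = (start, end)
            i += 2
        else:
            if len(parts) != 2:
                raise ValueError(f"bad fixed-position line: {lines[i]!r}")
            fixed[int(parts[0]) - 1] = parts[1]
            i += 1
    c = MotifConstraint(
        region=region, required_substructure=required, fixed_positions=fixed
    )
    if target is not None:
        c.validate_against(target)
    return c


def write_constraint(c: MotifConstraint, path) -> None:
    with open(path, "w") as fh:
        for pos in sorted(c.fixed_positions):
            fh.write(f"{pos + 1} {c.fixed_positions[pos]}\n")
        if c.region[1] > c.region[0]:
            fh.write(f"motif {c.region[0] + 1} {c.region[1]}\n")
            fh.write(c.required_substructure + "\n")
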