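"""Core sequence and secondary-structure types.

An RNA secondary structure is held both as a dot-bracket string and as the
set of base pairs it encodes; the two views are kept consistent by
construction.  Only nested (pseudoknot-free) structures are representable,
which is all the downstream machinery (coarse-grained trees, Nussinov-style
folding, inverse design) supports.

Coordinates are 0-based half-open everywhere inside the package; report
writers convert to 1-based inclusive (GenBank style) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")

#: Legal base pairs, Watson-Crick plus GU wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
WATSON_CRICK_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
)


class StructureParseError(ValueError):
    """Raised for malformed dot-bracket input; carries the offending index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence over {A, C, G, U}.

    DNA input is accepted and normalized: T becomes U and lowercase is
    uppercased on construction.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        norm = self.residues.upper().replace("T", "U")
        bad = set(norm) - RNA_ALPHABET
        if not norm:
            raise ValueError(f"sequence {self.id!r} is empty")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def to_dna(self) -> str:
        """The sequence in DNA letters (U -> T), e.g. for database search."""
        return self.residues.replace("U", "T")

    def with_residues(self, residues: str, suffix: str = "") -> "RnaSequence":
        """A copy carrying new residues (id optionally suffixed)."""
        return RnaSequence(self.id + suffix, residues, self.description)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure: dot-bracket string plus its pair set.

    ``pairs`` holds (i, j) with i < j, 0-based; it is derived from the
    dot-bracket text, and the two representations round-trip.
    """

    dotbracket: str
    pairs: frozenset = field(compare=False)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def partner(self) -> dict:
        """Map position -> pairing partner (both directions)."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @classmethod
    def from_pairs(cls, length: int, pairs) -> "SecondaryStructure":
        chars = ["."] * length
        for i, j in pairs:
            if not (0 <= i < j < length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {length}")
            if chars[i] != "." or chars[j] != ".":
                raise ValueError(f"position reused in pair ({i}, {j})")
            chars[i], chars[j] = "(", ")"
        s = cls(dotbracket="".join(chars), pairs=frozenset(map(tuple, pairs)))
        # reject crossing pairs: re-parsing must give back the same set
        if parse_dotbracket(s.dotbracket).pairs != s.pairs:
            raise ValueError("pair set is pseudoknotted (crossing pairs)")
        return s

    def is_open_chain(self) -> bool:
        return not self.pairs


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket notation into a :class:`SecondaryStructure`.

    Whitespace is stripped.  Only ``.``, ``(`` and ``)`` are legal, so
    pseudoknots (which need extra bracket types) are rejected up front.

    Raises
    ------
    StructureParseError
        On an illegal character or unbalanced parentheses, naming the
        offending index.
    """
    s = "".join(text.split())
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(s):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureParseError(
                    f"unmatched ')' at index {i}", index=i
                )
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise StructureParseError(
                f"illegal character {c!r} at index {i}", index=i
            )
    if stack:
        raise StructureParseError(
            f"unclosed '(' at index {stack[0]}", index=stack[0]
        )
    return SecondaryStructure(dotbracket=s, pairs=frozenset(pairs))


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Symmetric-difference cardinality of the two base-pair sets.

    The standard base-pair metric: the number of pairs present in exactly
    one of the two structures.  Requires equal lengths (structures are
    compared on equal-length windows).
    """
    if len(a) != len(b):
        raise ValueError(
            f"structure lengths differ ({len(a)} vs {len(b)})"
        )
    return len(a.pairs ^ b.pairs)


def hamming_distance(a, b) -> int:
    """Number of differing positions between two equal-length sequences.

    Accepts :class:`RnaSequence` or plain strings; strings are normalized
    the same way (T -> U, uppercase) so DNA and RNA spellings compare equal.
    """
    sa = a.residues if isinstance(a, RnaSequence) else a.upper().replace("T", "U")
    sb = b.residues if isinstance(b, RnaSequence) else b.upper().replace("T", "U")
    if len(sa) != len(sb):
        raise ValueError(f"sequence lengths differ ({len(sa)} vs {len(sb)})")
    return sum(x != y for x, y in zip(sa, sb))


@dataclass(frozen=True)
class MotifConstraint:
    """A protected structural fragment plus fixed nucleotides.

    ``region`` is a 0-based half-open interval on the target structure whose
    dot-bracket substring (``required_substructure``) must be reproduced
    exactly by any acceptable design -- e.g. the multibranch loop where
    ligand binding occurs.  ``fixed_positions`` maps 0-based positions to
    the nucleotide required there (essential ligand-contacting residues).
    """

    region: tuple[int, int] = (0, 0)
    required_substructure: str = ""
    fixed_positions: dict = field(default_factory=dict)

    def __post_init__(self):
        start, end = self.region
        if start < 0 or end < start:
            raise ValueError(f"invalid region {self.region}")
        if end - start != len(self.required_substructure):
            raise ValueError(
                "required_substructure length does not match region span"
            )
        for pos, nt in self.fixed_positions.items():
            if pos < 0:
                raise ValueError(f"fixed position {pos} is negative")
            if nt.upper().replace("T", "U") not in RNA_ALPHABET:
                raise ValueError(f"fixed position {pos}: illegal nucleotide {nt!r}")

    @property
    def is_empty(self) -> bool:
        return self.region[0] == self.region[1] and not self.fixed_positions

    def validate_against(self, target: SecondaryStructure, seq_len: int | None = None):
        """Check region/positions fit the target structure (raises ValueError)."""
        start, end = self.region
        if end > len(target):
            raise ValueError(
                f"constraint region {self.region} exceeds structure length {len(target)}"
            )
        if self.required_substructure and target.dotbracket[start:end] != self.required_substructure:
            raise ValueError(
                "required_substructure does not match the target structure over the region"
            )
        n = seq_len if seq_len is not None else len(target)
        for pos in self.fixed_positions:
            if pos >= n:
                raise ValueError(f"fixed position {pos} outside sequence length {n}")
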