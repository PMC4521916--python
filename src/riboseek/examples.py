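"""Worked-example aptamer sequences used throughout docs and tests.

The guanine-sensing purine riboswitch aptamer upstream of the *Bacillus
subtilis* ``xpt`` gene (69 nt) is the canonical query for this kind of
structure-based search: its minimum-free-energy fold is nearly identical
to the experimentally derived three-stem multibranch structure.  The
preQ1-sensing ``queC`` aptamer from *B. subtilis* and the mutant series
around it illustrate why structure, not sequence, carries the signal:
seventeen structure-preserving point mutations leave the fold (and
database detectability) intact, while one further compensatory pair
substitution that looks harmless by complementarity alone collapses the
predicted structure entirely.
"""

from .structures import RnaSequence

#: B. subtilis xpt guanine riboswitch aptamer domain, 69 nt.
XPT_APTAMER = RnaSequence(
    "xpt",
    "CACUCAUAUAAUCGCGUGGAUAUGGCACGCAAGUUUCUACCGGGCACCGUAAAUGUCCGACUAUGGGUG",
    "B. subtilis xpt guanine riboswitch aptamer domain",
)

#: A fully escaped covariant mutant of the xpt aptamer: same predicted
#: shape, no remaining database similarity.
XPT_COVARIANT_ESCAPE = RnaSequence(
    "xpt_escape",
    "UGAAUGUAUAAUUCGACCUGGCAACGGUCGAAGUUUCUACCAAAAAAUAACCGUUUUUGACUACAUUCA",
    "covariant escape mutant of the xpt aptamer",
)

#: The escape mutant with its 3' segment restored toward the wild type --
#: the borderline sequence that regains (remote) database similarity.
XPT_BORDERLINE_RESTORED = RnaSequence(
    "xpt_borderline",
    "UGAAUGUAUAAUUCGACCUGGCAACGGUCGAAGUUUCUACCGGGCACCGUAAAUGUCCGACUACAUUCA",
    "escape mutant with the right segment restored toward xpt",
)

#: B. subtilis queC preQ1 riboswitch aptamer, wild type (53 nt).
PREQ1_WILDTYPE = RnaSequence(
    "queC",
    "CCGTGCGATATGCGGGAGAGGTTCTAGCTACACCCTCTATAAAAAACTAAGGA",
    "B. subtilis queC preQ1 riboswitch aptamer, wild type",
)

#: Seventeen structure-preserving point mutations from the wild type;
#: still folds to the wild-type structure and still produces hits.
PREQ1_MUTANT_17 = RnaSequence(
    "queC_m17",
    "ACGTGCGATATGCGTGGGCCGTTCTAGCTACACCGGCCATTTTTTTCATTGGA",
    "preQ1 aptamer, 17 structure-preserving mutations from wild type",
)

#: Two further mutations forming one compensatory C-G -> A-U pair change
#: in the 5' stem: nominally covariant, but the whole predicted structure
#: collapses under the thermodynamic model -- and database hits vanish.
PREQ1_MUTANT_19 = RnaSequence(
    "queC_m19",
    "ATGTGCGATATGCATGGGCCGTTCTAGCTACACCGGCCATTTTTTTCATTGGA",
    "preQ1 aptamer after one further compensatory pair change (structure collapses)",
)

#: An alternative structure-preserving mutant of the wild type that keeps
#: the fold and retains remote database similarity.
PREQ1_MUTANT_ALT = RnaSequence(
    "queC_alt",
    "AAGTGCGATATGCTTGGGCCGTTCTAGCTACACCGGCCATAAAAAAGAAAGGA",
    "alternative structure-preserving preQ1 aptamer mutant",
)
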