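# Methods

## Overview

`riboseek` turns a structure-conservation search into a sequence-
similarity search. A verified aptamer (sequence + secondary structure) is
mutated out of its similarity well, redesigned so that its predicted MFE
fold again matches the aptamer's coarse-grained shape, and the designed
sequences are screened against a nucleotide database. Hits are vetted
structurally, not by alignment score. The expensive operation — energy-
minimization folding — is applied only to the query, the design
trajectory, and aptamer-sized windows around hits, never to a sliding
window over the whole database.

## Representations and distances

**Secondary structure** is a nested (pseudoknot-free) set of base pairs,
stored together with its dot-bracket string. Pseudoknots are rejected at
parse time; lonely pairs are permitted in parsing, and the folding engine
decides whether to produce them.

**Coarse-grained (Shapiro) tree.** A structure is decomposed into motifs:
maximal helices (S), the loop each helix closes — hairpin (H), bulge (B),
interior loop (I) or multibranch loop (M) — and external single-stranded
runs (E), all under a virtual root (R), ordered 5'→3'. The unweighted
grain is used: nodes carry no size annotation, so the tree encodes shape
only and is invariant under compensatory base-pair changes. Convention
notes (these choices affect absolute distance values, so they are stated
explicitly): the virtual root is counted as a node; every maximal
external run contributes one E node; a bulge requires unpaired residues
on exactly one side of the single branch, an interior loop on both.

**Distances.** Base-pair distance is the cardinality of the symmetric
difference of the two pair sets — the standard convention, a true metric,
and insensitive to dialect at its tiny weight in the objective. Tree
distance is the ordered tree edit distance with unit insert/delete/
relabel costs, computed with Zhang–Shasha's dynamic program (implemented
in-package) and verified in tests against exhaustive Tai-mapping
enumeration on small trees.

## Folding engines

Folding sits behind a two-method engine contract so every downstream
stage is engine-agnostic.

* **builtin** — Nussinov-style DP with pair scores GC −3, AU −2, GU −1
  (arbitrary units reported as dG), minimum hairpin loop of 3 nt, and a
  deterministic traceback that prefers pairing the 5'-most position with
  its smallest optimal partner. Its optimum is verified against
  brute-force enumeration of all nested structures for short sequences.
  Use it for tests, toys, and anywhere full determinism across platforms
  matters.
* **vienna** — ViennaRNA MFE folding (kcal/mol) through the Python
  bindings; the engine for biological runs.

No temperature or ionic parameters are exposed; defaults are used
throughout. Vetting outcomes can shift between thermodynamic parameter
revisions: e.g. the 17-fold-mutated preQ1 aptamer in `examples` refolds
with a one-position stem shift under current ViennaRNA parameters, while
the subsequent compensatory C-G→A-U change collapses the structure under
any revision. Tests assert only the latter, revision-stable fact.

## The design objective

    f(c, t) = w_n·|ν_t − ν_c| + w_G·|dG_t − dG_c| + w_m·motif_missing(c)
            + w_s·d_tree(t, c) + w_b·d_bp(t, c)

with fixed weights w_n = 100, w_G = 1, w_m = 1000, w_s = 100, w_b = 0.01.
The motif term is a *penalty indicator* — 1 exactly when the candidate's
dot-bracket over the protected region differs from the target's — so that
the dominant weight enforces the constraint rather than rewarding its
violation. The tree term is the primary structural signal; the base-pair
term only breaks ties among shape-identical candidates so solutions are
not over-dominated by shape. Neutrality ν (mutational robustness) is the
mean over all 3L single-point mutants of `1 − d_bp(fold(m), fold(s))/L`,
clipped to [0, 1] — a compatible stand-in for the measure used by earlier
shape-directed design solvers, whose exact formula is not published.
The ν and dG terms are disabled by default (flags expose them): distant
homologs with different nucleotide composition legitimately differ in
both.

## The annealer

Moves are biased toward the target's pairing pattern: unpaired-in-target
positions get single-nucleotide substitutions; paired positions are
rewritten as whole pairs from {AU, UA, GC, CG, GU, UG} (wobble included;
a strict-WC flag exists on the mutation operators). Fixed positions are
never touched; a fixed nucleotide inside a pair restricts that pair's
rewrites, and an unsatisfiable fixed pair is rejected before search.

The four-site look-ahead works in two stages per iteration: up to 4
elementary moves at distinct sites are sampled; each is evaluated alone,
and a clean single improvement is preferred. Only when no single move
improves are the moves composed into joint 2..4-site bundles — the
mechanism for stepping across objective plateaus and compensatory
changes. Acceptance is Metropolis with geometric cooling, with two
refinements that both exist for the same reason: the zero-objective set
is an enormous plateau (every sequence with the right fold ties), and the
solver's purpose is a *minimal* set of directed mutations, so (a)
exact-tie moves are accepted only if they do not increase Hamming
distance to the seed, and (b) among equal-objective bests the one closest
to the seed is kept. Pair rewrites prefer the minimal-edit option
(repair the broken side, keep the intact side) half the time.

Defaults: initial temperature 0.05, cooling 0.95 every 50 steps, at most
10,000 objective evaluations, early exit at objective 0. The temperature
is deliberately placed between the objective's two move scales — one
base pair costs 0.01, one tree edit costs 100. A temperature at or above
1 makes every fine-scale move free, and the annealer then performs an
undirected random walk that diffuses away from its seed; far below 0.01
it becomes purely greedy. 0.05 accepts occasional one-to-few-bp uphill
moves while keeping tree-level damage forbidden. All randomness flows
from the schedule's seed; batch runs derive per-run seeds deterministically
from (base seed, seed index, run index), and identical inputs reproduce
identical outputs byte for byte.

## Similarity search

A self-contained seed-and-extend engine stands in for `blastn` so the
escape loop and the screening stage run with no network or external
binary. Parameters mimic the permissive "somewhat similar sequences"
task: match +2, mismatch −3, gap open 5 and extend 2 (a length-L gap
costs 5 + 2L), word size 7, both strands indexed. Seeds are extended
ungapped under x-drop termination (default 16 raw); extensions scoring at
least 22 raw are refined by a local gapped alignment (Biopython's
PairwiseAligner) of the full query against a window around the seed.
E-values use the published ungapped Karlin–Altschul constants for +2/−3
(λ = 0.625, K = 0.41) — calibration values, not fitted. Overlapping
alignments of one locus keep the best score; hits sort by E-value.

The documented miss class of any word-seeded search applies: an alignment
whose optimal path contains no run of 7 exact matches cannot be seeded.
The property tests quantify this against a full Smith–Waterman scan and
require every discrepancy to belong to that class.

**Choosing the E-cutoff.** The default cutoff 10 mirrors the web
default against nr/nt, where the score needed to reach E = 10 sits far
into the tail of the random-alignment distribution. Against a miniature
database the same nominal cutoff admits the ~9-match alignments that
occur by chance several times per query, and the "mutate until no hits"
escape loop can then never terminate. Pipeline configurations should
therefore calibrate the cutoff to database size so the *expected number
of chance hits* K·m·n·e^(−λS) at the threshold score is well below 1;
for the ~10 kb fixtures used here that is e_cutoff = 1e-3. This
reproduces the effective stringency of the full-scale search rather than
its nominal parameter.

## Windows and vetting

Around each hit an aptamer-length window is cut, anchored by the hit's
query offset (as many positions as precede the aligned query segment are
added upstream in the hit's orientation), shifted inward at record edges,
and reverse-complemented for minus-strand hits; gapped hits spanning more
subject than query are centred instead. The window is folded and
compared to the query: the verdict is `shapiro_distance ≤ 2` (the
observed distance of genuine cross-species aptamer matches) plus, when a
motif constraint is configured, equality of the run-length-compressed
per-position motif labels over the protected region. Raw base-pair
distance is reported but never rejects on its own: small shifts in the
connections between coarse-grained motifs move many individual pairs
while preserving the architecture, which is precisely the flexibility the
method exists to exploit. Windows identical to the query sequence are
flagged "known" and excluded from novel-candidate counts. Reports print
1-based inclusive coordinates; everything internal is 0-based half-open.

## Pipeline modes

**general** — N random-escape traces (default budget 3L mutations each,
re-querying after every mutation) produce seeds; each seed goes to the
solver `runs_per_seed` times; unique designs are screened. Most designs
legitimately yield nothing — they land too far from anything in the
database — and are logged, not errors.

**covariant** — the structure-strict special case: escape uses only
refold-verified compensatory moves, so every intermediate folds exactly
to the query structure. Designs are the escape endpoint plus a
restoration walk that undoes whole moves (most recent first) until
database similarity reappears, emitting the borderline sequences — the
thin shell of sequence space where novel but findable homologs live. Cheap, deterministic, and sufficient to recover structure-preserved
plants; it cannot reach candidates whose fine structure differs from the
query's, which is what the general mode is for.

Stage errors abort with the stage name and the exact replay seed;
`preflight` warns (does not abort) when the query's fold deviates from
its reference or the query has no database hits.

## Synthetic data

`generate_fixture` emulates the target scenario: uniform-random
nucleotide background records carrying homologs produced by chains of
refold-verified covariant mutations, planted without overlap on either
strand at recorded coordinates, plus optional scrambled decoys (same
composition, shuffled). Default divergence is 12 covariant steps ≈ 16–22
changed positions on the 69-nt query — about 75–80% identity, the regime
of genuine cross-species aptamer matches. What the fixtures do *not*
emulate: real genomic base composition and repeats, families of related
hits, alternative structures, transcriptional context, or a database
within orders of magnitude of nr/nt. Passing the end-to-end tests
therefore demonstrates the machinery — escape terminates, designs carry
the structure, the search finds what alignment can find, vetting accepts
exactly the structure-preserved loci — not field performance on real
genomes.

## Problem sizes in tests and acceptance runs

Chosen to exercise every stage at meaningful scale: folding-oracle
enumeration up to 18 nt; tree-distance oracle up to 6-node trees; search
oracle on ~30 kb databases with 25–30 queries; design convergence on 50
random nested targets of 12–25 nt; end-to-end recall over 8–10
independent fixtures (3 × 1.5 kb records) in covariant mode with 4
escapes per run, and one general-mode campaign of 10 escapes × 2 solver
runs.

## Known limitations

* Nested structures only; pseudoknotted aptamers are out of reach.
* The built-in engine is a teaching/testing model, not a thermodynamic
  one; biological conclusions require the ViennaRNA engine, and vetting
  outcomes inherit its parameter-revision sensitivity.
* The local search stand-in is not BLAST: no low-complexity masking, no
  composition-based statistics, ungapped Karlin–Altschul constants
  applied to gapped scores.
* General-mode designs scatter around the query at roughly twice the
  escape distance; recovering a specific distant locus is probabilistic
  and improves with more escapes and runs per seed, exactly as in the
  underlying search strategy.
* Neutrality is O(3L) folds per evaluation — leave it disabled except on
  short sequences or final-candidate scoring.
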