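# riboseek

Structure-based riboswitch aptamer search by moving the search into
sequence space.

## The problem

Riboswitch aptamer domains are conserved in *structure* at least as
strongly as in sequence, so distant homologs — the interesting ones, in
under-sampled clades — routinely fall below the radar of plain
sequence-similarity search. Scanning genomes with windowed
energy-minimization folding finds them in principle but is far too slow
genome-wide, and the fold predicted inside an arbitrary window cannot be
sanity-checked the way the query's fold can.

`riboseek` implements the inverse strategy: keep the fast, well-understood
sequence search, but feed it *designed* sequences that carry the aptamer's
structure into new parts of sequence space.

1. **Escape.** Mutate the known aptamer until a similarity search of the
   target database returns nothing — the sequence has left the "well" of
   trivial self-similarity.
2. **Restore.** Hand the escaped sequence to a flexible inverse-folding
   solver that mutates it back until its predicted minimum-free-energy
   (MFE) fold again matches the aptamer's *shape*, holding a protected
   fragment (e.g. the ligand-binding multibranch loop) and any essential
   nucleotides exactly fixed. A structure-strict special case replaces the
   solver with verified compensatory (covariant) mutations only.
3. **Screen and vet.** Search every designed sequence against the
   database; around each hit, cut an aptamer-sized window, fold it, and
   accept it as a candidate only if its coarse-grained structure matches
   the query's.

The solver minimizes the fixed-weight objective

    f(c, t) = 100·|ν(t) − ν(c)| + |ΔG(t) − ΔG(c)| + 1000·motif_missing(c)
            + 100·d_tree(t, c) + 0.01·d_bp(t, c)

where `d_tree` is the ordered tree edit distance between coarse-grained
(Shapiro) motif trees, `d_bp` the base-pair set distance, `motif_missing`
the indicator that the protected fragment's secondary structure is not
reproduced exactly, ν the single-mutant neutrality and ΔG the MFE (the ν
and ΔG terms are off by default). Candidate verdicts likewise key on the
Shapiro distance: a true homolog may shift many individual base pairs
while leaving the motif architecture intact.

It ships with a self-contained seed-and-extend nucleotide search
(word seeding on both strands, x-drop extension, gapped refinement,
Karlin–Altschul E-values) so everything runs locally; tabular
(outfmt-6-style) hits from a real `blastn` run can be substituted at the
same interface. Folding runs on ViennaRNA when its Python bindings are
available (`engine="vienna"`) or on a deterministic, oracle-verifiable
built-in Nussinov engine (`engine="builtin"`).

## Worked example

The guanine-sensing aptamer upstream of *B. subtilis* `xpt` (69 nt) is
the canonical query. The snippet plants one structure-preserved,
sequence-diverged homolog in a synthetic genome and runs the
structure-strict pipeline:

```python
from riboseek import ViennaEngine, fold_mfe, build_db, SearchParams
from riboseek.examples import XPT_APTAMER
from riboseek.pipeline import (
    PipelineConfig, generate_fixture, preflight, run_covariant,
)

engine = ViennaEngine()
reference, dG = fold_mfe(XPT_APTAMER, engine)

records, truth = generate_fixture(
    XPT_APTAMER, reference, n_records=3, record_length=2000,
    n_planted=1, divergence_steps=12, rng_seed=42, engine=engine,
)
config = PipelineConfig(
    query=XPT_APTAMER, reference_structure=reference,
    database=build_db(records), mode="covariant",
    n_escape_sequences=4, runs_per_seed=1,
    search_params=SearchParams(e_cutoff=1e-3),
    engine_name="vienna", rng_seed=7,
)
print(preflight(config))
reports = run_covariant(config)
```

which prints (formatted):

```
query fold (dG -21.3 kcal/mol):
((((((((.....(((((.......)))))..........((((((.......))))))..))))))))
planted homolog: rec2:1552-1620(-), 16 mutations from the query
preflight: fold-vs-reference bp=0 shapiro=0, query hits=1
accepted: rec2:1552-1620(-) bp_distance=0 shapiro_distance=0 preserved=53/69 e=5.7e-11
```

The query folds into the aptamer's three-stem multibranch architecture
(`R(S(M(S(H),S(H))))`); preflight confirms the fold matches the reference
and that the query still has a known location in the database. The run
then recovers the planted homolog on the minus strand at exactly its
planted coordinates: its window refolds to the query's structure
(base-pair and Shapiro distance 0) even though only 53 of 69 nucleotides
are preserved — a locus plain sequence search at this stringency would
already be losing.

The same stages are available from the shell:

```bash
riboseek fixture  --structure xpt.vienna --out db.fasta --truth truth.json
riboseek preflight --structure xpt.vienna --db db.fasta
riboseek run      --config run.yaml --seed 7 --out results/
```

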