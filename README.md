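# tecurate

Curation of de novo transposable-element (TE) consensus libraries.

De novo repeat finders (RepeatModeler2, EDTA, REPET, ...) emit *raw*
libraries: consensus sets that are redundant, fragmented, contaminated
with false positives (tandem repeats, multicopy host genes, single-copy
sequences) and partly unclassified or misclassified.  Annotating a genome
with such a library fragments the annotation and misattributes TE orders.
`tecurate` turns a raw library plus its genome assembly into a curated
one, for anyone who needs reliable TE annotations without weeks of manual
consensus-by-consensus curation.

## What it does

Given a raw library, the genome, a multicopy-gene/rRNA profile set and a
curated reference TE database, the pipeline runs:

1. **Preprocessing** — headers are parsed as `name#Order/Superfamily`
   (Wicker three-letter codes accepted); `DNA` orders become `TIR`,
   `Unknown` becomes `Unclassified`; satellites, RNAs and labels outside
   the nomenclature are excluded and logged.
2. **Redundancy reduction** — greedy incremental clustering at 95%
   identity and 98% coverage of the shorter sequence; the longest member
   represents each cluster.  Runs again at the end of the pipeline.
3. **Consensus extension** — up to 16 BEE rounds (BLAST, Extract,
   Extend): collect genomic copies at e-value ≤ 1e-20, extract them with
   500 bp flanks, re-align, re-polish the consensus, and stop each side
   when flank support collapses (the element end has been reached).
   After each round, families are split into subfamilies when
   average-linkage clustering of the copies on Kimura 2-parameter
   distances (d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)) separates well-populated
   groups.
4. **False-positive filtering** — a consensus is removed when it has at
   most one full-length fragment (FLF) in the genome, matches host-gene or
   rRNA profiles over ≥50% of its length (profile e-value ≤ 10), or is
   >60% simple sequence repeats.
5. **Classification** — consensus matching the reference database under
   the 80-80-80 rule (hit ≥80 bp, ≥80% identity, over ≥80% of the query)
   keep that classification.  Classified records without such a hit are
   checked for their order's expected structural features (LTRs, TIRs,
   poly(A) tails, coding domains); failures are kept but flagged with an
   `_inc` suffix.  Unclassified records go through a three-step rescue:
   homology at 70-70-70, coding-domain content (emitting generic
   `ClassI`/`ClassII` when only domains survive), then terminal repeats
   alone.

The package also ships the benchmarking metrics used to compare libraries
and annotations — perfect/good/present/missing family-quality labels,
NTE50/LTE50 (the N50 analogue over annotated copy lengths against half
the mobilome), short/overlapping copy counts, per-order genomic
proportions, chimera detection — and a simulator that generates genomes
with planted TE families, decoys and a ground-truth table, so the whole
pipeline is verifiable at desk scale.

## Worked example

Simulate the standard scenario (six families — 2 LTR, 2 TIR, 1 LINE,
1 MITE — at 15–25 copies and 3–8% divergence, degraded into a 27-record
raw library with duplicates, fragments, 8 decoys and one chimera), then
curate it:

```sh
$ tecurate simulate -o sim --seed 42
simulated dataset written to sim

$ tecurate run -l sim/raw_library.fa -g sim/genome.fa \
    -p sim/gene_profiles.json -r sim/rrna_profiles.json \
    -d sim/reference_db.fa -o curated
curated 6 consensus from 27 raw sequences -> curated

$ grep ">" curated/curated_library.fa
>fam_ltr2#LTR/Gypsy
>fam_tir2#TIR/Tc1-Mariner
>fam_line1_r3#LINE/L1
>fam_mite1_r2#TIR
>chimera_1_sub1#TIR/hAT
>chimera_1_sub2#LTR/Copia
```

The 27 raw records collapse to 6 consensus — one per planted family.  The
manifest (`curated/manifest.json`) accounts for every record:

```
stage_counts:        {"input": 27, "after_preprocess": 27, "after_redundancy": 14,
                      "after_extension": 15, "after_false_positive_filter": 7,
                      "after_classification": 7, "curated": 6, "incomplete": 0}
removals_by_reason:  {"redundant": 14, "few_flf": 3, "gene_or_rrna": 2, "ssr": 3}
```

All three SSR decoys fell to the SSR filter, both host-gene decoys to the
profile filter, and the three single-copy decoys to the FLF filter.  The
chimeric record (an LTR element fused to a TIR element) was recognised
during extension — its genomic copies form two disjoint alignment groups
— and split back into its constituent families (`chimera_1_sub1/_sub2`).
Note the curated ids keep their raw-library provenance: `fam_line1_r3`
was the longest surviving duplicate of the LINE family and `fam_mite1_r2`
was rescued from a blanked classification as order TIR (MITEs are
nonautonomous TIR elements).

Benchmarking the curated library against the planted ancestors:

```sh
$ tecurate bench -r sim/ancestors.fa -t curated/curated_library.fa -o bench.json
{"good": 0, "missing": 0, "perfect": 6, "present": 0}
```

All six families are *perfect*: matched by a single curated sequence at
>95% identity and >95% coverage.

## Library API

```python
from tecurate import run_pipeline, PipelineConfig
from tecurate.simulate import simulate_dataset

ds = simulate_dataset(seed=42)
curated, manifest = run_pipeline(
    ds.raw_library, ds.genome,
    gene_profiles=ds.gene_profiles, rrna_profiles=ds.rrna_profiles,
    reference_db=ds.reference_db, outdir="curated",
)
```

Every stage is also importable on its own (`tecurate.redundancy`,
`tecurate.extension`, `tecurate.filters`, `tecurate.classify`,
`tecurate.benchmark`, `tecurate.search`).  See `docs/methods.md` for the
models, parameter defaults and design decisions.
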