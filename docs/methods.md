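# Methods

This note documents the models and procedures behind `tecurate`, the
defaults that matter, the numerical choices, what the simulator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Sequence search

All nucleotide similarity queries (copy collection, redundancy
statistics, homology classification, library benchmarking) go through one
internal seed-and-extend local search: exact 11-mer seeds on both
strands, grouped by diagonal, extended ungapped with match +1 /
mismatch −2 scoring and an X-drop of 20.  Coordinates are 0-based
half-open with subject positions always on the forward strand; a `−` hit
means the reverse complement of the query matches the subject.

Significance uses the ungapped Karlin–Altschul approximation
`E = K·m·n·e^(−λS)` with λ = 1.33 and K = 0.621 (the published values for
+1/−2 scoring) and search space m·n = query length × total subject
length.  Because every pipeline stage filters on a fixed e-value cutoff,
any calibrated monotone score→e-value map gives identical filtering
behaviour; the constants are not tuned.

The extension is ungapped.  This is exact under the substitution-only
divergence model the simulator uses by default and adequate for the
high-identity (≥80%) matches the pipeline acts on; under real indel-rich
divergence a gapped aligner adapter would be the upgrade path.  Hits
nested inside the subject span of a higher-scoring hit (the signature of
internal repeats such as the two LTRs of one element) are discarded
before loci are formed.

Copy collection applies two filters beyond the e-value cutoff
(default 1e-20): an identity floor of 0.80 — a genuine family copy at the
divergences the pipeline handles aligns far above it, while conserved
coding domains shared with *other* families fall below — and a cap of 40
best-scoring loci.  Collinear hits closer than 50 bp on the same
contig/strand merge into one locus only when their query spans are
essentially disjoint (<50% mutual overlap), so split fragments of one
copy merge but tandem copies stay separate.

## Profile search

Protein domains (RT, INT, GAG, PROT, RNaseH, EN, Transposase, Helicase)
and the host-gene/rRNA decoy sets are position-specific scoring matrices
over peptides, scanned against all six translation frames.  Matrices are
log2-odds with 0.9 emission probability on the consensus residue; for
such matrices the natural-scale Karlin–Altschul λ is ln 2 by
construction, and the per-profile λ is still solved numerically (Brent's
method on the mean column moment condition) so that externally supplied
matrices are handled correctly.  The default reporting cutoff is
e-value ≤ 10, matching common profile-scanner practice; planted domains
score orders of magnitude below any random window, so results are
insensitive to this cutoff.

## Redundancy reduction

Greedy incremental clustering in the CD-HIT-EST style: sequences sorted
longest-first, each joining the first cluster whose representative it
matches at ≥95% identity and ≥98% coverage *of the shorter sequence*
(identity is the length-weighted mean over merged hits, coverage the
merged hit span on the shorter).  Measuring coverage on the shorter
sequence lets exact fragments be absorbed by their parent consensus.  The
representative is the longest member, ties broken by lexicographically
smallest id, which makes the outcome independent of input order.

## Consensus extension (BEE rounds)

Each round: collect copies, extract each copy's genomic window with
500 bp flanks on the still-open sides (clipped at contig bounds,
strand-normalized), build a multiple alignment, re-polish the consensus,
detect edges.  Default budget 16 rounds; the loop stops early once both
sides are closed, and a state with both sides closed is a fixpoint.

**Anchored MSA.**  The alignment is center-star, anchored on the current
consensus: each copy's matching segment is globally aligned to its
consensus interval (edlib) and its gaps projected onto consensus columns;
insertions relative to the consensus become pooled insertion columns, but
only where at least half the locally aligned rows carry them — otherwise
single-copy alignment artifacts would leak into the core.

**Flank placement.**  Flank sequence is aligned by mutual support rather
than by a general-purpose aligner: flanks are anchored at the core
boundary and compared outward with a +1/−1 walk; each flank contributes
characters only out to its supported extent against the best-supported
reference flank (minimum 20 bp, minimum walk score 10).  Flanks of copies
that do not reach the consensus end, or that cover less than half the
consensus, contribute nothing.  The point of this construction: beyond
the true element end every copy's flank is unrelated genomic context, so
support — and column depth — collapses there.  A conventional aligner
would stack unrelated flanks into compact columns and destroy that
signal.

**Edge detection.**  A side is done when the mean depth over the
outermost 50 flank columns (absent columns counting as zero) falls below
max(2, 0.1 × median core depth).  On a newly closed side, flank columns
are kept outward from the core while their depth stays above the same
threshold and trimmed beyond that collapse point, so an element end lying
inside the 500 bp window is recovered exactly.  Fewer than two collected
loci closes both sides immediately and leaves the consensus unchanged: a
single row can neither support extension nor reach the polishing depth
threshold.

**Polishing.**  Per-column majority vote among non-gap characters, ties
broken in the fixed order A<C<G<T; columns with depth below
max(2, 0.2 × median core depth) are dropped from the termini only, never
from the interior.

**Subfamily splitting.**  Pairwise Kimura 2-parameter distances
(`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, transitions/transversions counted over
columns where both rows have a plain base) feed average-linkage
hierarchical clustering cut at 0.10 substitutions/site; clusters with ≥5
members become subfamilies and smaller clusters join their nearest large
cluster.  Three numerical guards shape this:

* Saturated pairs (1−2P−Q ≤ 0 or 1−2Q ≤ 0) are imputed at the matrix
  maximum.  Pairs sharing fewer than 100 comparable columns — typically
  opposite truncations — carry no subfamily information and are imputed
  at the mean informative distance instead; imputing them high would
  carve families up by truncation pattern.
* A split is accepted only when the mean between-cluster distance exceeds
  1.3× the mean within-cluster distance.  A uniformly diverged family is
  a star-shaped cloud whose pairwise distances straddle any fixed cutoff;
  without a separation criterion, cutoff noise shatters it.
* Rows falling into disconnected components of the comparable-overlap
  graph (two or more components with ≥5 rows) are split by component
  before any distance clustering: rows that share no aligned columns
  cannot belong to one family.  This is what resolves chimeric consensus
  — their copies cover disjoint segments — back into constituent
  families.

## False-positive filtering

Checks run in a fixed order, first failure recorded: (1) full-length
fragments — loci whose merged hit span covers ≥94% of the consensus; a
count ≤1 (the default ceiling, configurable) removes the record;
(2) host-gene/rRNA homology — profile hits at e-value ≤10 whose projected
nucleotide span covers ≥50% of the consensus (the coverage requirement
protects genuine TEs that captured a gene fragment); (3) simple sequence
repeats >60% of the length.  Verdicts are per-record and independent of
library order; raising the FLF ceiling can only remove more records,
never fewer.

SSR tracts are found by an exhaustive period-1..6 scan: for each period a
tract follows a +1 match / −2 mismatch score walk over
`seq[i] == seq[i−p]` and ends at its score maximum (X-drop 12), with
minimum length 12 and ≥80% self-matches.  Ending at the score maximum
stops tracts from leaking into flanking non-repetitive sequence, which a
fixed per-unit mismatch budget does not (after a long perfect tract the
accumulated budget lets the tract run ~100+ bp into random sequence; a
literal per-two-units budget is also degenerate at period 1, where it
tolerates 50% mismatches).

## Classification

Records matching the reference database under the 80-80-80 rule keep the
donor's classification.  The rule takes the merged hits per subject:
longest hit ≥80 bp, length-weighted identity ≥0.80, merged span ≥80% of
the query; 70-70-70 is the same operation relaxed.  All thresholds are
inclusive (≥), and relaxing any threshold can never turn a pass into a
fail.

Structural checking evaluates an editable per-order rules table
(`data/structure_rules.tsv`): e.g. LTR requires direct terminal repeats
or RT+INT domains; LINE a poly(A) tail or RT/EN domain and *no* direct
terminal repeats; SINE poly(A), ≤1 kb and no coding domain; TIR inverted
terminal repeats or a transposase; MITE inverted repeats, no coding
domain, ≤800 bp; Helitron a helicase.  A failing record keeps its
classification but is flagged incomplete (`_inc` id suffix); in
fully-automatic mode it stays in the library, in semiautomatic mode it
goes to the inspection report instead.

Terminal repeat detection: LTRs are the best direct local alignment
between the first and last quarters of the sequence (≥100 bp, ≥80%
identity); TIRs the best ungapped terminal reverse-complement match
starting within 20 nt of each terminus, scored +1/−2 with a minimum score
equal to the minimum length (10) — the score floor keeps the false
discovery rate on random termini negligible (~10⁻⁴ per sequence), at the
documented cost that TIRs near the 10 bp minimum must be near-exact.
Poly(A): a run of ≥10 nt at ≥90% adenine within the last 30 nt, forward
orientation only (library consensus are orientation-normalized upstream).

The three-step rescue of unclassified records: (1) homology at 70-70-70;
(2) coding domains — retrotransposon domains yield order LTR with direct
terminal repeats, LINE with a poly(A) and no terminal repeats, otherwise
the generic class label `ClassI`; DNA-transposon domains yield TIR with
inverted repeats, Helitron with a helicase, otherwise `ClassII`; when
both kinds of domain are present the majority kind wins (ties to
retrotransposon); (3) terminal repeats alone: direct → LTR, inverted →
TIR.  Generic class labels are written in headers exactly as
`name#ClassI` / `name#ClassII`.  The rescue table cannot emit MITE; a
rescued MITE family is labelled TIR, which the tests count as the correct
order since MITEs are nonautonomous TIR elements.

## Benchmarking metrics

Family quality against a reference library: *perfect* — one test
sequence alone matches at >95% identity and >95% coverage of the
reference (a dominant match wins even when minor secondary hits exist);
*good* — several test sequences jointly reach those thresholds;
*present* — the same at >80%/>80%; otherwise *missing*.  Identity per
test sequence is the length-weighted mean across its merged hits.

NTE50/LTE50: copies sorted longest-first are accumulated until the
cumulative length reaches the supplied target (50% of the mobilome, or of
the genome where that is the convention); NTE50 is the number of copies
consumed, LTE50 the length of the last one; undefined when the total
falls short.  Overlapping copies: merged regions (strict overlap only —
book-ended intervals do not merge, the `bedtools merge -d -1` convention)
annotated by ≥2 distinct consensus ids.  Order proportions: per-order
interval unions over the genome length.  Chimeras: records with hits at
>80% identity covering >50% of reference consensus (coverage measured on
the reference/subject side) from two or more distinct orders.

Annotation input is accepted as BED (0-based half-open) or RepeatMasker
`.out` (1-based inclusive, converted on read, `DNA/...` labels resolved
to TIR).

## Simulator

The simulator is the package's test bed.  Families are built from
uniform random DNA with planted structure: identical LTRs, exact inverted
TIRs, a 15 nt poly(A), and back-translated domain peptides.  Each
family's domains are a 15%-diverged variant of the role's consensus
peptide back-translation — domains are conserved across families at the
protein level, not the nucleotide level, and identical nucleotide domains
would let one family's extension walk into another's copies.  Copies are
inserted into an i.i.d. uniform background at per-site divergence with a
2:1 transition:transversion ratio, optional 5′/3′ truncation, and random
strand; every insertion is recorded in a truth table.  Library
degradation adds near-duplicates (~97% identity), central fragments, SSR
decoys (~85% tandem repeat), host-gene decoys (mostly coding, two "exon"
copies of a decoy-profile peptide), single-copy decoys, blanked
classifications and cross-order chimeric concatenations.

The standard scenario (seed 42 by default): six families — 2 LTR, 2 TIR,
1 LINE, 1 MITE — at 15–25 copies, 3–8% divergence, 30% of copies
truncated to 0.3–1.0 completeness, in ~320 kb of background; decoy copies
(3 SSR, 2 gene ×3 copies each; 3 singletons ×1) live on a second contig
without truncation so each decoy reaches the filter that names it.  The
reference database carries two of the six families plus unrelated
classified entries, leaving the other families to the structural
classification path.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: nested/fragmented-into-each-other insertions,
indel divergence (available as an option, off by default so oracle
alignments stay unambiguous), non-uniform base composition and repetitive
background, segmental duplications, satellite arrays beyond period 6,
biological subfamily age structure, and raw-library error modes beyond
the modelled ones.  Desk-scale problem sizes (hundreds of kb, tens of
copies) were chosen so the full suite and the acceptance script run in
minutes; the algorithms themselves are size-independent.

## Determinism

All randomness flows through seeded numpy generators; profile peptides
derive from CRC32 of their role tag; clustering, polishing and reporting
use fixed sort orders and tie-breaks.  Two pipeline runs on identical
inputs produce byte-identical libraries, reports and manifests (the
manifest records no timestamps).

## Known limitations

* Ungapped hit extension under-merges copies with real indels; the
  center-star MSA inherits small column shifts near indels.
* Superfamily assignment comes only from homology; structural evidence
  assigns orders at best (no Copia-vs-Gypsy domain-order logic, no
  target-site-duplication detection).
* The FLF definition (≥94% coverage) and the edge/subfamily constants
  are declared defaults, exposed in `PipelineConfig`, not fitted to data.
* `evaluate_family_quality` measures coverage of the reference by merged
  spans; interspersed low-identity segments inside a merged span are not
  re-examined.
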