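# Methods

`comparome` reimplements, as a tested library, the bespoke computational
layer of a comparative long-read yeast genomics workflow: pairwise
structural-variant (SV) classification and tallying, Ty retrotransposon
annotation with viability calls, pangenome-based gene-loss calling, and a
multi-criterion introgression-candidate ORF filter. Because the real
long-read assemblies such analyses run on are large external datasets, the
package ships a synthetic-panel generator that plants every feature class
the analyses detect, together with machine-readable truth tables; all
quantitative claims about the code are recovery statistics against that
planted truth.

## Synthetic strain panels (`synthdata`)

An ancestral genome is drawn i.i.d. per base at a configurable GC content
(default 0.38, yeast-like). Strains arise by walking a user-supplied strain
tree; each branch applies i.i.d. per-site substitutions at its own rate
(each hit site mutates to a uniformly chosen different base), so strains
below a shared branch share those substitutions. Rates are capped at 0.25
substitutions/site. There is no rate heterogeneity, no recombination, no
indel/microsatellite mutation model, and no read-level simulation — the
generator emulates assembled genomes, not sequencing.

Features are planted after substitution, and all planted intervals are
excluded from background substitution, which keeps every truth coordinate
exact; planted features must not overlap one another within a strain
(validated). Planting directives are applied right-to-left per chromosome
so that earlier edits never shift later truth coordinates; final (edited)
coordinates are recovered through an explicit offset map.

* **SVs**: DEL removes a segment; INS inserts random sequence; DUP appends
  an adjacent tandem copy; INV reverse-complements in place; TRA moves a
  terminal donor segment onto the end of an acceptor chromosome (modeling a
  terminal-transfer translocation of the ~80-kb scale observed between
  yeast chromosomes; reciprocal translocations are out of scope).
* **Ty elements**: a synthetic consensus library mirrors the five yeast Ty
  classes (LTRs ~250–370 bp, internal coding regions ~5 kb built from
  stop-free codons ending in TAA, one declared reading frame). Planted
  states are solo LTR, complete (LTR–internal–LTR) and internally truncated
  (default 2-kb central deletion); loss-of-function lesions are an in-frame
  premature TAA at ~40% of the coding region or a 1-bp coding deletion.
* **Genes / ORFs**: genes occupy fixed non-overlapping intervals; an absent
  gene's interval is replaced by neutral random sequence of the same
  length, so genome length is preserved and presence truth is exact. ORF
  catalogs are extracted from the emitted genomes at the annotated
  coordinates. Introgressed ORFs receive substitutions at a target
  divergence in the focal strains only.

Default rates: the seven-strain study panel uses 0.005 substitutions/site
per branch (0.002 on focal-leaf branches below a shared 0.005 clade
branch, 0.02 on the outgroup stand-in branch). These are fixture choices
representing a plausibly diverged intraspecific panel plus one congeneric
outgroup, not measurements. The SV benchmark panel uses 0.002/site per
derived strain: low enough that, with exact-match seeding (min seed 20 bp)
and chain gaps up to 100 bp, substitution clusters essentially never mimic
a ≥50-bp block break (that would need ~5+ substitutions spaced <20 bp
apart), so recovery statistics measure the classifier rather than seeding
noise.

Everything is a pure function of the configuration (including its seed);
`emit_fixture` writes per-strain FASTA/GFF3/ORF-FASTA, truth TSVs, the Ty
library, an ortholog-group table derived from the presence truth, and an
md5 manifest, byte-identically for identical configs.

What passing these benchmarks does *not* show: robustness to assembly
error, repeats beyond the planted duplications, nested/overlapping
variation, rate heterogeneity, or real Ty sequence diversity. The planted
panels are deliberately clean so that recall/precision = 1 is the correct
expectation.

## Whole-genome alignment (`seqalign`)

Alignment is exact-match seeding plus collinear chaining, a deliberately
transparent stand-in for a MUMmer-class aligner:

* **MEMs**: all maximal exact matches ≥ `min_seed` (default 20 bp) on both
  strands, found by merging k-mer hits along diagonals (exactly equivalent
  to brute-force enumeration, which the tests assert on random pairs up to
  200 bp). N never matches, including N-vs-N.
* **Chaining**: seeds are partitioned by (ref chromosome, query
  chromosome, strand); within a partition the maximum-weight collinear
  chain (weight = summed seed length; gaps on either genome ≤ `max_gap`,
  default 100 bp; overlaps ≤ 25 bp tolerated because MEMs can overrun a
  breakpoint by chance matches) is extracted repeatedly by exact dynamic
  programming. Chains spanning < `min_block` (default 1000 bp) are
  dropped. Block identity = seed-covered columns / block columns.
* **Local alignment** (ORF scale) is affine-gap Smith-Waterman via
  Biopython's PairwiseAligner with BLASTN-like scoring (+1/−1, gap open
  −4, extend −1). Identity is matches over aligned columns (gaps count as
  columns, not matches); query coverage is the aligned query span over
  query length. `scan_gene_presence` reports the longest aligned span of a
  gene per subject sequence, supporting the "longest span ≪ gene length"
  truncation diagnosis.

Coordinates are 0-based half-open everywhere internally; minus-strand
features carry forward-strand query coordinates. Conversion to 1-based
happens only in GFF3 writers. PAF is the alignment interchange format;
round-trip preserves block fields (seed anchors are in-memory only).

## SV classification (`svscan`)

Events ≥ `min_size` (default 50 bp) are classified from the blocks of one
genome pair. Within each reference chromosome the syntenic context is the
query chromosome aligned at the chromosome start (leftmost block); this
anchoring keeps a terminal transfer larger than the retained portion from
masquerading as the context. Rules:

* block on a different query chromosome → TRA (size = reference span);
* "−"-strand block in a collinear context → INV;
* between consecutive collinear "+" blocks: interval overlap ≥ min_size on
  one genome while the other advances → DUP (whichever genome carries the
  extra copy); otherwise gap classification, where the indel size is the
  *difference* of the two gaps (the shared part of both gaps is
  substitution noise around the breakpoint) — DEL if the reference gap
  dominates, INS if the query gap dominates, one DEL plus one INS if both
  gaps independently exceed min_size;
* pairs of collinear blocks separated by an intervening INV/TRA block are
  not gap-classified (the intervening event explains the gap);
* inside a block, consecutive seed-anchor gaps whose difference is
  ≥ min_size are called DEL/INS. This is what makes the 50-bp threshold
  sharp: an indel smaller than `max_gap` never splits a chain, but its
  asymmetric anchor gap is unambiguous, while substitution clusters
  produce equal gaps on both genomes and can never fire the rule.

Events with identical (type, reference interval) are merged, leftmost
representation. Breakpoints are localized to within the seeding length: a
substitution within `min_seed` bp of a junction hides the flanking
mini-seed, so planted-truth evaluation matches calls within ±25 bp
(min_seed + slack); on substitution-free fixtures calls are within a few
bp of truth. Nested/overlapping variation and read-backed validation are
out of scope.

The all-vs-all design runs every ordered (reference, query) pair — n
strains give n(n−1) comparisons, 210 for 15 strains — and summaries report
per-reference mean/min/max totals and per-type means.

## Ty annotation (`tyscan`)

Each library part (LTR, internal) is scanned against the genome by MEM
chaining with a generous 2.5-kb chain gap so internal truncations up to
~2.5 kb stay within one hit; hits are filtered at ≥80% identity over ≥50%
of the consensus part. A locus hit by several classes goes to the
higher-identity class; an exact Ty1/Ty2 tie gets the pooled "Ty1/Ty2"
label. Greedy left-to-right grouping within a 10-kb pairing window (chosen
to exceed the ~6-kb full element length) and the same strand/class yields
states: LTR+internal+LTR with ≥95% internal consensus coverage → complete;
any internal hit otherwise → truncated; lone LTR → solo LTR.

Viability: the internal region is anchored to the consensus by MEM chains;
each declared coding region is translated in its declared frame. A stop
codon before the consensus stop, a net coding indel not divisible by
three, or any single indel run ≥ 30 bp ("extensive frameshift",
configurable) → loss of function; solo LTRs are not applicable. Silent
substitutions cannot change the call, since only stops and indels are
consulted.

The transposition-vs-duplication test extracts the ~10-kb regions
containing two same-class elements, masks the elements themselves with N
(so element-sequence identity cannot masquerade as flank identity), and
chains MEMs between the regions: identity ≥ 90% over ≥ 50% of the shorter
unmasked region (inclusive comparisons) → segmental duplication; seed
coverage at background level (≤ 5%) → independent transposition; anything
between → indeterminate.

## Gene content (`genecontent`)

The presence/absence matrix is built from an ortholog-group table
(group_id, strain, gene_id); presence = the strain has ≥1 member. Strains
carry role tags (focal / other conspecific / outgroup). Two loss
definitions: *candidate losses* are genes in the non-focal conspecific
pangenome that also occur in ≥1 outgroup and in no focal strain; *missing
core genes* are genes in all non-focal conspecific strains and in no focal
strain. Both are validated against set-comprehension oracles on random
matrices.

The introgression filter evaluates each ORF of the first focal strain (the
clade anchor). Focal-clade presence is operationalized as reciprocal best
local alignment at ≥80% identity over ≥50% of the query in every focal
strain — the coverage condition exists because a short high-identity local
segment between unrelated ORFs is not orthology. For each focal copy, the
best hit per non-focal strain is found by alignment score (candidates
pre-ranked by shared 15-mer count; equal scores tie-break to the
lexicographically smallest id). Pooling the clade's alignments per ORF,
the four criteria are: (i) found in all focal strains; (ii) mean identity
≤ 95%; (iii) mean query coverage ≥ 0.75 (a per-alignment-minimum mode is
available); (iv) fraction of alignments with identity ≤ 95% at least 2/3.
All thresholds are inclusive, applied to nucleotide identity, and
configurable. The "two-thirds of alignments" clause is read per-ORF across
the clade's alignments rather than pooled over the whole ORF set; ORFs
with no non-focal hit are reported with a `no_hit` reason rather than
silently dropped. On substitution-only fixtures the filter is monotone in
planted divergence.

## Pipeline (`pipeline`, CLI `comparome`)

One YAML configuration (unknown keys rejected by name, defaults filled)
drives simulate → align → sv → ty → genes. Each stage writes its own
subdirectory once; alignments travel between stages as PAF; the report
JSON carries output paths, record counts, the parameter echo, version and
runtime. Determinism is end-to-end: identical config + seed reproduces the
output tree byte-for-byte (the report's runtime field aside). Problem
sizes of the shipped presets — 100–250 kb genomes, 6–7 strains, ≤30 ORFs
per strain — were chosen so a full benchmark cycle runs in minutes on one
CPU while still exercising every code path at realistic feature scales.

## Reproducing the numbers

`scripts/acceptance.py --seed N --out results.json` regenerates every
fixture from the seed, reruns all evaluations, and writes the recovery
statistics plus the default panel's analysis counts. The panel plants 7
candidate gene losses (4 of them missing core genes via full conspecific
support, plus 2 missing-core-only genes lacking outgroup support) and 3
introgressed ORFs; the reported counts are recomputed by the pipeline at
run time.

## Known limitations

* The aligner is exact-match seeded: highly diverged pairs (≳5%/site)
  fragment into short chains and SV calls degrade; the intended regime is
  intraspecific comparison.
* Breakpoint localization is limited to ~min_seed bp next to substitution
  clusters (see above).
* DUP calls do not distinguish tandem from dispersed duplication beyond
  the adjacency implied by the overlap rule; inversions flanked by indels
  suppress gap calls across the inverted block.
* E-value statistics are deliberately not reproduced; alignment score and
  span are reported instead.
* The Ty library is synthetic; real-library idiosyncrasies (shared
  Ty1/Ty2 homology, soloLTR divergence dating) are outside the planted
  model except for the explicit identity-tie rule.
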