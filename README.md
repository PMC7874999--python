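# comparome

Comparative yeast genomics with planted-truth benchmarking: pairwise
structural-variant (SV) classification, Ty retrotransposon annotation with
viability calls, pangenome gene-loss calling, and an introgression-candidate
ORF filter — together with a synthetic strain-panel generator that plants
every feature class these analyses detect and emits exact truth tables.

## Who this is for

Comparative genomics studies of *Saccharomyces cerevisiae* (and similar
small eukaryotes) increasingly rest on long-read assemblies compared
all-vs-all: SVs ≥50 bp of five types (deletions, insertions, duplications,
inversions, translocations), LTR retrotransposon (Ty1–Ty5) content split
into complete / truncated / solo-LTR states with a functional-viability
call, clade-restricted gene losses against a pangenome, and ORFs whose
anomalously low identity to conspecifics suggests introgression. This
package implements that analysis layer as a reusable, fully tested library
with a CLI, and — because the real assemblies are large external data —
ships a simulator so every stage is validated by recall/precision against
planted ground truth.

## The core methods

* **Alignment**: all maximal exact matches (MEMs) ≥ 20 bp on both strands,
  chained into maximal collinear blocks by exact dynamic programming
  (gaps ≤ 100 bp, blocks ≥ 1 kb). ORF-scale comparisons use affine-gap
  local alignment (match +1, mismatch −1, gap open −4, extend −1);
  identity = matches / aligned columns, coverage = aligned query span /
  query length.
* **SV classification** from block structure: reference-gap → DEL,
  query-gap → INS (sizes are the gap *difference*, so substitution noise
  around a breakpoint cancels), interval re-use on one genome → DUP,
  strand flip → INV, query-chromosome switch → TRA; events ≥ 50 bp, one
  leftmost representation each. n strains → n(n−1) ordered comparisons
  (15 strains → 210).
* **Ty annotation**: consensus LTR/internal hits grouped within a 10-kb
  window into complete / truncated / solo-LTR loci; premature stop codons
  or extensive frameshifts (net coding indel not a multiple of 3, or an
  indel run ≥ 30 bp) mark an element loss-of-function; a 10-kb masked-flank
  comparison separates segmental duplication from independent
  transposition.
* **Gene content**: candidate losses = genes in the non-focal conspecific
  pangenome, present in ≥1 outgroup, absent from the focal clade; missing
  core genes = genes in *all* non-focal conspecifics, absent from the
  focal clade. Introgression candidates must be found in all focal
  strains, have mean identity ≤ 95% against non-focal best hits, ≥ 75%
  query coverage, and ≥ 2/3 of alignments at ≤ 95% identity (all
  inclusive).

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

Run the seven-strain demonstration panel — a 3-strain focal clade sharing
an 80-kb terminal translocation, three other conspecific strains, one
outgroup stand-in; planted gene losses, Ty loci and introgressed ORFs:

```sh
comparome run --seed 5 --out panel_run
```

which prints the consolidated record counts:

```json
{
  "alignment_blocks": 330,
  "candidate_gene_losses": 7,
  "introgression_candidates": 3,
  "missing_core_genes": 6,
  "pairwise_comparisons": 42,
  "strains": 7,
  "structural_variants": 340,
  "ty_elements": 13
}
```

Reading the numbers: 7 strains give 42 ordered alignment comparisons; the
gene stage recovers exactly the planted content — 7 candidate gene losses
(absent from the focal clade, supported by the outgroup), 6 missing core
genes (absent from the focal clade, present in every other conspecific),
and 3 introgression-candidate ORFs (planted at 8% divergence, detected at
~92% identity); 13 Ty loci are the planted solo LTRs and complete Ty5
elements. Per-stage tables (PAF alignments, per-pair SV TSV/BEDPE, the SV
count matrix and per-reference summary, per-strain Ty annotations and the
composition table, the presence/absence matrix and candidate lists) are
under `panel_run/`, with `report.json` tying them together. Rerunning with
the same seed reproduces the tree byte-for-byte.

Individual stages are available as `comparome simulate|align|sv|ty|genes`,
and everything is importable:

```python
from comparome.synthdata import sv_benchmark_config, simulate
from comparome.seqalign import align_genomes
from comparome.svscan import call_svs

fx = simulate(sv_benchmark_config(seed=1))
calls = call_svs(align_genomes(fx.genomes["base"], fx.genomes["sv1"]))
# five events: one DEL, INS, DUP, INV and TRA, matching fx.truth.planted_svs
```

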