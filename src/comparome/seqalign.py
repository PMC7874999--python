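"""Pairwise whole-genome alignment by exact-match seeding and collinear chaining.

The aligner finds all maximal exact matches (MEMs) of a minimum length
between two sequences on both strands, then partitions them into maximal
collinear chains under a gap rule. Chains become :class:`AlignmentBlock`
records that downstream structural-variant classification consumes. Local
ORF-scale alignment (affine-gap Smith-Waterman, via Bio.Align) reports the
percent-identity and query-coverage quantities used by the introgression
filter, and a gene-presence scanner reports longest aligned spans of a gene
against a subject sequence set.

Coordinates are 0-based half-open; query coordinates of "-" strand features
are always given on the forward strand of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .genome import Genome, revcomp

DEFAULT_MIN_SEED = 20
DEFAULT_MAX_GAP = 100
DEFAULT_MIN_BLOCK = 1000

#: Overlap (bp) tolerated between consecutive seeds in a chain. Maximal
#: matches flanking an indel can overrun the breakpoint by a few chance
#: matches, producing slightly negative gaps.
CHAIN_OVERLAP_SLACK = 25


@dataclass(frozen=True)
class MatchSeed:
    """A maximal exact match between reference and query."""

    ref_chrom: str
    ref_start: int
    qry_chrom: str
    qry_start: int  # forward strand of the query
    length: int
    strand: str  # "+" or "-"

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


@dataclass
class AlignmentBlock:
    """One collinear aligned segment between a reference and a query genome."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int  # forward strand
    qry_end: int
    strand: str
    identity: float  # percent, 0..100
    n_seeds: int
    # seed anchors (ref_start, qry_start, length) retained for intra-block
    # indel scanning; not serialized to PAF
    seeds: list[tuple[int, int, int]] = field(default_factory=list, repr=False)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


# --------------------------------------------------------------------------
# MEM finding
# --------------------------------------------------------------------------

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer codes and a validity mask (windows containing non-ACGT
    bases are invalid; N never matches, including N-vs-N)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    code = np.zeros(n, dtype=np.int64)
    for i in range(k):
        code = code * 4 + arr[i : i + n]
    bad = (arr >= 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return code, valid


def _mems_one_strand(ref: str, qry: str, k: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches >= k between ref and qry (forward only),
    as (ref_start, qry_start, length)."""
    if len(ref) < k or len(qry) < k:
        return []
    r = _encode(ref)
    q = _encode(qry)
    rcode, rvalid = _kmer_codes(r, k)
    qcode, qvalid = _kmer_codes(q, k)
    rpos = np.nonzero(rvalid)[0]
    qpos = np.nonzero(qvalid)[0]
    if rpos.size == 0 or qpos.size == 0:
        return []
    rcode = rcode[rpos]
    qcode = qcode[qpos]
    order = np.argsort(rcode, kind="stable")
    sorted_codes = rcode[order]
    left = np.searchsorted(sorted_codes, qcode, "left")
    right = np.searchsorted(sorted_codes, qcode, "right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return []
    qidx = np.repeat(np.arange(qcode.size), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    flat = np.arange(total) - np.repeat(offsets[:-1], counts) + np.repeat(left, counts)
    ridx = order[flat]
    ri = rpos[ridx]
    qi = qpos[qidx]
    # merge k-mer hits into maximal runs per diagonal: a hit at (ri, qi)
    # belongs to the same maximal match as a hit at (ri+1, qi+1)
    diag = qi - ri
    o = np.lexsort((ri, diag))
    ri, qi, diag = ri[o], qi[o], diag[o]
    new_run = np.ones(ri.size, dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (ri[1:] != ri[:-1] + 1)
    starts = np.nonzero(new_run)[0]
    ends = np.concatenate([starts[1:], [ri.size]]) - 1
    lengths = ri[ends] - ri[starts] + k
    return list(zip(ri[starts].tolist(), qi[starts].tolist(), lengths.tolist()))


def find_mems(
    ref_seq: str,
    qry_seq: str,
    min_len: int = DEFAULT_MIN_SEED,
    ref_chrom: str = "ref",
    qry_chrom: str = "qry",
) -> list[MatchSeed]:
    """All maximal exact matches >= ``min_len`` on both strands.

    N never matches (including N-vs-N). Deterministic; sorted by
    (ref_start, qry_start, strand). Empty sequences yield an empty result.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    seeds: list[MatchSeed] = []
    for r0, q0, ln in _mems_one_strand(ref_seq, qry_seq, min_len):
        seeds.append(MatchSeed(ref_chrom, r0, qry_chrom, q0, ln, "+"))
    qlen = len(qry_seq)
    for r0, q0_rc, ln in _mems_one_strand(ref_seq, revcomp(qry_seq), min_len):
        seeds.append(
            MatchSeed(ref_chrom, r0, qry_chrom, qlen - (q0_rc + ln), ln, "-")
        )
    seeds.sort(key=lambda s: (s.ref_start, s.qry_start, s.strand))
    return seeds


# --------------------------------------------------------------------------
# Chaining
# --------------------------------------------------------------------------


def _chain_coords(seed: MatchSeed) -> tuple[int, int]:
    """Query coordinates in chain orientation: forward coords on "+",
    reverse-strand coords (descending forward order) mapped to an ascending
    axis on "-". Only gap arithmetic uses these."""
    if seed.strand == "+":
        return seed.qry_start, seed.qry_end
    # ascending along the reverse strand == descending forward coordinate
    return -seed.qry_end, -seed.qry_start


def chain_link_ok(a: MatchSeed, b: MatchSeed, max_gap: int) -> bool:
    """Whether seed ``b`` may directly follow seed ``a`` in a chain:
    ordered on both sequences with neither inter-seed gap exceeding
    ``max_gap`` (small overlaps tolerated)."""
    if b.ref_start <= a.ref_start:
        return False
    a_q0, a_q1 = _chain_coords(a)
    b_q0, b_q1 = _chain_coords(b)
    if b_q0 <= a_q0:
        return False
    ref_gap = b.ref_start - a.ref_end
    qry_gap = b_q0 - a_q1
    return (
        -CHAIN_OVERLAP_SLACK <= ref_gap <= max_gap
        and -CHAIN_OVERLAP_SLACK <= qry_gap <= max_gap
    )


def _best_chain(seeds: list[MatchSeed], max_gap: int) -> list[int]:
    """Max-weight collinear chain (weight = total seed length) among
    ``seeds``, by O(n^2) dynamic programming with numpy-vectorized inner
    loop. Ties broken toward the earlier predecessor. Returns indices."""
    n = len(seeds)
    order = sorted(range(n), key=lambda i: (seeds[i].ref_start, _chain_coords(seeds[i])[0]))
    ref_start = np.array([seeds[i].ref_start for i in order])
    ref_end = np.array([seeds[i].ref_end for i in order])
    q0 = np.array([_chain_coords(seeds[i])[0] for i in order])
    q1 = np.array([_chain_coords(seeds[i])[1] for i in order])
    length = np.array([seeds[i].length for i in order])
    score = length.astype(np.int64).copy()
    back = np.full(n, -1, dtype=np.int64)
    for j in range(1, n):
        ok = (
            (ref_start[:j] < ref_start[j])
            & (q0[:j] < q0[j])
            & (ref_start[j] - ref_end[:j] <= max_gap)
            & (ref_start[j] - ref_end[:j] >= -CHAIN_OVERLAP_SLACK)
            & (q0[j] - q1[:j] <= max_gap)
            & (q0[j] - q1[:j] >= -CHAIN_OVERLAP_SLACK)
        )
        if ok.any():
            cand = np.where(ok, score[:j], np.int64(-(1 << 60)))
            p = int(np.argmax(cand))
            if cand[p] + length[j] > score[j]:
                score[j] = cand[p] + length[j]
                back[j] = p
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(order[best])
        best = int(back[best])
    chain.reverse()
    return chain


def _block_from_chain(chain: list[MatchSeed]) -> AlignmentBlock:
    ref_start = min(s.ref_start for s in chain)
    ref_end = max(s.ref_end for s in chain)
    qry_start = min(s.qry_start for s in chain)
    qry_end = max(s.qry_end for s in chain)
    # union of seed cover on the reference = matched columns
    ivs = sorted((s.ref_start, s.ref_end) for s in chain)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s0, e0 in ivs[1:]:
        if s0 > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s0, e0
        else:
            cur_e = max(cur_e, e0)
    covered += cur_e - cur_s
    columns = max(ref_end - ref_start, qry_end - qry_start)
    identity = min(100.0, 100.0 * covered / columns) if columns else 100.0
    anchors = sorted((s.ref_start, s.qry_start, s.length) for s in chain)
    return AlignmentBlock(
        ref_chrom=chain[0].ref_chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        qry_chrom=chain[0].qry_chrom,
        qry_start=qry_start,
        qry_end=qry_end,
        strand=chain[0].strand,
        identity=identity,
        n_seeds=len(chain),
        seeds=anchors,
    )


def chain_seeds(
    seeds: Sequence[MatchSeed],
    max_gap: int = DEFAULT_MAX_GAP,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> list[AlignmentBlock]:
    """Partition seeds into maximal collinear chains.

    Seeds are first partitioned by (ref_chrom, qry_chrom, strand); within a
    partition the highest-weight chain (total seed length, exact DP) is
    extracted repeatedly until no seeds remain. Chains whose longer span is
    below ``min_block`` are dropped. Block identity is the fraction of block
    columns covered by seeds, in percent.
    """
    groups: dict[tuple[str, str, str], list[MatchSeed]] = {}
    for s in seeds:
        groups.setdefault((s.ref_chrom, s.qry_chrom, s.strand), []).append(s)
    blocks: list[AlignmentBlock] = []
    for key in sorted(groups):
        remaining = groups[key]
        while remaining:
            idx = _best_chain(remaining, max_gap)
            chain = [remaining[i] for i in idx]
            picked = set(idx)
            remaining = [s for i, s in enumerate(remaining) if i not in picked]
            block = _block_from_chain(chain)
            if max(block.ref_span, block.qry_span) >= min_block:
                blocks.append(block)
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return blocks


def align_genomes(
    ref: Genome,
    qry: Genome,
    min_seed: int = DEFAULT_MIN_SEED,
    max_gap: int = DEFAULT_MAX_GAP,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> list[AlignmentBlock]:
    """Whole-genome alignment: MEM seeding + chaining per chromosome pair.

    Blocks are reported in reference coordinate order. Repeats may yield
    overlapping blocks; these are passed through for the SV classifier to
    resolve.
    """
    if len(ref) == 0 or len(qry) == 0:
        raise ValueError("cannot align a genome with zero chromosomes")
    seeds: list[MatchSeed] = []
    for rc, rseq in ref.chromosomes.items():
        for qc, qseq in qry.chromosomes.items():
            seeds.extend(find_mems(rseq, qseq, min_seed, ref_chrom=rc, qry_chrom=qc))
    return chain_seeds(seeds, max_gap=max_gap, min_block=min_block)


# --------------------------------------------------------------------------
# Local (ORF-scale) alignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Identity / coverage / span summary of one optimal local alignment."""

    identity: float  # percent over aligned columns (gaps count as columns)
    query_coverage: float  # fraction of query length inside the aligned region
    aligned_span: int  # bp spanned on the target
    score: float


DEFAULT_SCORING = {"match": 1, "mismatch": -1, "gap_open": -4, "gap_extend": -1}


def _aligner(scoring: dict | None) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    return Align.PairwiseAligner(
        mode="local",
        match_score=sc["match"],
        mismatch_score=sc["mismatch"],
        open_gap_score=sc["gap_open"],
        extend_gap_score=sc["gap_extend"],
    )


def local_align(
    query: str, target: str, scoring: dict | None = None
) -> LocalAlignmentResult:
    """Optimal local alignment of ``query`` against ``target`` under affine
    gap scoring (BLASTN-like defaults). Identity is matches over aligned
    columns x 100; gap columns inside the aligned region count as columns.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(scoring)
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return LocalAlignmentResult(0.0, 0.0, 0, 0.0)
    aln = alignments[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    identity = 100.0 * c.identities / columns if columns else 0.0
    t_aligned, q_aligned = aln.aligned
    q_lo = int(q_aligned[0][0])
    q_hi = int(q_aligned[-1][1])
    t_lo = int(t_aligned[0][0])
    t_hi = int(t_aligned[-1][1])
    return LocalAlignmentResult(
        identity=identity,
        query_coverage=(q_hi - q_lo) / len(query),
        aligned_span=t_hi - t_lo,
        score=float(aln.score),
    )


@dataclass(frozen=True)
class PresenceHit:
    """Best local-alignment hit of a gene against one subject sequence."""

    subject: str
    span: int
    identity: float
    score: float
    target_start: int
    target_end: int


def scan_gene_presence(
    gene: str,
    subject: Genome | dict[str, str],
    min_report: float = 25.0,
    scoring: dict | None = None,
) -> list[PresenceHit]:
    """Longest local-alignment spans of ``gene`` against each subject
    sequence, sorted by score (descending). Supports the diagnosis pattern
    where the longest aligned span is far below the gene length (gene
    truncated or absent). Hits scoring below ``min_report`` are omitted.
    """
    if not gene:
        raise ValueError("gene sequence must be non-empty")
    seqs = subject.chromosomes if isinstance(subject, Genome) else subject
    aligner = _aligner(scoring)
    hits: list[PresenceHit] = []
    for name, seq in seqs.items():
        if not seq:
            continue
        best = None
        for g in (gene, revcomp(gene)):
            alignments = aligner.align(seq, g)
            if len(alignments) == 0 or alignments.score < min_report:
                continue
            aln = alignments[0]
            if best is None or aln.score > best.score:
                c = aln.counts()
                columns = c.identities + c.mismatches + c.internal_gaps
                t_aligned, _ = aln.aligned
                t_lo, t_hi = int(t_aligned[0][0]), int(t_aligned[-1][1])
                best = PresenceHit(
                    subject=name,
                    span=t_hi - t_lo,
                    identity=100.0 * c.identities / columns if columns else 0.0,
                    score=float(aln.score),
                    target_start=t_lo,
                    target_end=t_hi,
                )
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, h.subject))
    return hits


# --------------------------------------------------------------------------
# PAF interchange
# --------------------------------------------------------------------------


class PafParseError(ValueError):
    pass


def write_paf(
    blocks: Iterable[AlignmentBlock],
    path: str | Path,
    ref_lengths: dict[str, int] | None = None,
    qry_lengths: dict[str, int] | None = None,
) -> None:
    """Write blocks as 12-column PAF (query-first convention; 0-based
    half-open; forward-strand query coordinates)."""
    ref_lengths = ref_lengths or {}
    qry_lengths = qry_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            matches = int(round(b.identity / 100.0 * max(b.ref_span, b.qry_span)))
            cols = [
                b.qry_chrom,
                qry_lengths.get(b.qry_chrom, b.qry_end),
                b.qry_start,
                b.qry_end,
                b.strand,
                b.ref_chrom,
                ref_lengths.get(b.ref_chrom, b.ref_end),
                b.ref_start,
                b.ref_end,
                matches,
                max(b.ref_span, b.qry_span),
                255,
            ]
            fh.write("\t".join(str(c) for c in cols) + f"\tns:i:{b.n_seeds}\n")


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read 12-column PAF back into alignment blocks. Round-trip through
    :func:`write_paf` is lossless for the block fields (seed anchors are not
    serialized)."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise PafParseError(
                    f"line {lineno}: expected >=12 PAF columns, got {len(cols)}"
                )
            try:
                qry_chrom = cols[0]
                qry_start, qry_end = int(cols[2]), int(cols[3])
                strand = cols[4]
                ref_chrom = cols[5]
                ref_start, ref_end = int(cols[7]), int(cols[8])
                matches = int(cols[9])
                aln_len = int(cols[10])
            except ValueError as exc:
                raise PafParseError(f"line {lineno}: {exc}") from exc
            if strand not in "+-":
                raise PafParseError(f"line {lineno}: bad strand {strand!r}")
            n_seeds = 1
            for tag in cols[12:]:
                if tag.startswith("ns:i:"):
                    n_seeds = int(tag[5:])
            identity = 100.0 * matches / aln_len if aln_len else 100.0
            blocks.append(
                AlignmentBlock(
                    ref_chrom=ref_chrom,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    qry_chrom=qry_chrom,
                    qry_start=qry_start,
                    qry_end=qry_end,
                    strand=strand,
                    identity=identity,
                    n_seeds=n_seeds,
                )
            )
    return blocks
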