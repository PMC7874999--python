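"""Structural-variant classification from whole-genome alignment blocks.

Events >= 50 bp between a reference and a query genome are classified into
five types: deletions (DEL), insertions (INS), duplications (DUP),
inversions (INV), and translocations (TRA). Classification operates on the
collinear blocks produced by :mod:`comparome.seqalign`:

* between consecutive same-strand collinear blocks, a reference gap without
  a matching query gap is a DEL, a query gap without a reference gap an INS,
  and a large gap on both sides one DEL plus one INS;
* a block pair whose intervals overlap on one genome by >= min_size while
  the other genome advances is a DUP (the genome that advances carries the
  extra copy; both orientations are reported as DUP);
* a "-"-strand block inside an otherwise collinear context is an INV;
* a block whose query chromosome differs from the dominant query chromosome
  of its reference-chromosome context is a TRA (terminal-segment transfer).

Because blocks are exact-match chains, an indel smaller than the chaining
``max_gap`` never splits a block; those events appear as asymmetric gaps
between consecutive seed anchors inside one block and are called from there
(substitution clusters produce equal gaps on both genomes, which never
trigger a call).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import Genome
from .seqalign import AlignmentBlock, align_genomes

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")
DEFAULT_MIN_SIZE = 50


@dataclass(frozen=True)
class StructuralVariant:
    """A classified structural event (coordinates 0-based half-open;
    query coordinates on the forward strand)."""

    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    size: int

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")


def _dominant_qry_chrom(blocks: list[AlignmentBlock]) -> str:
    """Query chromosome forming the syntenic context of a reference
    chromosome: the one aligned at the reference chromosome start (leftmost
    block, ties broken toward the larger block). Anchoring on the start
    rather than on total span keeps a terminal-segment transfer larger than
    the retained portion from masquerading as the context."""
    leftmost = min(blocks, key=lambda b: (b.ref_start, -b.ref_span, b.qry_chrom))
    return leftmost.qry_chrom


def _intra_block_indels(block: AlignmentBlock, min_size: int) -> list[StructuralVariant]:
    """DEL/INS from asymmetric gaps between consecutive seed anchors."""
    out: list[StructuralVariant] = []
    if len(block.seeds) < 2 or block.strand != "+":
        return out
    anchors = block.seeds
    for (r0, q0, l0), (r1, q1, _l1) in zip(anchors, anchors[1:]):
        ref_gap = r1 - (r0 + l0)
        qry_gap = q1 - (q0 + l0)
        d = ref_gap - qry_gap
        if d >= min_size:
            start = r0 + l0 + max(qry_gap, 0)
            out.append(
                StructuralVariant(
                    "DEL", block.ref_chrom, start, start + d,
                    block.qry_chrom, q0 + l0, q0 + l0, d,
                )
            )
        elif -d >= min_size:
            start = q0 + l0 + max(ref_gap, 0)
            out.append(
                StructuralVariant(
                    "INS", block.ref_chrom, r0 + l0, r0 + l0,
                    block.qry_chrom, start, start - d, -d,
                )
            )
    return out


def call_svs(
    blocks: list[AlignmentBlock], min_size: int = DEFAULT_MIN_SIZE
) -> list[StructuralVariant]:
    """Classify structural variants >= ``min_size`` from the alignment
    blocks of one reference/query genome pair.

    Events are reported once, leftmost representation; events with an
    identical (type, reference interval) arising from overlapping block
    pairs are merged. ``min_size`` applies to the event's larger side.
    """
    by_ref: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chrom, []).append(b)
    events: list[StructuralVariant] = []
    for ref_chrom in sorted(by_ref):
        chrom_blocks = sorted(
            by_ref[ref_chrom], key=lambda b: (b.ref_start, b.ref_end, b.qry_start)
        )
        for i in range(1, len(chrom_blocks)):
            if chrom_blocks[i].ref_start < chrom_blocks[i - 1].ref_start:
                raise ValueError("alignment blocks are not sortable by position")
        dominant = _dominant_qry_chrom(chrom_blocks)
        collinear: list[AlignmentBlock] = []
        # a pair of collinear blocks separated by an INV/TRA block must not
        # be gap-classified: the intervening event explains the gap
        separated: list[bool] = []
        pending_sep = False
        for b in chrom_blocks:
            if b.qry_chrom != dominant:
                # reference segment joined onto a different query chromosome
                if b.ref_span >= min_size:
                    events.append(
                        StructuralVariant(
                            "TRA", ref_chrom, b.ref_start, b.ref_end,
                            b.qry_chrom, b.qry_start, b.qry_end, b.ref_span,
                        )
                    )
                pending_sep = True
                continue
            if b.strand == "-":
                if b.ref_span >= min_size:
                    events.append(
                        StructuralVariant(
                            "INV", ref_chrom, b.ref_start, b.ref_end,
                            b.qry_chrom, b.qry_start, b.qry_end, b.ref_span,
                        )
                    )
                pending_sep = True
                continue
            collinear.append(b)
            separated.append(pending_sep)
            pending_sep = False
            events.extend(_intra_block_indels(b, min_size))
        # gaps and overlaps between consecutive collinear "+" blocks
        for a, b, sep in zip(collinear, collinear[1:], separated[1:]):
            if sep:
                continue
            ref_gap = b.ref_start - a.ref_end
            qry_gap = b.qry_start - a.qry_end
            if ref_gap <= -min_size and qry_gap > -min_size:
                # reference re-covers an interval while the query advances:
                # the query genome carries the extra (tandem) copy
                events.append(
                    StructuralVariant(
                        "DUP", ref_chrom, b.ref_start, a.ref_end,
                        b.qry_chrom, a.qry_end, b.qry_start + (a.ref_end - b.ref_start),
                        -ref_gap,
                    )
                )
                continue
            if qry_gap <= -min_size and ref_gap > -min_size:
                # query interval overlaps a previously used query interval
                # while the reference advances: extra copy in the reference
                events.append(
                    StructuralVariant(
                        "DUP", ref_chrom, a.ref_end, a.ref_end - qry_gap,
                        b.qry_chrom, b.qry_start, a.qry_end, -qry_gap,
                    )
                )
                continue
            rg = max(ref_gap, 0)
            qg = max(qry_gap, 0)
            # the shared portion of the two gaps is substitution noise
            # around the breakpoint; the indel itself is the difference
            d = rg - qg
            if qg < min_size and d >= min_size:
                events.append(
                    StructuralVariant(
                        "DEL", ref_chrom, a.ref_end + qg, a.ref_end + qg + d,
                        b.qry_chrom, a.qry_end + qg, a.qry_end + qg, d,
                    )
                )
            elif rg < min_size and -d >= min_size:
                events.append(
                    StructuralVariant(
                        "INS", ref_chrom, a.ref_end + rg, a.ref_end + rg,
                        b.qry_chrom, a.qry_end + rg, a.qry_end + rg - d, -d,
                    )
                )
            elif rg >= min_size and qg >= min_size:
                events.append(
                    StructuralVariant(
                        "DEL", ref_chrom, a.ref_end, a.ref_end + rg,
                        b.qry_chrom, a.qry_end, a.qry_end, rg,
                    )
                )
                events.append(
                    StructuralVariant(
                        "INS", ref_chrom, a.ref_end, a.ref_end,
                        b.qry_chrom, a.qry_end, a.qry_end + qg, qg,
                    )
                )
    # duplicate suppression: identical (type, ref interval) merged,
    # leftmost-lowest wins ties
    events.sort(
        key=lambda e: (e.ref_chrom, e.ref_start, e.ref_end, e.type, e.qry_chrom, e.qry_start)
    )
    seen: set[tuple] = set()
    unique: list[StructuralVariant] = []
    for e in events:
        key = (e.type, e.ref_chrom, e.ref_start, e.ref_end)
        if key in seen:
            continue
        seen.add(key)
        unique.append(e)
    return unique


# --------------------------------------------------------------------------
# All-vs-all pairwise design
# --------------------------------------------------------------------------


def enumerate_pairs(strains: list[str]) -> list[tuple[str, str]]:
    """Exhaustive ordered reference-query pairs; n strains -> n(n-1)."""
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain names")
    return [(r, q) for r, q in itertools.permutations(strains, 2)]


@dataclass
class SVMatrix:
    """Per ordered strain pair: per-type SV counts and totals."""

    strains: list[str]
    counts: pd.DataFrame  # index (ref, qry); columns DEL..TRA, total

    def total(self, ref: str, qry: str) -> int:
        return int(self.counts.loc[(ref, qry), "total"])


def pairwise_sv_matrix(
    genomes: list[Genome],
    min_seed: int | None = None,
    max_gap: int | None = None,
    min_block: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
) -> SVMatrix:
    """Align every ordered (reference, query) genome pair and tabulate SV
    counts per type. 15 strains yield 210 comparisons."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain names")
    kw = {}
    if min_seed is not None:
        kw["min_seed"] = min_seed
    if max_gap is not None:
        kw["max_gap"] = max_gap
    if min_block is not None:
        kw["min_block"] = min_block
    by_name = {g.name: g for g in genomes}
    rows = []
    for ref_name, qry_name in enumerate_pairs(names):
        blocks = align_genomes(by_name[ref_name], by_name[qry_name], **kw)
        svs = call_svs(blocks, min_size=min_size)
        row = {"ref": ref_name, "qry": qry_name}
        for t in SV_TYPES:
            row[t] = sum(1 for e in svs if e.type == t)
        row["total"] = len(svs)
        rows.append(row)
    counts = pd.DataFrame(rows).set_index(["ref", "qry"])
    return SVMatrix(strains=names, counts=counts)


def summarize_sv(matrix: SVMatrix, strain_order: list[str] | None = None) -> pd.DataFrame:
    """Per strain-as-reference summary: mean/min/max of totals across its
    comparisons, plus per-type means."""
    if matrix.counts.empty:
        raise ValueError("empty SV matrix")
    order = strain_order or matrix.strains
    rows = []
    for strain in order:
        sub = matrix.counts.xs(strain, level="ref")
        row = {
            "strain": strain,
            "mean_total": float(sub["total"].mean()),
            "min_total": int(sub["total"].min()),
            "max_total": int(sub["total"].max()),
        }
        for t in SV_TYPES:
            row[f"mean_{t}"] = float(sub[t].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain")


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def write_bedpe(svs: list[StructuralVariant], path: str | Path) -> None:
    """BEDPE: ref interval, qry interval, name=type, score=size, strands."""
    with open(path, "w") as fh:
        for e in svs:
            strand = "-" if e.type == "INV" else "+"
            fh.write(
                f"{e.ref_chrom}\t{e.ref_start}\t{e.ref_end}\t"
                f"{e.qry_chrom}\t{e.qry_start}\t{e.qry_end}\t"
                f"{e.type}\t{e.size}\t+\t{strand}\n"
            )


def svs_to_frame(svs: list[StructuralVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "type": e.type,
                "ref_chrom": e.ref_chrom,
                "ref_start": e.ref_start,
                "ref_end": e.ref_end,
                "qry_chrom": e.qry_chrom,
                "qry_start": e.qry_start,
                "qry_end": e.qry_end,
                "size": e.size,
            }
            for e in svs
        ],
        columns=[
            "type", "ref_chrom", "ref_start", "ref_end",
            "qry_chrom", "qry_start", "qry_end", "size",
        ],
    )
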