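"""Ty retrotransposon annotation, state and viability classification.

Yeast LTR retrotransposons (Ty1-Ty5) are annotated against a consensus
library holding, per class, an LTR consensus and an internal coding-region
consensus with declared reading frames. Loci are classified by state:

* ``complete``   - both flanking LTRs plus a (near-)full internal region;
* ``truncated``  - an internal region lacking part of the consensus span or
                   missing a flanking LTR;
* ``solo_LTR``   - a lone LTR left behind by intra-element recombination.

Elements carrying coding sequence are additionally classified as
``functional`` or ``loss_of_function``: a premature stop codon, or an
extensive frameshift (net coding indel not a multiple of three, or any
indel run of >= 30 bp), marks the element as putatively unable to
transpose. A 10-kb flank comparison distinguishes segmental duplication of
an element-containing region from independent transposition events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome, revcomp
from .seqalign import chain_seeds, find_mems

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_PART_FRACTION = 0.5
DEFAULT_PAIRING_WINDOW = 10_000
DEFAULT_FRAMESHIFT_EXTENSIVE_BP = 30
#: internal-consensus coverage required to call a locus "complete"
COMPLETE_INTERNAL_COVERAGE = 0.95
#: chaining gap for consensus-vs-genome scans; generous so that internal
#: truncations up to ~2.5 kb stay within a single hit
TY_SCAN_MAX_GAP = 2500


@dataclass(frozen=True)
class CodingRegion:
    """Reading frame on the internal consensus (0-based half-open)."""

    frame: int
    start: int
    end: int


@dataclass
class TyClassSpec:
    ltr: str
    internal: str
    coding: list[CodingRegion]


@dataclass
class TyLibrary:
    """Per-class LTR + internal consensus sequences with reading frames."""

    classes: dict[str, TyClassSpec]

    def __post_init__(self) -> None:
        for name, spec in self.classes.items():
            if not spec.ltr or not spec.internal:
                raise ValueError(f"{name}: LTR and internal sequences must be non-empty")
            for cr in spec.coding:
                if not (0 <= cr.start < cr.end <= len(spec.internal)):
                    raise ValueError(f"{name}: coding region outside internal bounds")

    def __contains__(self, cls: str) -> bool:
        return cls in self.classes

    def __getitem__(self, cls: str) -> TyClassSpec:
        return self.classes[cls]

    # FASTA with class|part headers + YAML sidecar for reading frames
    def write(self, fasta_path: str | Path, yaml_path: str | Path) -> None:
        records = []
        for name, spec in self.classes.items():
            records.append(SeqRecord(Seq(spec.ltr), id=f"{name}|LTR", description=""))
            records.append(
                SeqRecord(Seq(spec.internal), id=f"{name}|internal", description="")
            )
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        frames = {
            name: [[cr.frame, cr.start, cr.end] for cr in spec.coding]
            for name, spec in self.classes.items()
        }
        with open(yaml_path, "w") as fh:
            yaml.safe_dump({"coding_regions": frames}, fh)

    @classmethod
    def read(cls, fasta_path: str | Path, yaml_path: str | Path) -> "TyLibrary":
        parts: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            name, _, part = rec.id.partition("|")
            parts.setdefault(name, {})[part] = str(rec.seq).upper()
        with open(yaml_path) as fh:
            frames = yaml.safe_load(fh)["coding_regions"]
        classes = {}
        for name, d in parts.items():
            coding = [CodingRegion(*c) for c in frames.get(name, [])]
            classes[name] = TyClassSpec(ltr=d["LTR"], internal=d["internal"], coding=coding)
        return cls(classes)


@dataclass
class ComponentHit:
    """Local hit of one library part (LTR or internal) on a genome."""

    ty_class: str
    part: str  # "LTR" or "internal"
    chrom: str
    start: int
    end: int
    strand: str
    identity: float  # percent over the aligned (matched) region
    part_coverage: float  # fraction of the consensus part covered


@dataclass
class TyElement:
    """An annotated retrotransposon locus."""

    strain: str
    ty_class: str
    state: str  # complete | truncated | solo_LTR
    viability: str  # functional | loss_of_function | not_applicable
    chrom: str
    start: int
    end: int
    components: list[ComponentHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def internal_hit(self) -> ComponentHit | None:
        for h in self.components:
            if h.part == "internal":
                return h
        return None


# --------------------------------------------------------------------------
# Scanning
# --------------------------------------------------------------------------


def scan_ty(
    genome: Genome,
    library: TyLibrary,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_part_fraction: float = DEFAULT_MIN_PART_FRACTION,
    min_seed: int = 20,
) -> list[ComponentHit]:
    """Hits of each library part against the genome, filtered by identity
    and by covered fraction of the consensus part.

    Hits overlapping a higher-identity hit of another class at the same
    locus are suppressed (Ty1/Ty2 cross-matching rule); an exact identity
    tie between Ty1 and Ty2 yields the joint label "Ty1/Ty2".
    """
    raw: list[ComponentHit] = []
    for cls_name in sorted(library.classes):
        spec = library.classes[cls_name]
        for part_name, part_seq in (("LTR", spec.ltr), ("internal", spec.internal)):
            for chrom, chrom_seq in genome.chromosomes.items():
                seeds = find_mems(
                    chrom_seq, part_seq, min_seed, ref_chrom=chrom, qry_chrom=part_name
                )
                blocks = chain_seeds(
                    seeds, max_gap=TY_SCAN_MAX_GAP, min_block=min(100, len(part_seq))
                )
                for b in blocks:
                    columns = max(b.ref_span, b.qry_span)
                    covered = b.identity / 100.0 * columns
                    ident = 100.0 * covered / min(b.ref_span, b.qry_span)
                    coverage = covered / len(part_seq)
                    if ident >= min_identity and coverage >= min_part_fraction:
                        raw.append(
                            ComponentHit(
                                ty_class=cls_name,
                                part=part_name,
                                chrom=chrom,
                                start=b.ref_start,
                                end=b.ref_end,
                                strand=b.strand,
                                identity=min(100.0, ident),
                                part_coverage=min(1.0, coverage),
                            )
                        )
    return _resolve_cross_class(raw)


def _resolve_cross_class(hits: list[ComponentHit]) -> list[ComponentHit]:
    """Assign loci hit by several classes to the higher-identity class;
    exact Ty1/Ty2 ties get the pooled "Ty1/Ty2" label."""
    hits = sorted(hits, key=lambda h: (h.chrom, h.start, -h.identity, h.ty_class))
    out: list[ComponentHit] = []
    for h in hits:
        merged = False
        for kept in out:
            if (
                kept.chrom == h.chrom
                and kept.part == h.part
                and min(kept.end, h.end) - max(kept.start, h.start)
                > 0.5 * min(kept.end - kept.start, h.end - h.start)
            ):
                if (
                    h.identity == kept.identity
                    and {h.ty_class, kept.ty_class} == {"Ty1", "Ty2"}
                ):
                    kept.ty_class = "Ty1/Ty2"
                merged = True
                break
        if not merged:
            out.append(h)
    out.sort(key=lambda h: (h.chrom, h.start, h.part))
    return out


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


def classify_elements(
    hits: list[ComponentHit],
    strain: str = "",
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
) -> list[TyElement]:
    """Greedy left-to-right grouping of component hits into elements.

    Within ``pairing_window`` and the same strand/class: LTR+internal+LTR
    form a complete element (if the internal hit covers the consensus),
    internal with at most one LTR or an incomplete internal span is
    truncated, and a lone LTR is a solo LTR. Each hit is assigned to at
    most one element.
    """
    by_chrom: dict[str, list[ComponentHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    elements: list[TyElement] = []
    for chrom in sorted(by_chrom):
        hs = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end))
        i = 0
        while i < len(hs):
            h = hs[i]
            group = [h]
            if h.part == "LTR":
                j = i + 1
                if (
                    j < len(hs)
                    and hs[j].part == "internal"
                    and hs[j].ty_class == h.ty_class
                    and hs[j].strand == h.strand
                    and hs[j].start - h.end <= pairing_window
                ):
                    group.append(hs[j])
                    k = j + 1
                    if (
                        k < len(hs)
                        and hs[k].part == "LTR"
                        and hs[k].ty_class == h.ty_class
                        and hs[k].strand == h.strand
                        and hs[k].start - hs[j].end <= pairing_window
                    ):
                        group.append(hs[k])
            elif h.part == "internal":
                k = i + 1
                if (
                    k < len(hs)
                    and hs[k].part == "LTR"
                    and hs[k].ty_class == h.ty_class
                    and hs[k].strand == h.strand
                    and hs[k].start - h.end <= pairing_window
                ):
                    group.append(hs[k])
            i += len(group)
            elements.append(_element_from_group(strain, group))
    return elements


def _element_from_group(strain: str, group: list[ComponentHit]) -> TyElement:
    parts = [h.part for h in group]
    internal = next((h for h in group if h.part == "internal"), None)
    n_ltr = sum(1 for p in parts if p == "LTR")
    if internal is None:
        state = "solo_LTR"
        viability = "not_applicable"
    elif n_ltr == 2 and internal.part_coverage >= COMPLETE_INTERNAL_COVERAGE:
        state = "complete"
        viability = "unassessed"
    else:
        state = "truncated"
        viability = "unassessed"
    return TyElement(
        strain=strain,
        ty_class=group[0].ty_class,
        state=state,
        viability=viability,
        chrom=group[0].chrom,
        start=min(h.start for h in group),
        end=max(h.end for h in group),
        components=group,
    )


# --------------------------------------------------------------------------
# Viability
# --------------------------------------------------------------------------


def _anchor_map(consensus: str, elem_seq: str, min_seed: int = 20):
    """Collinear anchor list [(cons_start, elem_start, length), ...] from
    the best MEM chain of consensus vs element sequence."""
    seeds = find_mems(consensus, elem_seq, min_seed, ref_chrom="c", qry_chrom="e")
    seeds = [s for s in seeds if s.strand == "+"]
    blocks = chain_seeds(seeds, max_gap=TY_SCAN_MAX_GAP, min_block=min_seed)
    if not blocks:
        return []
    best = max(blocks, key=lambda b: b.identity / 100.0 * max(b.ref_span, b.qry_span))
    return best.seeds  # (cons_start, elem_start, length)


def assess_viability(
    element: TyElement,
    genome: Genome,
    library: TyLibrary,
    frameshift_extensive_bp: int = DEFAULT_FRAMESHIFT_EXTENSIVE_BP,
) -> str:
    """Viability of an element carrying coding sequence.

    The internal region is extracted and anchored to the internal consensus;
    each declared coding region is translated in its declared frame. A stop
    codon before the consensus stop, a net coding indel not a multiple of
    three, or any indel run >= ``frameshift_extensive_bp`` marks the element
    loss_of_function. Solo LTRs are not_applicable.
    """
    if element.state == "solo_LTR":
        return "not_applicable"
    internal = element.internal_hit()
    if internal is None:
        return "loss_of_function"
    lib_cls = element.ty_class.split("/")[0]
    if lib_cls not in library:
        raise ValueError(f"class {element.ty_class!r} not in library")
    spec = library[lib_cls]
    elem_seq = genome.fetch(internal.chrom, internal.start, internal.end)
    if internal.strand == "-":
        elem_seq = revcomp(elem_seq)
    anchors = _anchor_map(spec.internal, elem_seq)
    if not anchors:
        return "loss_of_function"

    def to_elem(cpos: int) -> int:
        # map a consensus position onto the element through the anchors
        for c0, e0, ln in anchors:
            if c0 <= cpos < c0 + ln:
                return e0 + (cpos - c0)
            if cpos < c0:
                return e0 - (c0 - cpos) if e0 - (c0 - cpos) >= 0 else e0
        c0, e0, ln = anchors[-1]
        return min(len(elem_seq), e0 + ln + (cpos - (c0 + ln)))

    for cr in spec.coding:
        e_start = max(0, to_elem(cr.start))
        e_end = min(len(elem_seq), to_elem(cr.end - 1) + 1)
        coding_seq = elem_seq[e_start:e_end]
        net_indel = len(coding_seq) - (cr.end - cr.start)
        # per-gap indel runs between consecutive anchors inside the region
        max_run = 0
        inner = [a for a in anchors if cr.start <= a[0] + a[2] and a[0] <= cr.end]
        for (c0, e0, l0), (c1, e1, _l1) in zip(inner, inner[1:]):
            c_gap = c1 - (c0 + l0)
            e_gap = e1 - (e0 + l0)
            max_run = max(max_run, abs(c_gap - e_gap))
        if net_indel % 3 != 0 or max_run >= frameshift_extensive_bp:
            return "loss_of_function"
        # translate in the declared frame; look for a premature stop
        frame_seq = coding_seq[cr.frame :]
        n_codons = len(frame_seq) // 3
        last = n_codons - 1
        for ci in range(n_codons):
            codon = frame_seq[3 * ci : 3 * ci + 3]
            if codon in STOP_CODONS and ci < last:
                return "loss_of_function"
    return "functional"


def annotate_genome(
    genome: Genome,
    library: TyLibrary,
    strain: str | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_part_fraction: float = DEFAULT_MIN_PART_FRACTION,
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
) -> list[TyElement]:
    """scan -> classify -> assess viability, for one strain genome."""
    hits = scan_ty(genome, library, min_identity, min_part_fraction)
    elements = classify_elements(hits, strain or genome.name, pairing_window)
    for e in elements:
        if e.state != "solo_LTR":
            e.viability = assess_viability(e, genome, library)
    return elements


# --------------------------------------------------------------------------
# Transposition vs segmental duplication (10-kb flank test)
# --------------------------------------------------------------------------


def transposition_vs_duplication(
    e1: TyElement,
    e2: TyElement,
    genome: Genome,
    flank_context: int = 10_000,
    flank_identity_threshold: float = 90.0,
    min_covered_fraction: float = 0.5,
    background_fraction: float = 0.05,
) -> str:
    """Compare the ~``flank_context``-bp regions containing two related
    intrastrain elements, with the element sequence itself masked.

    Shared flanks (identity >= threshold over >= half the shorter region)
    imply segmental duplication of the region; flank similarity at
    background level implies independent transposition; anything between is
    indeterminate. Comparisons at the thresholds are inclusive.
    """
    for e in (e1, e2):
        if e.chrom not in genome:
            raise ValueError(f"element chromosome {e.chrom!r} not in genome")

    def region(e: TyElement) -> str:
        pad = max(500, (flank_context - e.length) // 2)
        chrom_seq = genome[e.chrom]
        lo = max(0, e.start - pad)
        hi = min(len(chrom_seq), e.end + pad)
        seq = chrom_seq[lo:hi]
        # mask the element so element-sequence identity cannot masquerade
        # as flank identity
        m0, m1 = e.start - lo, e.end - lo
        return seq[:m0] + "N" * (m1 - m0) + seq[m1:]

    r1, r2 = region(e1), region(e2)
    shorter = min(len(r1) - e1.length, len(r2) - e2.length)
    if shorter <= 0:
        return "indeterminate"
    seeds = find_mems(r1, r2, 20)
    blocks = chain_seeds(seeds, max_gap=200, min_block=100)
    covered = sum(b.identity / 100.0 * max(b.ref_span, b.qry_span) for b in blocks)
    aligned = sum(min(b.ref_span, b.qry_span) for b in blocks)
    cov_frac = covered / shorter
    identity = 100.0 * covered / aligned if aligned else 0.0
    if cov_frac >= min_covered_fraction and identity >= flank_identity_threshold:
        return "segmental_duplication"
    if cov_frac <= background_fraction:
        return "independent_transposition"
    return "indeterminate"


# --------------------------------------------------------------------------
# Summaries and serialization
# --------------------------------------------------------------------------

TY_STATES = ("complete", "truncated", "solo_LTR")


def ty_summary(
    elements_by_strain: dict[str, list[TyElement]], normalize: bool = False
) -> pd.DataFrame:
    """Per strain x class x state counts and cumulative length.

    With ``normalize`` each (class, state) count column is scaled by its
    maximum across strains (x / x_max), for visual comparison.
    """
    if not elements_by_strain:
        raise ValueError("need at least one strain")
    rows = []
    for strain, elements in elements_by_strain.items():
        for e in elements:
            rows.append(
                {"strain": strain, "ty_class": e.ty_class, "state": e.state,
                 "length": e.length}
            )
    strains = list(elements_by_strain)
    if not rows:
        return pd.DataFrame(index=pd.Index(strains, name="strain"))
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["strain", "ty_class", "state"])
        .agg(count=("length", "size"), total_bp=("length", "sum"))
        .reset_index()
        .pivot(index="strain", columns=["ty_class", "state"], values=["count", "total_bp"])
        .reindex(strains)
        .fillna(0)
        .astype(int)
    )
    if normalize:
        count_cols = [c for c in counts.columns if c[0] == "count"]
        norm = counts[count_cols].astype(float)
        for c in count_cols:
            m = norm[c].max()
            if m > 0:
                norm[c] = norm[c] / m
        return norm
    return counts


def elements_to_frame(elements: list[TyElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": e.strain,
                "ty_class": e.ty_class,
                "state": e.state,
                "viability": e.viability,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "n_components": len(e.components),
            }
            for e in elements
        ],
        columns=["strain", "ty_class", "state", "viability", "chrom", "start", "end",
                 "n_components"],
    )


def write_elements_gff3(elements: list[TyElement], path: str | Path) -> None:
    """GFF3 with LTR_retrotransposon / long_terminal_repeat feature types."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(elements, 1):
            eid = f"Ty_{i:04d}"
            ftype = (
                "long_terminal_repeat" if e.state == "solo_LTR" else "LTR_retrotransposon"
            )
            fh.write(
                f"{e.chrom}\tcomparome\t{ftype}\t{e.start + 1}\t{e.end}\t.\t"
                f"{'+' if not e.components else e.components[0].strand}\t.\t"
                f"ID={eid};class={e.ty_class};state={e.state};viability={e.viability}\n"
            )
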