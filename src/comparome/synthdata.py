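"""Synthetic strain panels with known evolutionary structure and planted
features, plus machine-readable truth tables.

The generator emulates a clade of related yeast genomes: an ancestral
genome is evolved along a user-supplied strain tree (i.i.d. per-base
substitutions per branch), and each leaf strain then receives planted
features — structural variants of all five classes (including a terminal
translocation analog), Ty retrotransposon loci in all states, clade-
restricted gene absences, and ORFs diverged to a target level in a focal
clade. Substitutions are applied before planting and planted intervals are
excluded from background substitution, so every truth coordinate is exact.

All outputs are pure functions of the configuration, including its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, GeneFeature, revcomp, write_gff3, write_orf_fasta
from .tyscan import CodingRegion, TyClassSpec, TyLibrary

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MAX_RATE = 0.25
SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")
ROLES = ("focal", "other_conspecific", "outgroup")


# --------------------------------------------------------------------------
# Primitive operations
# --------------------------------------------------------------------------


def generate_ancestor(
    n_chroms: int,
    chrom_lengths: list[int],
    gc: float,
    seed: int,
    chrom_names: list[str] | None = None,
    name: str = "ancestor",
) -> Genome:
    """Random ancestral genome with the requested chromosome count and
    lengths; base composition matches ``gc`` in expectation."""
    if n_chroms != len(chrom_lengths):
        raise ValueError("n_chroms does not match chrom_lengths")
    if any(l <= 0 for l in chrom_lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    names = chrom_names or [f"chr{i + 1}" for i in range(n_chroms)]
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {}
    for cname, length in zip(names, chrom_lengths):
        arr = rng.choice(BASES, size=length, p=p)
        chroms[cname] = arr.tobytes().decode("ascii")
    return Genome(name, chroms)


@dataclass(frozen=True)
class Substitution:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str


def apply_substitutions(
    genome: Genome,
    rate: float,
    seed: int | np.random.Generator,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[Genome, list[Substitution]]:
    """Substitute each site independently with probability ``rate`` to a
    uniformly chosen different base; returns the new genome and records of
    every change. Sites inside ``exclude`` intervals are left untouched.
    """
    if not 0.0 <= rate <= MAX_RATE:
        raise ValueError(f"substitution rate must be in [0, {MAX_RATE}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exclude = exclude or {}
    new_chroms: dict[str, str] = {}
    records: list[Substitution] = []
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hit = rng.random(arr.size) < rate
        for lo, hi in exclude.get(chrom, []):
            hit[lo:hi] = False
        # only ACGT sites are substituted
        base_idx = np.full(arr.size, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            base_idx[arr == b] = i
        hit &= base_idx >= 0
        pos = np.nonzero(hit)[0]
        if pos.size:
            shift = rng.integers(1, 4, size=pos.size)
            new_idx = (base_idx[pos].astype(np.int64) + shift) % 4
            old = arr[pos].copy()
            arr[pos] = BASES[new_idx]
            for p, ob, nb in zip(pos.tolist(), old.tolist(), arr[pos].tolist()):
                records.append(Substitution(chrom, p, chr(ob), chr(nb)))
        new_chroms[chrom] = arr.tobytes().decode("ascii")
    return Genome(genome.name, new_chroms), records


@dataclass(frozen=True)
class SVRecord:
    """Truth record of a planted structural variant. ``ref_*`` coordinates
    are in the unedited (base) genome, ``qry_*`` in the edited strain."""

    strain: str
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    size: int


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.38) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


def plant_sv(
    genome: Genome,
    sv_type: str,
    chrom: str,
    pos: int,
    size: int,
    payload_seed: int = 0,
    acceptor_chrom: str | None = None,
) -> tuple[Genome, SVRecord]:
    """Plant one structural variant at ``pos`` (current genome coordinates).

    DEL removes ``size`` bp; INS inserts ``size`` random bp; DUP appends an
    adjacent tandem copy of the segment; INV replaces the segment with its
    reverse complement; TRA moves the terminal segment ``[pos, end)`` of
    ``chrom`` onto the end of ``acceptor_chrom``.
    """
    if sv_type not in SV_TYPES:
        raise ValueError(f"unknown SV type {sv_type!r}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    g = genome.copy()
    if sv_type == "TRA":
        if acceptor_chrom is None or acceptor_chrom not in genome:
            raise ValueError("TRA requires a valid acceptor_chrom")
        if pos + size != len(seq):
            raise ValueError("TRA segment must be terminal on the donor chromosome")
        if pos < 0:
            raise ValueError("interval out of bounds")
        segment = seq[pos:]
        g.chromosomes[chrom] = seq[:pos]
        acc = g.chromosomes[acceptor_chrom]
        g.chromosomes[acceptor_chrom] = acc + segment
        rec = SVRecord(
            genome.name, "TRA", chrom, pos, pos + size,
            acceptor_chrom, len(acc), len(acc) + size, size,
        )
        return g, rec
    if not (0 <= pos and pos + (0 if sv_type == "INS" else size) <= len(seq)):
        raise ValueError(f"interval {chrom}:{pos}+{size} out of bounds")
    if sv_type == "DEL":
        g.chromosomes[chrom] = seq[:pos] + seq[pos + size :]
        rec = SVRecord(genome.name, "DEL", chrom, pos, pos + size, chrom, pos, pos, size)
    elif sv_type == "INS":
        payload = random_dna(np.random.default_rng(payload_seed), size)
        g.chromosomes[chrom] = seq[:pos] + payload + seq[pos:]
        rec = SVRecord(genome.name, "INS", chrom, pos, pos, chrom, pos, pos + size, size)
    elif sv_type == "DUP":
        segment = seq[pos : pos + size]
        g.chromosomes[chrom] = seq[: pos + size] + segment + seq[pos + size :]
        rec = SVRecord(
            genome.name, "DUP", chrom, pos, pos + size, chrom, pos + size,
            pos + 2 * size, size,
        )
    else:  # INV
        segment = seq[pos : pos + size]
        g.chromosomes[chrom] = seq[:pos] + revcomp(segment) + seq[pos + size :]
        rec = SVRecord(
            genome.name, "INV", chrom, pos, pos + size, chrom, pos, pos + size, size
        )
    return g, rec


# --------------------------------------------------------------------------
# Ty library and element construction
# --------------------------------------------------------------------------

_TY_LTR_LEN = {"Ty1": 334, "Ty2": 332, "Ty3": 340, "Ty4": 371, "Ty5": 251}
_TY_INTERNAL_CODONS = {"Ty1": 1760, "Ty2": 1770, "Ty3": 1570, "Ty4": 1840, "Ty5": 1666}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def synthetic_ty_library(seed: int = 0) -> TyLibrary:
    """A synthetic stand-in for a curated Ty consensus library: per class a
    random LTR and a stop-free internal coding consensus ending in TAA, with
    one declared reading frame spanning the internal region. Lengths mirror
    the real elements (LTRs ~250-370 bp, internal regions ~5 kb)."""
    rng = np.random.default_rng(seed)
    classes: dict[str, TyClassSpec] = {}
    for cls, ltr_len in _TY_LTR_LEN.items():
        ltr = random_dna(rng, ltr_len)
        n_codons = _TY_INTERNAL_CODONS[cls]
        codons = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 1)
        internal = "".join(_NONSTOP_CODONS[i] for i in codons) + "TAA"
        classes[cls] = TyClassSpec(
            ltr=ltr,
            internal=internal,
            coding=[CodingRegion(frame=0, start=0, end=3 * n_codons)],
        )
    return TyLibrary(classes)


@dataclass(frozen=True)
class TyTruthRecord:
    strain: str
    ty_class: str
    state: str
    viability: str
    chrom: str
    start: int
    end: int
    lesion: str


TY_STATES = ("complete", "truncated", "solo_LTR")


def build_ty_element_sequence(
    library: TyLibrary,
    ty_class: str,
    state: str,
    viability: str,
    truncation_bp: int = 2000,
) -> tuple[str, str]:
    """Element sequence for planting, plus a lesion description.

    solo_LTR is one LTR copy; complete is LTR+internal+LTR; truncated has a
    ``truncation_bp`` block deleted from the middle of the internal region.
    loss_of_function introduces an in-frame premature TAA at 40% of the
    coding region (complete) — truncations are loss_of_function by
    construction; a "frameshift" viability value requests a 1-bp coding
    deletion instead of a stop codon.
    """
    if ty_class not in library:
        raise ValueError(f"unknown Ty class {ty_class!r}")
    if state not in TY_STATES:
        raise ValueError(f"unknown state {state!r}")
    spec = library[ty_class]
    if state == "solo_LTR":
        if viability not in ("not_applicable",):
            raise ValueError("solo_LTR carries no coding sequence; viability must be not_applicable")
        return spec.ltr, "none"
    internal = spec.internal
    lesion = "none"
    if viability == "loss_of_function":
        cr = spec.coding[0]
        codon_i = (cr.end - cr.start) // 3 * 2 // 5  # ~40% into the region
        p = cr.start + cr.frame + 3 * codon_i
        internal = internal[:p] + "TAA" + internal[p + 3 :]
        lesion = f"premature_stop@{p}"
    elif viability == "frameshift":
        cr = spec.coding[0]
        p = cr.start + cr.frame + (cr.end - cr.start) // 3 * 2 // 5 * 3
        internal = internal[:p] + internal[p + 1 :]
        lesion = f"frameshift_del1@{p}"
        viability = "loss_of_function"
    elif viability != "functional":
        raise ValueError(f"unknown viability {viability!r}")
    if state == "truncated":
        if truncation_bp >= len(internal):
            raise ValueError("truncation exceeds internal length")
        mid = (len(internal) - truncation_bp) // 2
        internal = internal[:mid] + internal[mid + truncation_bp :]
        lesion = f"internal_truncation_{truncation_bp}bp" + (
            "" if lesion == "none" else ";" + lesion
        )
    return spec.ltr + internal + spec.ltr, lesion


def plant_ty_element(
    genome: Genome,
    library: TyLibrary,
    ty_class: str,
    state: str,
    viability: str,
    chrom: str,
    pos: int,
    truncation_bp: int = 2000,
) -> tuple[Genome, TyTruthRecord]:
    """Insert a constructed Ty element at ``pos`` (current coordinates)."""
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} not in genome")
    if not 0 <= pos <= len(genome[chrom]):
        raise ValueError("position out of bounds")
    seq, lesion = build_ty_element_sequence(
        library, ty_class, state, viability, truncation_bp
    )
    g = genome.copy()
    s = g.chromosomes[chrom]
    g.chromosomes[chrom] = s[:pos] + seq + s[pos:]
    truth_viability = (
        "not_applicable"
        if state == "solo_LTR"
        else ("loss_of_function" if state == "truncated" or viability != "functional" else "functional")
    )
    rec = TyTruthRecord(
        genome.name, ty_class, state, truth_viability, chrom, pos, pos + len(seq), lesion
    )
    return g, rec


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One branch of the strain tree; leaves carry strain names and roles."""

    name: str
    rate: float = 0.0
    role: str | None = None  # leaves only
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def validate(self) -> None:
        if not 0.0 <= self.rate <= MAX_RATE:
            raise ValueError(f"branch {self.name!r}: rate outside [0, {MAX_RATE}]")
        if not self.children:
            if self.role not in ROLES:
                raise ValueError(f"leaf {self.name!r}: role must be one of {ROLES}")
        for c in self.children:
            c.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        return cls(
            name=d["name"],
            rate=float(d.get("rate", 0.0)),
            role=d.get("role"),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "rate": self.rate}
        if self.role:
            d["role"] = self.role
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass(frozen=True)
class SVDirective:
    strain: str
    type: str
    chrom: str
    pos: int
    size: int
    acceptor_chrom: str | None = None


@dataclass(frozen=True)
class TyDirective:
    strain: str
    ty_class: str
    state: str
    viability: str  # functional | loss_of_function | frameshift | not_applicable
    chrom: str
    pos: int
    truncation_bp: int = 2000


@dataclass(frozen=True)
class GeneDirective:
    gene_id: str
    chrom: str
    start: int
    length: int
    pattern: str  # core | focal_absent | explicit
    present_in: tuple[str, ...] = ()  # for pattern == "explicit"


@dataclass(frozen=True)
class IntrogressionDirective:
    gene_id: str
    divergence: float
    strains: tuple[str, ...]


@dataclass
class SimConfig:
    """Full simulation recipe; all outputs are pure functions of it."""

    seed: int
    chrom_lengths: list[int]
    gc: float = 0.38
    chrom_names: list[str] | None = None
    tree: TreeNode | None = None
    sv_plan: list[SVDirective] = field(default_factory=list)
    ty_plan: list[TyDirective] = field(default_factory=list)
    gene_plan: list[GeneDirective] = field(default_factory=list)
    introgression_plan: list[IntrogressionDirective] = field(default_factory=list)
    ty_library_seed: int = 0

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)

    def chrom_name(self, i: int) -> str:
        return (self.chrom_names or [f"chr{j + 1}" for j in range(self.n_chroms)])[i]

    def strains(self) -> list[str]:
        return [l.name for l in self.tree.leaves()] if self.tree else []

    def roles(self) -> dict[str, str]:
        return {l.name: l.role for l in self.tree.leaves()} if self.tree else {}

    def validate(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.tree is None:
            raise ValueError("a strain tree is required")
        self.tree.validate()
        strains = self.strains()
        if len(set(strains)) != len(strains):
            raise ValueError("strain names must be unique")
        names = [self.chrom_name(i) for i in range(self.n_chroms)]
        lengths = dict(zip(names, self.chrom_lengths))
        for d in self.sv_plan:
            if d.strain not in strains:
                raise ValueError(f"sv_plan strain {d.strain!r} unknown")
            if d.chrom not in lengths:
                raise ValueError(f"sv_plan chromosome {d.chrom!r} unknown")
            end = d.pos if d.type == "INS" else d.pos + d.size
            if not (0 <= d.pos and end <= lengths[d.chrom]):
                raise ValueError(f"sv_plan interval out of bounds: {d}")
            if d.type == "TRA" and d.pos + d.size != lengths[d.chrom]:
                raise ValueError("TRA must move a terminal segment")
        for t in self.ty_plan:
            if t.strain not in strains:
                raise ValueError(f"ty_plan strain {t.strain!r} unknown")
            if not 0 <= t.pos <= lengths[t.chrom]:
                raise ValueError(f"ty_plan position out of bounds: {t}")
        gene_ids = [g.gene_id for g in self.gene_plan]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in gene plan")
        for g in self.gene_plan:
            if g.start + g.length > lengths[g.chrom]:
                raise ValueError(f"gene plan exceeds chromosome capacity: {g.gene_id}")
        for intro in self.introgression_plan:
            if not 0.0 <= intro.divergence <= MAX_RATE:
                raise ValueError("introgression divergence outside [0, 0.25]")
            if intro.gene_id not in set(gene_ids):
                raise ValueError(f"unknown ORF id {intro.gene_id!r} in introgression plan")
            for s in intro.strains:
                if s not in strains:
                    raise ValueError(f"introgression strain {s!r} unknown")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        """Planted intervals must be mutually non-overlapping per strain."""
        for strain in self.strains():
            per_chrom: dict[str, list[tuple[int, int, str]]] = {}
            for d in self.sv_plan:
                if d.strain != strain:
                    continue
                end = d.pos + (1 if d.type == "INS" else d.size)
                per_chrom.setdefault(d.chrom, []).append((d.pos, end, f"SV:{d.type}"))
            for t in self.ty_plan:
                if t.strain == strain:
                    per_chrom.setdefault(t.chrom, []).append((t.pos, t.pos + 1, "Ty"))
            for g in self.gene_plan:
                per_chrom.setdefault(g.chrom, []).append(
                    (g.start, g.start + g.length, f"gene:{g.gene_id}")
                )
            for chrom, ivs in per_chrom.items():
                ivs.sort()
                for (s0, e0, n0), (s1, e1, n1) in zip(ivs, ivs[1:]):
                    if s1 < e0:
                        raise ValueError(
                            f"{strain}/{chrom}: planted features overlap ({n0} and {n1})"
                        )


# --------------------------------------------------------------------------
# Truth tables
# --------------------------------------------------------------------------


@dataclass
class TruthTables:
    """Machine-readable ground truth for every planted feature."""

    substitutions: pd.DataFrame  # strain, chrom, pos, ref_base, alt_base
    planted_svs: pd.DataFrame  # SVRecord columns + strain
    planted_ty: pd.DataFrame  # TyTruthRecord columns
    gene_presence: pd.DataFrame  # genes x strains bool
    introgressed_orfs: pd.DataFrame  # gene_id, strains, divergence

    _FILES = {
        "substitutions": "substitutions.tsv",
        "planted_svs": "planted_svs.tsv",
        "planted_ty": "planted_ty.tsv",
        "gene_presence": "gene_presence.tsv",
        "introgressed_orfs": "introgressed_orfs.tsv",
    }

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            df: pd.DataFrame = getattr(self, attr)
            index = attr == "gene_presence"
            df.to_csv(outdir / fname, sep="\t", index=index)

    @classmethod
    def from_dir(cls, outdir: str | Path) -> "TruthTables":
        outdir = Path(outdir)
        kw = {}
        for attr, fname in cls._FILES.items():
            if attr == "gene_presence":
                df = pd.read_csv(outdir / fname, sep="\t", index_col=0)
                df = df.astype(bool)
            else:
                df = pd.read_csv(outdir / fname, sep="\t")
            kw[attr] = df
        return cls(**kw)

    def equals(self, other: "TruthTables") -> bool:
        for attr in self._FILES:
            a: pd.DataFrame = getattr(self, attr)
            b: pd.DataFrame = getattr(other, attr)
            if a.shape != b.shape:
                return False
            if len(a) and not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                if attr == "gene_presence":
                    if not a.equals(b):
                        return False
                else:
                    return False
        return True


# --------------------------------------------------------------------------
# Simulator
# --------------------------------------------------------------------------


@dataclass
class Fixture:
    """In-memory result of a simulation run."""

    config: SimConfig
    genomes: dict[str, Genome]
    annotations: dict[str, list[GeneFeature]]
    orf_catalogs: dict[str, dict[str, str]]
    ty_library: TyLibrary
    truth: TruthTables
    roles: dict[str, str]


class _EditMap:
    """Coordinate map from base (pre-planting) to edited strain coordinates
    for positions outside every edit interval."""

    def __init__(self) -> None:
        self.shifts: dict[str, list[tuple[int, int]]] = {}  # chrom -> (anchor, delta)

    def add(self, chrom: str, anchor: int, delta: int) -> None:
        self.shifts.setdefault(chrom, []).append((anchor, delta))

    def map(self, chrom: str, pos: int) -> int:
        return pos + sum(d for a, d in self.shifts.get(chrom, []) if a <= pos)


def _exclusion_zones(config: SimConfig) -> dict[str, list[tuple[int, int]]]:
    """Intervals excluded from background substitution: SV intervals, genes
    that can be absent somewhere, and introgression target genes."""
    zones: dict[str, list[tuple[int, int]]] = {}
    for d in config.sv_plan:
        end = d.pos + (0 if d.type == "INS" else d.size)
        if end > d.pos:
            zones.setdefault(d.chrom, []).append((d.pos, end))
    intro_ids = {i.gene_id for i in config.introgression_plan}
    for g in config.gene_plan:
        if g.pattern != "core" or g.gene_id in intro_ids:
            zones.setdefault(g.chrom, []).append((g.start, g.start + g.length))
    return zones


def _gene_presence(config: SimConfig) -> pd.DataFrame:
    strains = config.strains()
    roles = config.roles()
    rows = {}
    for g in config.gene_plan:
        if g.pattern == "core":
            present = {s: True for s in strains}
        elif g.pattern == "focal_absent":
            present = {s: roles[s] != "focal" for s in strains}
        elif g.pattern == "explicit":
            present = {s: s in g.present_in for s in strains}
        else:
            raise ValueError(f"unknown gene pattern {g.pattern!r}")
        rows[g.gene_id] = present
    if rows:
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=strains)
    else:
        df = pd.DataFrame(index=pd.Index([], name="gene_id"), columns=strains)
    df.index.name = "gene_id"
    return df.fillna(False).astype(bool)


def simulate(config: SimConfig) -> Fixture:
    """Run the full generator: ancestor -> tree substitutions -> planting."""
    config.validate()
    ancestor = generate_ancestor(
        config.n_chroms,
        config.chrom_lengths,
        config.gc,
        seed=int(np.random.SeedSequence([config.seed, 0]).generate_state(1)[0] % (2**31)),
        chrom_names=[config.chrom_name(i) for i in range(config.n_chroms)],
    )
    zones = _exclusion_zones(config)
    library = synthetic_ty_library(config.ty_library_seed)
    presence = _gene_presence(config)
    roles = config.roles()

    # ---- substitutions along the tree (shared branches => shared changes)
    leaf_genomes: dict[str, Genome] = {}
    leaf_subs: dict[str, list[Substitution]] = {}

    def walk(node: TreeNode, genome: Genome, subs: list[Substitution], path: tuple[int, ...]):
        if node.rate > 0:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, *path]))
            genome, recs = apply_substitutions(genome, node.rate, rng, exclude=zones)
            subs = subs + recs
        if not node.children:
            leaf_genomes[node.name] = genome.copy(node.name)
            leaf_subs[node.name] = subs
            return
        for i, child in enumerate(node.children):
            walk(child, genome, subs, path + (i,))

    walk(config.tree, ancestor, [], ())

    # ---- per-strain planting
    genomes: dict[str, Genome] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    orf_catalogs: dict[str, dict[str, str]] = {}
    sv_truth: list[dict] = []
    ty_truth: list[TyTruthRecord] = []
    sub_rows: list[dict] = []

    for strain in config.strains():
        g = leaf_genomes[strain]
        strain_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, _stable_id(strain)])
        )
        # gene absences: interval replaced by neutral sequence (length kept)
        for gene in config.gene_plan:
            if not bool(presence.loc[gene.gene_id, strain]):
                s = g.chromosomes[gene.chrom]
                neutral = random_dna(strain_rng, gene.length, config.gc)
                g.chromosomes[gene.chrom] = (
                    s[: gene.start] + neutral + s[gene.start + gene.length :]
                )
        # introgressed ORFs: focal copies diverged to the target level
        for intro in config.introgression_plan:
            if strain in intro.strains:
                gene = next(x for x in config.gene_plan if x.gene_id == intro.gene_id)
                sub_g = Genome(strain, {gene.chrom: g.fetch(gene.chrom, gene.start, gene.start + gene.length)})
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, 3, _stable_id(strain), _stable_id(intro.gene_id)]
                    )
                )
                sub_g, _ = apply_substitutions(sub_g, intro.divergence, rng)
                s = g.chromosomes[gene.chrom]
                g.chromosomes[gene.chrom] = (
                    s[: gene.start] + sub_g[gene.chrom] + s[gene.start + gene.length :]
                )
        # length-changing edits (SVs and Ty insertions), right to left
        edits: list[tuple[int, str, object]] = []
        for d in config.sv_plan:
            if d.strain == strain:
                edits.append((d.pos, "sv", d))
        for t in config.ty_plan:
            if t.strain == strain:
                edits.append((t.pos, "ty", t))
        emap = _EditMap()
        pending_tra: list[tuple[str, SVRecord]] = []
        for pos, kind, d in sorted(edits, key=lambda e: (e[2].chrom, -e[0])):
            if kind == "sv":
                payload_seed = int(
                    np.random.SeedSequence(
                        [config.seed, 4, _stable_id(strain), pos]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                if d.type == "TRA":
                    g, rec = plant_sv(
                        g, d.type, d.chrom, pos, d.size, payload_seed,
                        acceptor_chrom=d.acceptor_chrom,
                    )
                    pending_tra.append((strain, rec))
                    continue
                g, rec = plant_sv(g, d.type, d.chrom, pos, d.size, payload_seed)
                delta = {"DEL": -d.size, "INS": d.size, "DUP": d.size, "INV": 0}[d.type]
                anchor = pos + (d.size if d.type in ("DEL", "DUP") else 0)
                if delta:
                    emap.add(d.chrom, anchor, delta)
                sv_truth.append(
                    {
                        "strain": strain, "type": d.type, "ref_chrom": d.chrom,
                        "ref_start": rec.ref_start, "ref_end": rec.ref_end,
                        "qry_chrom": d.chrom,
                        "qry_start": rec.qry_start, "qry_end": rec.qry_end,
                        "size": d.size, "edit_pos": pos,
                    }
                )
            else:
                g, rec = plant_ty_element(
                    g, library, d.ty_class, d.state, d.viability, d.chrom, pos,
                    truncation_bp=d.truncation_bp,
                )
                emap.add(d.chrom, pos, rec.end - rec.start)
                ty_truth.append(rec)
        # remap edited-strain coordinates for features planted left of later
        # edits (edits were applied right-to-left, so each record's own
        # coordinates are base coordinates at plant time; shifting by edits
        # strictly to the left yields final coordinates)
        for i, rec in enumerate(ty_truth):
            if rec.strain != strain:
                continue
            offset = sum(
                dd for aa, dd in emap.shifts.get(rec.chrom, []) if aa < rec.start
            )
            ty_truth[i] = TyTruthRecord(
                rec.strain, rec.ty_class, rec.state, rec.viability, rec.chrom,
                rec.start + offset, rec.end + offset, rec.lesion,
            )
        for row in sv_truth:
            if row["strain"] != strain or row["type"] == "TRA":
                continue
            off = sum(
                dd for aa, dd in emap.shifts.get(row["qry_chrom"], [])
                if aa < row["edit_pos"]
            )
            row["qry_start"] += off
            row["qry_end"] += off
        for strain_name, rec in pending_tra:
            acc_len = len(g[rec.qry_chrom])
            sv_truth.append(
                {
                    "strain": strain_name, "type": "TRA", "ref_chrom": rec.ref_chrom,
                    "ref_start": rec.ref_start, "ref_end": rec.ref_end,
                    "qry_chrom": rec.qry_chrom,
                    "qry_start": acc_len - rec.size, "qry_end": acc_len,
                    "size": rec.size, "edit_pos": rec.ref_start,
                }
            )
        # substitutions truth, in final coordinates
        for s in leaf_subs[strain]:
            sub_rows.append(
                {
                    "strain": strain, "chrom": s.chrom,
                    "pos": emap.map(s.chrom, s.pos),
                    "ref_base": s.ref_base, "alt_base": s.alt_base,
                }
            )
        # gene annotations + ORF catalog, in final coordinates
        feats: list[GeneFeature] = []
        catalog: dict[str, str] = {}
        for gene in config.gene_plan:
            if not bool(presence.loc[gene.gene_id, strain]):
                continue
            start = emap.map(gene.chrom, gene.start)
            feats.append(GeneFeature(gene.gene_id, gene.chrom, start, start + gene.length))
            catalog[gene.gene_id] = g.fetch(gene.chrom, start, start + gene.length)
        genomes[strain] = g
        annotations[strain] = feats
        orf_catalogs[strain] = catalog

    sv_df = pd.DataFrame(
        sv_truth,
        columns=["strain", "type", "ref_chrom", "ref_start", "ref_end",
                 "qry_chrom", "qry_start", "qry_end", "size", "edit_pos"],
    ).drop(columns=["edit_pos"])
    ty_df = pd.DataFrame(
        [asdict(t) for t in ty_truth],
        columns=["strain", "ty_class", "state", "viability", "chrom", "start", "end",
                 "lesion"],
    )
    intro_df = pd.DataFrame(
        [
            {"gene_id": i.gene_id, "strains": ",".join(i.strains),
             "divergence": i.divergence}
            for i in config.introgression_plan
        ],
        columns=["gene_id", "strains", "divergence"],
    )
    sub_df = pd.DataFrame(
        sub_rows, columns=["strain", "chrom", "pos", "ref_base", "alt_base"]
    )
    truth = TruthTables(
        substitutions=sub_df,
        planted_svs=sv_df,
        planted_ty=ty_df,
        gene_presence=presence,
        introgressed_orfs=intro_df,
    )
    return Fixture(
        config=config,
        genomes=genomes,
        annotations=annotations,
        orf_catalogs=orf_catalogs,
        ty_library=library,
        truth=truth,
        roles=roles,
    )


def _stable_id(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


# --------------------------------------------------------------------------
# Fixture emission
# --------------------------------------------------------------------------


def emit_fixture(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full fixture tree (per-strain FASTA + GFF3 + ORF FASTA,
    truth TSVs, Ty library, manifest). Identical seed => byte-identical
    output. Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate(config)
    manifest: dict = {"seed": config.seed, "strains": [], "files": {}}

    def record(path: Path) -> None:
        digest = hashlib.md5(path.read_bytes()).hexdigest()
        manifest["files"][str(path.relative_to(outdir))] = digest

    for strain in config.strains():
        fa = outdir / f"{strain}.fa"
        fx.genomes[strain].to_fasta(fa)
        gff = outdir / f"{strain}.gff3"
        write_gff3(fx.annotations[strain], gff)
        orfs = outdir / f"{strain}_orfs.fa"
        write_orf_fasta(fx.orf_catalogs[strain], orfs)
        for p in (fa, gff, orfs):
            record(p)
        manifest["strains"].append(
            {"name": strain, "role": fx.roles[strain],
             "genome": fa.name, "annotation": gff.name, "orfs": orfs.name}
        )
    truth_dir = outdir / "truth"
    fx.truth.to_dir(truth_dir)
    for f in sorted(truth_dir.iterdir()):
        record(f)
    lib_fa = outdir / "ty_library.fa"
    lib_yaml = outdir / "ty_library.yaml"
    fx.ty_library.write(lib_fa, lib_yaml)
    record(lib_fa)
    record(lib_yaml)
    groups = ortholog_group_table(fx.truth.gene_presence)
    groups_path = outdir / "ortholog_groups.tsv"
    groups.to_csv(groups_path, sep="\t", index=False)
    record(groups_path)
    roles_path = outdir / "strain_roles.tsv"
    pd.DataFrame(
        [{"strain": s, "role": r} for s, r in fx.roles.items()]
    ).to_csv(roles_path, sep="\t", index=False)
    record(roles_path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def ortholog_group_table(presence: pd.DataFrame) -> pd.DataFrame:
    """Ortholog-group table (group_id, strain, gene_id) equivalent to the
    planted presence/absence truth."""
    rows = []
    for gene_id, row in presence.iterrows():
        for strain, present in row.items():
            if bool(present):
                rows.append(
                    {"group_id": gene_id, "strain": strain,
                     "gene_id": f"{strain}|{gene_id}"}
                )
    return pd.DataFrame(rows, columns=["group_id", "strain", "gene_id"])


# --------------------------------------------------------------------------
# Preset study-condition configurations
# --------------------------------------------------------------------------


def sv_benchmark_config(seed: int = 1) -> SimConfig:
    """Six-strain SV benchmark: an unedited base strain plus five derived
    strains, each carrying one planted event of each of the five types
    (200 bp - 80 kb) on a 100 kb + 150 kb genome, at 0.002 substitutions/
    site of background divergence."""
    derived = [f"sv{i}" for i in range(1, 6)]
    tree = TreeNode(
        "root",
        0.0,
        children=[TreeNode("base", 0.0, role="other_conspecific")]
        + [TreeNode(s, 0.002, role="other_conspecific") for s in derived],
    )
    sv_plan = []
    for s in derived:
        sv_plan += [
            SVDirective(s, "DEL", "chr1", 15_000, 200),
            SVDirective(s, "INS", "chr1", 40_000, 500),
            SVDirective(s, "DUP", "chr1", 60_000, 2_500),
            SVDirective(s, "INV", "chr1", 80_000, 4_000),
            SVDirective(s, "TRA", "chr2", 70_000, 80_000, acceptor_chrom="chr1"),
        ]
    return SimConfig(
        seed=seed, chrom_lengths=[100_000, 150_000], tree=tree, sv_plan=sv_plan
    )


def ty_benchmark_config(seed: int = 1) -> SimConfig:
    """Three strains, each planted with 3 solo LTRs, one complete functional
    element, one premature-stop element, one frameshifted element, and one
    internally 2-kb-truncated element on a clean 60-kb chromosome."""
    strains = ["tyA", "tyB", "tyC"]
    tree = TreeNode(
        "root", 0.0,
        children=[TreeNode(s, 0.0, role="other_conspecific") for s in strains],
    )
    plan = []
    for s in strains:
        plan += [
            TyDirective(s, "Ty1", "solo_LTR", "not_applicable", "chr1", 5_000),
            TyDirective(s, "Ty2", "solo_LTR", "not_applicable", "chr1", 12_000),
            TyDirective(s, "Ty5", "solo_LTR", "not_applicable", "chr1", 19_000),
            TyDirective(s, "Ty1", "complete", "functional", "chr1", 26_000),
            TyDirective(s, "Ty2", "complete", "loss_of_function", "chr1", 34_000),
            TyDirective(s, "Ty3", "complete", "frameshift", "chr1", 42_000),
            TyDirective(s, "Ty5", "truncated", "functional", "chr1", 50_000),
        ]
    return SimConfig(seed=seed, chrom_lengths=[60_000], tree=tree, ty_plan=plan)


def introgression_benchmark_config(seed: int = 1) -> SimConfig:
    """Three focal + three non-focal strains; 12 ORFs of 750 bp; three ORFs
    introgressed at 8% divergence in the focal clade."""
    focal = ["F1", "F2", "F3"]
    others = ["N1", "N2", "N3"]
    tree = TreeNode(
        "root", 0.0,
        children=[
            TreeNode("focal_clade", 0.0, children=[TreeNode(s, 0.002, role="focal") for s in focal]),
        ]
        + [TreeNode(s, 0.002, role="other_conspecific") for s in others],
    )
    gene_plan = [
        GeneDirective(f"orf{i:02d}", "chr1", 1_000 + i * 1_500, 750, "core")
        for i in range(12)
    ]
    intro = [
        IntrogressionDirective(f"orf{i:02d}", 0.08, tuple(focal)) for i in range(3)
    ]
    return SimConfig(
        seed=seed, chrom_lengths=[40_000], tree=tree, gene_plan=gene_plan,
        introgression_plan=intro,
    )


def default_panel_config(seed: int = 1) -> SimConfig:
    """Seven-strain study panel: a 3-strain focal clade (East Asian
    Clade IX analog, sharing a terminal translocation), three other
    conspecific strains, and one outgroup stand-in; genes with core /
    focal-absent / sporadic presence patterns; introgressed ORFs; planted
    Ty loci; 0.005 substitutions/site per branch."""
    focal = ["F1", "F2", "F3"]
    others = ["N1", "N2", "N3"]
    tree = TreeNode(
        "root", 0.0,
        children=[
            TreeNode(
                "focal_clade", 0.005,
                children=[TreeNode(s, 0.002, role="focal") for s in focal],
            ),
            TreeNode("N1", 0.005, role="other_conspecific"),
            TreeNode("N2", 0.005, role="other_conspecific"),
            TreeNode("N3", 0.005, role="other_conspecific"),
            TreeNode("OUT", 0.02, role="outgroup"),
        ],
    )
    all_strains = focal + others + ["OUT"]
    non_focal = others + ["OUT"]
    gene_plan: list[GeneDirective] = []
    # 20 core genes on chr1
    for i in range(20):
        gene_plan.append(
            GeneDirective(f"g{i:03d}", "chr1", 1_000 + i * 1_500, 900, "core")
        )
    # 4 focal-absent genes present in every non-focal strain (missing core
    # genes, and loss candidates via the outgroup)
    for i in range(20, 24):
        gene_plan.append(
            GeneDirective(f"g{i:03d}", "chr1", 1_000 + i * 1_500, 900, "focal_absent")
        )
    # 3 focal-absent genes with sporadic non-focal presence (loss candidates
    # but not missing core genes)
    sporadic = [("N1", "OUT"), ("N2", "N3", "OUT"), ("N1", "N3", "OUT")]
    for i, present in zip(range(24, 27), sporadic):
        gene_plan.append(
            GeneDirective(
                f"g{i:03d}", "chr1", 1_000 + i * 1_500, 900, "explicit", tuple(present)
            )
        )
    # 2 genes absent from focal AND outgroup (missing core genes that are
    # not loss candidates: no outgroup support)
    for i in range(27, 29):
        gene_plan.append(
            GeneDirective(
                f"g{i:03d}", "chr1", 1_000 + i * 1_500, 900, "explicit", tuple(others)
            )
        )
    intro = [
        IntrogressionDirective(f"g{i:03d}", 0.08, tuple(focal)) for i in range(3)
    ]
    sv_plan: list[SVDirective] = []
    for s in focal:  # the shared ~80-kb terminal translocation analog
        sv_plan.append(SVDirective(s, "TRA", "chr2", 70_000, 80_000, acceptor_chrom="chr1"))
    sv_plan += [
        SVDirective("N1", "INV", "chr1", 80_000, 4_000),
        SVDirective("N2", "DEL", "chr1", 80_000, 300),
        SVDirective("N3", "DUP", "chr1", 80_000, 2_500),
        SVDirective("F1", "DEL", "chr1", 90_000, 500),
        SVDirective("F2", "INS", "chr1", 90_000, 500),
    ]
    ty_plan: list[TyDirective] = []
    for s in all_strains:
        ty_plan.append(TyDirective(s, "Ty1", "solo_LTR", "not_applicable", "chr2", 5_000))
    for s in focal:
        ty_plan += [
            TyDirective(s, "Ty5", "complete", "functional", "chr2", 20_000),
            TyDirective(s, "Ty5", "solo_LTR", "not_applicable", "chr2", 40_000),
        ]
    return SimConfig(
        seed=seed,
        chrom_lengths=[100_000, 150_000],
        tree=tree,
        sv_plan=sv_plan,
        ty_plan=ty_plan,
        gene_plan=gene_plan,
        introgression_plan=intro,
    )


PRESETS = {
    "panel": default_panel_config,
    "sv_benchmark": sv_benchmark_config,
    "ty_benchmark": ty_benchmark_config,
    "introgression_benchmark": introgression_benchmark_config,
}


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------


def config_from_yaml(path: str | Path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "preset" in d:
        cfg = PRESETS[d["preset"]](int(d.get("seed", 1)))
        return cfg
    return SimConfig(
        seed=int(d["seed"]),
        chrom_lengths=[int(x) for x in d["chrom_lengths"]],
        gc=float(d.get("gc", 0.38)),
        chrom_names=d.get("chrom_names"),
        tree=TreeNode.from_dict(d["tree"]),
        sv_plan=[SVDirective(**x) for x in d.get("sv_plan", [])],
        ty_plan=[TyDirective(**x) for x in d.get("ty_plan", [])],
        gene_plan=[
            GeneDirective(**{**x, "present_in": tuple(x.get("present_in", []))})
            for x in d.get("gene_plan", [])
        ],
        introgression_plan=[
            IntrogressionDirective(**{**x, "strains": tuple(x["strains"])})
            for x in d.get("introgression_plan", [])
        ],
        ty_library_seed=int(d.get("ty_library_seed", 0)),
    )
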