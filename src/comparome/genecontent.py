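"""Pangenome presence/absence, gene-loss definitions, and the
introgression-candidate ORF filter.

Two gene-loss definitions are implemented against a genes x strains
presence/absence matrix whose strains carry role tags (focal clade, other
conspecific strains, outgroup species):

* *candidate gene losses* — genes in the cumulative gene set (pangenome) of
  the non-focal conspecific strains that are also found in at least one
  outgroup (so the gene predates the species) but are absent from every
  focal strain;
* *missing core genes* — genes in the consensus (core) set of all non-focal
  conspecific strains that are absent from every focal strain.

The introgression filter flags ORFs of a focal clade whose best alignments
against all non-focal conspecific ORF catalogs show anomalously low
identity: the ORF must be found in all focal strains, its mean percent
identity across non-focal best hits must be <= 95%, the aligned region must
cover >= 75% of the query ORF, and at least two-thirds of the clade's
alignments for the ORF must have <= 95% identity. All thresholds are
inclusive and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import GeneFeature, Genome
from .seqalign import LocalAlignmentResult, local_align

LOW_IDENTITY_CUTOFF = 95.0


@dataclass
class PresenceAbsenceMatrix:
    """Genes x strains boolean incidence with strain role tags."""

    cells: pd.DataFrame  # bool, index=gene ids, columns=strain names
    roles: dict[str, str]  # strain -> focal | other_conspecific | outgroup

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.cells.columns.has_duplicates:
            raise ValueError("duplicate strain names")
        missing = set(self.cells.columns) - set(self.roles)
        if missing:
            raise ValueError(f"strains without a role tag: {sorted(missing)}")
        self.cells = self.cells.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def strains(self) -> list[str]:
        return list(self.cells.columns)

    def strains_with_role(self, role: str) -> list[str]:
        return [s for s in self.strains if self.roles[s] == role]


def build_matrix(
    ortholog_groups: pd.DataFrame,
    strains: list[str],
    roles: dict[str, str],
) -> PresenceAbsenceMatrix:
    """Presence/absence matrix from an ortholog-group table with columns
    (group_id, strain, gene_id): one row per group, presence = the strain
    has at least one member. Ordering is stable (first appearance for
    groups, panel order for strains)."""
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain names in panel")
    required = {"group_id", "strain", "gene_id"}
    if not required.issubset(ortholog_groups.columns):
        raise ValueError(f"ortholog group table needs columns {sorted(required)}")
    unknown = set(ortholog_groups["strain"]) - set(strains)
    if unknown:
        raise ValueError(f"strains in groups but not in panel: {sorted(unknown)}")
    genes = list(dict.fromkeys(ortholog_groups["group_id"]))
    cells = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"), columns=strains)
    for group, strain in zip(ortholog_groups["group_id"], ortholog_groups["strain"]):
        cells.loc[group, strain] = True
    return PresenceAbsenceMatrix(cells=cells, roles=dict(roles))


def _split_panel(
    matrix: PresenceAbsenceMatrix, focal: set[str] | None
) -> tuple[list[str], list[str], list[str]]:
    focal_strains = (
        sorted(focal) if focal is not None else matrix.strains_with_role("focal")
    )
    if not focal_strains:
        raise ValueError("focal strain set is empty")
    conspecific = [
        s for s in matrix.strains
        if matrix.roles[s] != "outgroup" and s not in focal_strains
    ]
    outgroups = matrix.strains_with_role("outgroup")
    return focal_strains, conspecific, outgroups


def candidate_gene_losses(
    matrix: PresenceAbsenceMatrix, focal: set[str] | None = None
) -> list[str]:
    """Genes present in the pangenome of the non-focal conspecific strains
    AND in at least one outgroup, but absent from every focal strain."""
    focal_strains, conspecific, outgroups = _split_panel(matrix, focal)
    if not outgroups:
        raise ValueError("at least one outgroup strain must be tagged")
    c = matrix.cells
    mask = (
        c[conspecific].any(axis=1)
        & c[outgroups].any(axis=1)
        & ~c[focal_strains].any(axis=1)
    )
    return list(c.index[mask])


def missing_core_genes(
    matrix: PresenceAbsenceMatrix, focal: set[str] | None = None
) -> list[str]:
    """Genes present in the consensus (core) set of all non-focal
    conspecific strains but absent from every focal strain."""
    focal_strains, conspecific, _ = _split_panel(matrix, focal)
    if not conspecific:
        raise ValueError("no non-focal conspecific strains in panel")
    c = matrix.cells
    mask = c[conspecific].all(axis=1) & ~c[focal_strains].any(axis=1)
    return list(c.index[mask])


# --------------------------------------------------------------------------
# Introgression-candidate ORF filter
# --------------------------------------------------------------------------


@dataclass
class FilterThresholds:
    max_mean_identity: float = 95.0
    min_query_coverage: float = 0.75
    min_low_identity_fraction: float = 2.0 / 3.0
    low_identity_cutoff: float = LOW_IDENTITY_CUTOFF
    ortholog_min_identity: float = 80.0
    ortholog_min_coverage: float = 0.5
    coverage_mode: str = "mean"  # "mean" or "min" across best hits

    def __post_init__(self) -> None:
        if not 0 <= self.max_mean_identity <= 100:
            raise ValueError("max_mean_identity outside [0, 100]")
        if not 0 <= self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage outside [0, 1]")
        if not 0 <= self.min_low_identity_fraction <= 1:
            raise ValueError("min_low_identity_fraction outside [0, 1]")
        if self.coverage_mode not in ("mean", "min"):
            raise ValueError("coverage_mode must be 'mean' or 'min'")


@dataclass
class IntrogressionCandidate:
    orf_id: str
    mean_identity: float
    query_coverage: float
    low_identity_fraction: float
    found_in_all_focal: bool
    passes_identity: bool
    passes_coverage: bool
    passes_low_identity_fraction: bool
    n_alignments: int
    reason: str = ""
    focal_members: dict[str, str] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return (
            self.found_in_all_focal
            and self.passes_identity
            and self.passes_coverage
            and self.passes_low_identity_fraction
        )


def _kmer_set(seq: str, k: int = 15) -> set[str]:
    return {seq[i : i + k] for i in range(0, max(0, len(seq) - k + 1))}


def best_hit(
    query: str,
    catalog: dict[str, str],
    prefilter_top: int = 3,
) -> tuple[str | None, LocalAlignmentResult | None]:
    """Best-matching ORF in ``catalog`` by local-alignment score.

    Candidate targets are pre-ranked by shared 15-mer count and only the
    top few aligned (exhaustive alignment against every catalog entry is
    quadratic in catalog size with no effect on the outcome for diverged-
    but-homologous ORFs). Equal-score ties go to the lexicographically
    smallest target id.
    """
    if not catalog:
        return None, None
    qk = _kmer_set(query)
    ranked = sorted(
        catalog,
        key=lambda t: (-len(qk & _kmer_set(catalog[t])), t),
    )
    shortlist = ranked[:prefilter_top]
    best_id, best_res = None, None
    for tid in sorted(shortlist):
        res = local_align(query, catalog[tid])
        if (
            best_res is None
            or res.score > best_res.score
            or (res.score == best_res.score and tid < best_id)
        ):
            best_id, best_res = tid, res
    if best_res is None or best_res.score <= 0:
        return None, None
    return best_id, best_res


def _focal_orthologs(
    orf_id: str,
    orf_catalogs: dict[str, dict[str, str]],
    focal: list[str],
    min_identity: float,
    min_coverage: float = 0.5,
) -> dict[str, str]:
    """Members of the ORF's ortholog group across the focal clade, by
    reciprocal best local alignment at >= ``min_identity``% identity over
    >= ``min_coverage`` of the query (a short high-identity local segment
    between unrelated ORFs is not orthology)."""
    anchor = focal[0]
    members = {anchor: orf_id}
    query = orf_catalogs[anchor][orf_id]
    for strain in focal[1:]:
        tid, res = best_hit(query, orf_catalogs[strain])
        if tid is None or res.identity < min_identity or res.query_coverage < min_coverage:
            continue
        back_id, _ = best_hit(orf_catalogs[strain][tid], orf_catalogs[anchor])
        if back_id == orf_id:
            members[strain] = tid
    return members


def introgression_candidates(
    orf_catalogs: dict[str, dict[str, str]],
    focal: list[str],
    others: list[str],
    thresholds: FilterThresholds | None = None,
) -> list[IntrogressionCandidate]:
    """Apply the four-criterion introgression filter to every ORF of the
    first focal strain (the clade anchor).

    For each focal copy of the ORF, the best-matching ORF in every
    non-focal strain is found by local alignment; identity and query
    coverage are pooled across the clade's alignments. ORFs with zero
    non-focal hits are flagged ``no_hit`` and excluded with a reason rather
    than silently dropped.
    """
    if not focal:
        raise ValueError("focal strain set is empty")
    for s in list(focal) + list(others):
        if s not in orf_catalogs or not orf_catalogs[s]:
            raise ValueError(f"missing or empty ORF catalog for strain {s!r}")
    th = thresholds or FilterThresholds()
    focal = sorted(focal)
    others = sorted(others)
    results: list[IntrogressionCandidate] = []
    anchor = focal[0]
    for orf_id in sorted(orf_catalogs[anchor]):
        members = _focal_orthologs(
            orf_id, orf_catalogs, focal,
            th.ortholog_min_identity, th.ortholog_min_coverage,
        )
        found_all = len(members) == len(focal)
        identities: list[float] = []
        coverages: list[float] = []
        for strain, member_id in sorted(members.items()):
            query = orf_catalogs[strain][member_id]
            for other in others:
                tid, res = best_hit(query, orf_catalogs[other])
                if tid is None:
                    continue
                identities.append(res.identity)
                coverages.append(res.query_coverage)
        if not identities:
            results.append(
                IntrogressionCandidate(
                    orf_id=orf_id, mean_identity=0.0, query_coverage=0.0,
                    low_identity_fraction=0.0, found_in_all_focal=found_all,
                    passes_identity=False, passes_coverage=False,
                    passes_low_identity_fraction=False, n_alignments=0,
                    reason="no_hit", focal_members=members,
                )
            )
            continue
        mean_identity = sum(identities) / len(identities)
        coverage = (
            sum(coverages) / len(coverages)
            if th.coverage_mode == "mean"
            else min(coverages)
        )
        low_frac = sum(
            1 for i in identities if i <= th.low_identity_cutoff
        ) / len(identities)
        results.append(
            IntrogressionCandidate(
                orf_id=orf_id,
                mean_identity=mean_identity,
                query_coverage=coverage,
                low_identity_fraction=low_frac,
                found_in_all_focal=found_all,
                passes_identity=mean_identity <= th.max_mean_identity,
                passes_coverage=coverage >= th.min_query_coverage,
                passes_low_identity_fraction=low_frac >= th.min_low_identity_fraction,
                n_alignments=len(identities),
                focal_members=members,
            )
        )
    return results


def candidates_to_frame(candidates: list[IntrogressionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": c.orf_id,
                "mean_identity": c.mean_identity,
                "query_coverage": c.query_coverage,
                "low_identity_fraction": c.low_identity_fraction,
                "found_in_all_focal": c.found_in_all_focal,
                "passes_identity": c.passes_identity,
                "passes_coverage": c.passes_coverage,
                "passes_low_identity_fraction": c.passes_low_identity_fraction,
                "overall_pass": c.overall_pass,
                "n_alignments": c.n_alignments,
                "reason": c.reason,
            }
            for c in candidates
        ]
    )


# --------------------------------------------------------------------------
# Genome content summary
# --------------------------------------------------------------------------


def genome_content_summary(genome: Genome, annotation: list[GeneFeature]) -> dict:
    """Plain descriptive genome-content statistics: genome size, gene count,
    cumulative gene length, coding fraction, and noncoding bp."""
    size = genome.total_length
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    total_gene_len = 0
    for f in annotation:
        if f.chrom not in genome:
            raise ValueError(f"gene {f.gene_id}: unknown chromosome {f.chrom!r}")
        if not (0 <= f.start < f.end <= len(genome[f.chrom])):
            raise ValueError(f"gene {f.gene_id}: interval out of bounds")
        per_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        total_gene_len += f.length
    coding = 0
    for ivs in per_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                coding += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        coding += cur_e - cur_s
    return {
        "genome_size": size,
        "gene_count": len(annotation),
        "cumulative_gene_length": total_gene_len,
        "coding_fraction": coding / size if size else 0.0,
        "noncoding_bp": size - coding,
        "intron_count": 0,
        "intron_length": 0,
    }


def read_ortholog_groups(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
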