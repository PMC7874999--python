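"""Tests for presence/absence construction, gene-loss set definitions,
the introgression filter, and genome-content summaries."""

import numpy as np
import pandas as pd
import pytest

from comparome.genome import GeneFeature, Genome
from comparome.genecontent import (
    FilterThresholds,
    PresenceAbsenceMatrix,
    build_matrix,
    candidate_gene_losses,
    candidates_to_frame,
    genome_content_summary,
    introgression_candidates,
    missing_core_genes,
)
from comparome.synthdata import generate_ancestor

from .oracles import gene_loss_oracle

PANEL = [f"s{i}" for i in range(15)]
ROLES = {
    **{s: "focal" for s in PANEL[:3]},
    **{s: "other_conspecific" for s in PANEL[3:10]},
    **{s: "outgroup" for s in PANEL[10:]},
}


def random_matrix(rng, n_genes=200):
    cells = pd.DataFrame(
        rng.random((n_genes, len(PANEL))) < rng.uniform(0.2, 0.9),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
        columns=PANEL,
    )
    return PresenceAbsenceMatrix(cells=cells, roles=ROLES)


class TestBuildMatrix:
    def test_presence_from_groups(self):
        groups = pd.DataFrame(
            [
                {"group_id": "g1", "strain": "A", "gene_id": "A|g1"},
                {"group_id": "g1", "strain": "B", "gene_id": "B|g1"},
            ]
        )
        m = build_matrix(groups, ["A", "B", "C"],
                         {"A": "focal", "B": "other_conspecific", "C": "outgroup"})
        assert list(m.cells.loc["g1"]) == [True, True, False]

    def test_empty_table_empty_matrix(self):
        groups = pd.DataFrame(columns=["group_id", "strain", "gene_id"])
        m = build_matrix(groups, ["A"], {"A": "focal"})
        assert len(m.genes) == 0

    def test_unknown_strain_rejected(self):
        groups = pd.DataFrame([{"group_id": "g1", "strain": "Z", "gene_id": "x"}])
        with pytest.raises(ValueError, match="Z"):
            build_matrix(groups, ["A"], {"A": "focal"})

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_direct_tabulation(self, trial):
        rng = np.random.default_rng(100 + trial)
        rows = []
        for gi in range(30):
            for s in PANEL:
                if rng.random() < 0.5:
                    rows.append({"group_id": f"g{gi}", "strain": s, "gene_id": f"{s}|g{gi}"})
        if not rows:
            return
        groups = pd.DataFrame(rows)
        m = build_matrix(groups, PANEL, ROLES)
        for _, r in groups.iterrows():
            assert bool(m.cells.loc[r.group_id, r.strain])
        expected_true = len({(r.group_id, r.strain) for _, r in groups.iterrows()})
        assert int(m.cells.values.sum()) == expected_true


class TestGeneLossSets:
    def test_candidate_rule_case(self):
        cells = pd.DataFrame(False, index=["g"], columns=PANEL)
        for s in PANEL[3:8]:
            cells.loc["g", s] = True
        for s in PANEL[10:12]:
            cells.loc["g", s] = True
        m = PresenceAbsenceMatrix(cells=cells, roles=ROLES)
        assert candidate_gene_losses(m) == ["g"]

    def test_no_outgroup_support_means_no_candidate(self):
        cells = pd.DataFrame(False, index=["g"], columns=PANEL)
        for s in PANEL[3:10]:
            cells.loc["g", s] = True
        m = PresenceAbsenceMatrix(cells=cells, roles=ROLES)
        assert candidate_gene_losses(m) == []
        # but it is a missing core gene: all conspecifics carry it
        assert missing_core_genes(m) == ["g"]

    def test_core_requires_every_conspecific(self):
        cells = pd.DataFrame(False, index=["g"], columns=PANEL)
        for s in PANEL[3:9]:  # 6 of 7 conspecifics
            cells.loc["g", s] = True
        m = PresenceAbsenceMatrix(cells=cells, roles=ROLES)
        assert missing_core_genes(m) == []

    def test_empty_focal_rejected(self):
        m = random_matrix(np.random.default_rng(0))
        with pytest.raises(ValueError):
            candidate_gene_losses(m, focal=set())

    @pytest.mark.parametrize("trial", range(50))
    def test_sets_match_comprehension_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        m = random_matrix(rng)
        cells = {g: dict(m.cells.loc[g]) for g in m.genes}
        assert set(candidate_gene_losses(m)) == gene_loss_oracle(cells, ROLES, "candidate")
        assert set(missing_core_genes(m)) == gene_loss_oracle(cells, ROLES, "core")
        # the core definition is the stricter conspecific requirement:
        # whenever a missing core gene has outgroup support it is also a
        # loss candidate
        candidates = set(candidate_gene_losses(m))
        for g in missing_core_genes(m):
            if any(cells[g][s] for s, r in ROLES.items() if r == "outgroup"):
                assert g in candidates


# --------------------------------------------------------------------------
# Introgression filter
# --------------------------------------------------------------------------


def _mutate(seq, positions):
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rot[out[p]]
    return "".join(out)


def _catalogs(rng, n_other_orfs=2):
    """Catalogs with one focal ORF 'orfX' and unrelated padding ORFs."""
    base = "".join(rng.choice(list("ACGT"), size=300))
    catalogs = {}
    for s in ("F1", "F2", "F3"):
        catalogs[s] = {"orfX": base}
    for s in ("N1", "N2", "N3"):
        catalogs[s] = {"orfX": base}
    for s in catalogs:
        for j in range(n_other_orfs):
            catalogs[s][f"pad{j}"] = "".join(rng.choice(list("ACGT"), size=300))
    return base, catalogs


class TestIntrogressionFilter:
    def test_planted_divergence_passes_all_criteria(self, intro_fixture):
        truth = set(intro_fixture.truth.introgressed_orfs.gene_id)
        cands = introgression_candidates(
            intro_fixture.orf_catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"]
        )
        passed = {c.orf_id for c in cands if c.overall_pass}
        assert passed == truth

    def test_mean_identity_exactly_95_is_inclusive_pass(self):
        rng = np.random.default_rng(1)
        base, catalogs = _catalogs(rng)
        positions = list(range(30, 30 + 15 * 16, 16))  # 15 interior subs = 95.0%
        for s in ("N1", "N2", "N3"):
            catalogs[s]["orfX"] = _mutate(base, positions)
        cands = introgression_candidates(catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
        c = next(x for x in cands if x.orf_id == "orfX")
        assert c.mean_identity == pytest.approx(95.0)
        assert c.overall_pass

    def test_mean_identity_just_above_95_fails_only_identity(self):
        rng = np.random.default_rng(2)
        base, catalogs = _catalogs(rng)
        low = list(range(30, 30 + 16 * 16, 16))  # 16 subs = 94.67%
        high = list(range(30, 30 + 12 * 20, 20))  # 12 subs = 96.0%
        catalogs["N1"]["orfX"] = _mutate(base, low)
        catalogs["N2"]["orfX"] = _mutate(base, low)
        catalogs["N3"]["orfX"] = _mutate(base, high)
        cands = introgression_candidates(catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
        c = next(x for x in cands if x.orf_id == "orfX")
        assert c.mean_identity > 95.0
        assert not c.passes_identity
        assert c.found_in_all_focal
        assert c.passes_coverage
        assert c.passes_low_identity_fraction  # 2/3 of alignments <= 95%
        assert not c.overall_pass

    def test_coverage_below_three_quarters_fails_only_coverage(self):
        rng = np.random.default_rng(3)
        base, catalogs = _catalogs(rng)
        # targets carry only 74% of the query, diverged ~6% inside that part
        prefix = base[:222]
        positions = list(range(20, 20 + 13 * 15, 15))
        for s in ("N1", "N2", "N3"):
            catalogs[s]["orfX"] = _mutate(prefix, positions)
        cands = introgression_candidates(catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
        c = next(x for x in cands if x.orf_id == "orfX")
        assert c.query_coverage == pytest.approx(0.74)
        assert not c.passes_coverage
        assert c.found_in_all_focal
        assert c.passes_identity
        assert c.passes_low_identity_fraction
        assert not c.overall_pass

    def test_orf_missing_from_one_focal_strain_fails_presence(self):
        rng = np.random.default_rng(4)
        base, catalogs = _catalogs(rng)
        del catalogs["F3"]["orfX"]
        positions = list(range(30, 30 + 20 * 13, 13))
        for s in ("N1", "N2", "N3"):
            catalogs[s]["orfX"] = _mutate(base, positions)
        cands = introgression_candidates(catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
        c = next(x for x in cands if x.orf_id == "orfX")
        assert not c.found_in_all_focal
        assert c.passes_identity
        assert c.passes_coverage
        assert c.passes_low_identity_fraction
        assert not c.overall_pass

    def test_orf_without_any_hit_reported_with_reason(self):
        rng = np.random.default_rng(5)
        base, catalogs = _catalogs(rng, n_other_orfs=0)
        for s in ("N1", "N2", "N3"):
            catalogs[s] = {"unrelated": "".join(rng.choice(list("ACGT"), size=300))}
        cands = introgression_candidates(catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
        by_id = {c.orf_id: c for c in cands}
        x = by_id["orfX"]
        assert x.reason == "no_hit" or x.n_alignments == 0 or not x.overall_pass

    def test_filter_monotone_in_divergence(self):
        """On substitution-only fixtures, raising planted divergence never
        turns a passing candidate into a failing one."""
        rng = np.random.default_rng(6)
        base, catalogs = _catalogs(rng)
        passing = []
        for div in (0.06, 0.09, 0.12):
            n_subs = int(div * 300)
            positions = list(range(15, 15 + n_subs * max(1, 270 // n_subs),
                                   max(1, 270 // n_subs)))[:n_subs]
            cat = {s: dict(c) for s, c in catalogs.items()}
            for f in ("F1", "F2", "F3"):
                cat[f]["orfX"] = _mutate(base, positions)
            cands = introgression_candidates(cat, ["F1", "F2", "F3"], ["N1", "N2", "N3"])
            c = next(x for x in cands if x.orf_id == "orfX")
            passing.append(c.overall_pass)
        assert passing[0]
        assert passing == sorted(passing, reverse=True) or all(passing)

    def test_deterministic_candidate_list(self, intro_fixture):
        a = introgression_candidates(
            intro_fixture.orf_catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"]
        )
        b = introgression_candidates(
            intro_fixture.orf_catalogs, ["F1", "F2", "F3"], ["N1", "N2", "N3"]
        )
        assert candidates_to_frame(a).equals(candidates_to_frame(b))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            FilterThresholds(max_mean_identity=120)


class TestGenomeContent:
    def test_coding_fraction_arithmetic(self):
        g = generate_ancestor(1, [10_000], 0.38, 7)
        feats = [
            GeneFeature("a", "chr1", 0, 1_000),
            GeneFeature("b", "chr1", 2_000, 3_000),
            GeneFeature("c", "chr1", 5_000, 6_000),
        ]
        s = genome_content_summary(g, feats)
        assert s["gene_count"] == 3
        assert s["cumulative_gene_length"] == 3_000
        assert s["coding_fraction"] == pytest.approx(0.3)
        assert s["noncoding_bp"] == 7_000

    def test_empty_annotation(self):
        g = generate_ancestor(1, [5_000], 0.38, 8)
        s = genome_content_summary(g, [])
        assert s["gene_count"] == 0
        assert s["noncoding_bp"] == 5_000

    def test_out_of_bounds_gene_rejected(self):
        g = generate_ancestor(1, [5_000], 0.38, 9)
        with pytest.raises(ValueError):
            genome_content_summary(g, [GeneFeature("a", "chr1", 4_000, 6_000)])

    def test_fixture_summary_matches_gene_plan(self, intro_fixture):
        cfg = intro_fixture.config
        for strain, genome in intro_fixture.genomes.items():
            s = genome_content_summary(genome, intro_fixture.annotations[strain])
            planned = [
                g for g in cfg.gene_plan
                if bool(intro_fixture.truth.gene_presence.loc[g.gene_id, strain])
            ]
            assert s["gene_count"] == len(planned)
            assert s["cumulative_gene_length"] == sum(g.length for g in planned)
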