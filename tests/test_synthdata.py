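"""Tests for the synthetic-panel generator: primitives, conservation
invariants, truth-table round trips, and deterministic emission."""

import hashlib

import numpy as np
import pytest
from scipy import stats

from comparome.genome import read_gff3, revcomp
from comparome.synthdata import (
    SimConfig,
    SVDirective,
    TreeNode,
    TruthTables,
    TyDirective,
    apply_substitutions,
    build_ty_element_sequence,
    emit_fixture,
    generate_ancestor,
    introgression_benchmark_config,
    plant_sv,
    plant_ty_element,
    simulate,
    sv_benchmark_config,
    synthetic_ty_library,
    ty_benchmark_config,
)


class TestGenerateAncestor:
    def test_exact_chromosome_count_and_lengths(self):
        g = generate_ancestor(2, [10_000, 8_000], 0.38, seed=7)
        assert [len(g[c]) for c in g] == [10_000, 8_000]

    def test_deterministic_for_fixed_seed(self):
        a = generate_ancestor(2, [10_000, 8_000], 0.38, seed=7)
        b = generate_ancestor(2, [10_000, 8_000], 0.38, seed=7)
        assert a.chromosomes == b.chromosomes

    def test_gc_one_yields_only_gc_bases(self):
        g = generate_ancestor(1, [5_000], 1.0, seed=1)
        assert set(g["chr1"]) <= {"G", "C"}

    def test_gc_matches_in_expectation(self):
        g = generate_ancestor(1, [200_000], 0.38, seed=2)
        gc = sum(c in "GC" for c in g["chr1"]) / 200_000
        assert abs(gc - 0.38) < 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_chroms=1, chrom_lengths=[0], gc=0.4, seed=1),
            dict(n_chroms=1, chrom_lengths=[100], gc=1.5, seed=1),
            dict(n_chroms=2, chrom_lengths=[100], gc=0.4, seed=1),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_ancestor(**kwargs)


class TestApplySubstitutions:
    def test_zero_rate_identity(self):
        g = generate_ancestor(1, [10_000], 0.38, 3)
        out, recs = apply_substitutions(g, 0.0, 4)
        assert out.chromosomes == g.chromosomes
        assert recs == []

    def test_substitution_count_within_binomial_bounds(self):
        g = generate_ancestor(1, [10_000], 0.38, 5)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 10_000, 0.01)
        outside = 0
        for seed in range(10):
            _, recs = apply_substitutions(g, 0.01, seed)
            outside += not lo <= len(recs) <= hi
        # over repeated seeds counts live in the central 99.9% interval;
        # tolerate a single tail draw
        assert outside <= 1

    def test_every_record_changes_the_base(self):
        g = generate_ancestor(1, [20_000], 0.38, 6)
        out, recs = apply_substitutions(g, 0.01, 7)
        assert recs
        for r in recs:
            assert r.ref_base != r.alt_base
            assert out["chr1"][r.pos] == r.alt_base
            assert g["chr1"][r.pos] == r.ref_base

    def test_length_unchanged_and_rate_validated(self):
        g = generate_ancestor(1, [5_000], 0.38, 8)
        out, _ = apply_substitutions(g, 0.02, 9)
        assert len(out["chr1"]) == 5_000
        with pytest.raises(ValueError):
            apply_substitutions(g, 0.3, 9)

    def test_excluded_intervals_untouched(self):
        g = generate_ancestor(1, [10_000], 0.38, 10)
        out, recs = apply_substitutions(g, 0.05, 11, exclude={"chr1": [(2_000, 4_000)]})
        assert out["chr1"][2_000:4_000] == g["chr1"][2_000:4_000]
        assert all(not 2_000 <= r.pos < 4_000 for r in recs)


class TestPlantSV:
    @pytest.fixture()
    def genome(self):
        return generate_ancestor(2, [10_000, 12_000], 0.38, 20)

    def test_deletion_shortens_chromosome(self, genome):
        out, rec = plant_sv(genome, "DEL", "chr1", 2_000, 500)
        assert len(out["chr1"]) == 9_500
        assert (rec.ref_start, rec.ref_end, rec.size) == (2_000, 2_500, 500)

    def test_insertion_lengthens_chromosome(self, genome):
        out, _ = plant_sv(genome, "INS", "chr1", 2_000, 300, payload_seed=1)
        assert len(out["chr1"]) == 10_300
        assert out["chr1"][:2_000] == genome["chr1"][:2_000]

    def test_inversion_is_length_preserving_involution(self, genome):
        out, _ = plant_sv(genome, "INV", "chr1", 2_000, 300)
        assert len(out["chr1"]) == 10_000
        assert out["chr1"][2_000:2_300] == revcomp(genome["chr1"][2_000:2_300])
        back, _ = plant_sv(out, "INV", "chr1", 2_000, 300)
        assert back["chr1"] == genome["chr1"]

    def test_duplication_appends_tandem_copy(self, genome):
        out, _ = plant_sv(genome, "DUP", "chr1", 2_000, 400)
        assert len(out["chr1"]) == 10_400
        assert out["chr1"][2_000:2_400] == out["chr1"][2_400:2_800]

    def test_terminal_translocation_moves_segment(self):
        g = generate_ancestor(2, [100_000, 150_000], 0.38, 21)
        out, rec = plant_sv(g, "TRA", "chr2", 70_000, 80_000, acceptor_chrom="chr1")
        assert len(out["chr2"]) == 70_000
        assert len(out["chr1"]) == 180_000
        assert out["chr1"][100_000:] == g["chr2"][70_000:]
        assert (rec.qry_start, rec.qry_end) == (100_000, 180_000)

    def test_non_terminal_translocation_rejected(self, genome):
        with pytest.raises(ValueError, match="terminal"):
            plant_sv(genome, "TRA", "chr1", 2_000, 500, acceptor_chrom="chr2")

    def test_out_of_bounds_rejected(self, genome):
        with pytest.raises(ValueError):
            plant_sv(genome, "DEL", "chr1", 9_800, 500)


class TestPlantTyElement:
    def test_solo_ltr_inserts_exactly_the_ltr(self):
        lib = synthetic_ty_library(0)
        g = generate_ancestor(1, [20_000], 0.38, 30)
        out, rec = plant_ty_element(
            g, lib, "Ty1", "solo_LTR", "not_applicable", "chr1", 5_000
        )
        assert rec.end - rec.start == len(lib["Ty1"].ltr)
        assert out["chr1"][rec.start : rec.end] == lib["Ty1"].ltr

    def test_premature_stop_translates_to_early_stop(self):
        lib = synthetic_ty_library(0)
        seq, lesion = build_ty_element_sequence(lib, "Ty2", "complete", "loss_of_function")
        assert lesion.startswith("premature_stop")
        ltr_len = len(lib["Ty2"].ltr)
        internal = seq[ltr_len : len(seq) - ltr_len]
        codons = [internal[i : i + 3] for i in range(0, len(internal) - 3, 3)]
        stops = [i for i, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
        assert stops and stops[0] < len(codons) - 1

    def test_truncation_removes_about_two_kb(self):
        lib = synthetic_ty_library(0)
        seq, lesion = build_ty_element_sequence(
            lib, "Ty5", "truncated", "functional", truncation_bp=2_000
        )
        full_len = 2 * len(lib["Ty5"].ltr) + len(lib["Ty5"].internal)
        assert full_len - len(seq) == 2_000
        assert "internal_truncation_2000bp" in lesion

    def test_state_viability_conflicts_rejected(self):
        lib = synthetic_ty_library(0)
        with pytest.raises(ValueError):
            build_ty_element_sequence(lib, "Ty1", "solo_LTR", "functional")
        with pytest.raises(ValueError):
            build_ty_element_sequence(lib, "Ty9", "complete", "functional")


class TestSimulate:
    def test_length_conservation(self, sv_fixture):
        """Total sequence length equals the ancestor plus insertions and
        duplications minus deletions; translocations conserve length."""
        cfg = sv_fixture.config
        base_total = sum(cfg.chrom_lengths)
        for strain, genome in sv_fixture.genomes.items():
            delta = 0
            for d in cfg.sv_plan:
                if d.strain != strain:
                    continue
                delta += {"DEL": -d.size, "INS": d.size, "DUP": d.size,
                          "INV": 0, "TRA": 0}[d.type]
            assert genome.total_length == base_total + delta

    def test_substitution_truth_resolves_in_emitted_sequence(self, sv_fixture):
        subs = sv_fixture.truth.substitutions
        assert len(subs) > 0
        sample = subs.sample(n=min(300, len(subs)), random_state=0)
        for _, r in sample.iterrows():
            assert sv_fixture.genomes[r.strain][r.chrom][r.pos] == r.alt_base

    def test_ty_truth_coordinates_resolve(self, ty_fixture):
        lib = ty_fixture.ty_library
        for _, r in ty_fixture.truth.planted_ty.iterrows():
            seq = ty_fixture.genomes[r.strain].fetch(r.chrom, r.start, r.end)
            ltr = lib[r.ty_class].ltr
            assert seq.startswith(ltr)
            if r.state != "solo_LTR":
                assert seq.endswith(ltr)

    def test_sv_truth_query_coordinates_resolve(self, sv_fixture):
        base = sv_fixture.genomes["base"]
        for _, r in sv_fixture.truth.planted_svs.iterrows():
            qry = sv_fixture.genomes[r.strain]
            if r.type == "INV":
                planted = qry.fetch(r.qry_chrom, r.qry_start, r.qry_end)
                original = base.fetch(r.ref_chrom, r.ref_start, r.ref_end)
                assert planted == revcomp(original)
            elif r.type == "TRA":
                assert qry.fetch(r.qry_chrom, r.qry_start, r.qry_end) == base.fetch(
                    r.ref_chrom, r.ref_start, r.ref_end
                )

    def test_gene_presence_pattern_semantics(self, intro_fixture):
        presence = intro_fixture.truth.gene_presence
        # all ORFs in the introgression benchmark are core genes
        assert presence.all().all()
        for strain, catalog in intro_fixture.orf_catalogs.items():
            assert set(catalog) == set(presence.index)

    def test_introgressed_orf_length_preserved_and_diverged(self, intro_fixture):
        truth = intro_fixture.truth.introgressed_orfs
        for _, r in truth.iterrows():
            focal = r.strains.split(",")
            for s in focal:
                orf = intro_fixture.orf_catalogs[s][r.gene_id]
                ref = intro_fixture.orf_catalogs["N1"][r.gene_id]
                assert len(orf) == len(ref)
            # non-focal copies untouched by introgression planting
        n = len(intro_fixture.orf_catalogs["F1"][truth.gene_id.iloc[0]])
        diffs = sum(
            a != b
            for a, b in zip(
                intro_fixture.orf_catalogs["F1"][truth.gene_id.iloc[0]],
                intro_fixture.orf_catalogs["N1"][truth.gene_id.iloc[0]],
            )
        )
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.08 * 0.75 / 0.75)
        assert lo * 0.7 <= diffs <= hi * 1.1  # target divergence, binomial slack

    def test_zero_divergence_keeps_focal_identical(self):
        cfg = introgression_benchmark_config(3)
        from dataclasses import replace

        cfg.introgression_plan = [
            replace(cfg.introgression_plan[0], divergence=0.0)
        ]
        # remove background divergence so copies are byte-identical
        for leaf in cfg.tree.leaves():
            leaf.rate = 0.0
        fx = simulate(cfg)
        gid = cfg.introgression_plan[0].gene_id
        assert fx.orf_catalogs["F1"][gid] == fx.orf_catalogs["N1"][gid]

    def test_overlapping_planted_features_rejected(self):
        tree = TreeNode("r", 0.0, children=[TreeNode("A", 0.0, role="other_conspecific")])
        cfg = SimConfig(
            seed=1, chrom_lengths=[50_000], tree=tree,
            sv_plan=[
                SVDirective("A", "DEL", "chr1", 10_000, 500),
                SVDirective("A", "INV", "chr1", 10_200, 500),
            ],
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate(cfg)


class TestEmitFixture:
    def test_manifest_lists_every_strain(self, tmp_path):
        cfg = ty_benchmark_config(2)
        manifest = emit_fixture(cfg, tmp_path / "fx")
        assert len(manifest["strains"]) == 3

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = sv_benchmark_config(4)
        m1 = emit_fixture(cfg, tmp_path / "a")
        m2 = emit_fixture(sv_benchmark_config(4), tmp_path / "b")
        assert m1["files"] == m2["files"]
        for rel in m1["files"]:
            a = hashlib.md5((tmp_path / "a" / rel).read_bytes()).hexdigest()
            assert a == m1["files"][rel]

    def test_truth_tables_round_trip_through_tsv(self, tmp_path):
        cfg = introgression_benchmark_config(5)
        emit_fixture(cfg, tmp_path / "fx")
        fx = simulate(cfg)
        back = TruthTables.from_dir(tmp_path / "fx" / "truth")
        assert fx.truth.equals(back)

    def test_gff3_round_trip_matches_presence_truth(self, tmp_path):
        cfg = introgression_benchmark_config(6)
        manifest = emit_fixture(cfg, tmp_path / "fx")
        fx = simulate(cfg)
        for entry in manifest["strains"]:
            feats = read_gff3(tmp_path / "fx" / entry["annotation"])
            annotated = {f.gene_id for f in feats}
            expected = set(
                fx.truth.gene_presence.index[fx.truth.gene_presence[entry["name"]]]
            )
            assert annotated == expected
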