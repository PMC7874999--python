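"""One-config orchestration: simulate -> align -> SV -> Ty -> genes.

A single YAML run configuration drives the whole pipeline; every stage
writes into its own subdirectory of the output tree (write-once), and a
consolidated JSON report records per-stage outputs, record counts, the
normalized parameter echo, and runtime. Identical config + seed yields an
identical output tree.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome import Genome, read_gff3, read_orf_fasta
from .seqalign import read_paf, write_paf
from .svscan import SVMatrix, call_svs, enumerate_pairs, summarize_sv, svs_to_frame, write_bedpe
from .tyscan import TyLibrary, annotate_genome, elements_to_frame, ty_summary, write_elements_gff3
from .genecontent import (
    FilterThresholds,
    build_matrix,
    candidate_gene_losses,
    candidates_to_frame,
    genome_content_summary,
    introgression_candidates,
    missing_core_genes,
    read_ortholog_groups,
)
from .synthdata import PRESETS, config_from_yaml, emit_fixture

logger = logging.getLogger("comparome")

_STAGES = ("simulate", "align", "sv", "ty", "genes")

_DEFAULTS: dict = {
    "seed": 1,
    "stages": {s: True for s in _STAGES},
    "simulate": {"preset": "panel"},
    "align": {"min_seed": 20, "max_gap": 100, "min_block": 1000},
    "sv": {"min_size": 50},
    "ty": {"min_identity": 80.0, "min_part_fraction": 0.5, "pairing_window": 10000},
    "genes": {
        "max_mean_identity": 95.0,
        "min_query_coverage": 0.75,
        "min_low_identity_fraction": 2.0 / 3.0,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Normalized pipeline configuration."""

    seed: int
    stages: dict[str, bool]
    simulate: dict
    align: dict
    sv: dict
    ty: dict
    genes: dict
    input_dir: str | None = None  # pre-existing fixture instead of simulate

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "simulate": self.simulate,
            "align": self.align,
            "sv": self.sv,
            "ty": self.ty,
            "genes": self.genes,
            "input_dir": self.input_dir,
        }


def _merge_section(name: str, user: dict, defaults: dict) -> dict:
    out = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown key {name}.{key!r}")
        out[key] = value
    return out


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load and normalize a run configuration; unknown keys are rejected by
    name and defaults are filled in. A normalized config re-validates to
    itself."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    known_top = {"seed", "stages", "simulate", "align", "sv", "ty", "genes", "input_dir"}
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unknown key {key!r}")
    stages = dict(_DEFAULTS["stages"])
    for key, value in (raw.get("stages") or {}).items():
        if key not in stages:
            raise ConfigError(f"unknown key stages.{key!r}")
        if not isinstance(value, bool):
            raise ConfigError(f"stages.{key} must be a boolean")
        stages[key] = value
    simulate_cfg = raw.get("simulate") or dict(_DEFAULTS["simulate"])
    input_dir = raw.get("input_dir")
    if input_dir is not None and stages.get("simulate", True):
        stages["simulate"] = False
    if input_dir is None and not stages["simulate"]:
        raise ConfigError("either the simulate stage or input_dir must provide inputs")
    if "preset" in simulate_cfg and simulate_cfg["preset"] not in PRESETS:
        raise ConfigError(f"unknown simulate.preset {simulate_cfg['preset']!r}")
    try:
        seed = int(raw.get("seed", _DEFAULTS["seed"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"seed must be an integer: {exc}") from exc
    return RunConfig(
        seed=seed,
        stages=stages,
        simulate=simulate_cfg,
        align=_merge_section("align", raw.get("align") or {}, _DEFAULTS["align"]),
        sv=_merge_section("sv", raw.get("sv") or {}, _DEFAULTS["sv"]),
        ty=_merge_section("ty", raw.get("ty") or {}, _DEFAULTS["ty"]),
        genes=_merge_section("genes", raw.get("genes") or {}, _DEFAULTS["genes"]),
        input_dir=input_dir,
    )


@dataclass
class RunReport:
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    version: str = __version__
    runtime_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "outputs": self.outputs,
                    "counts": self.counts,
                    "parameters": self.parameters,
                    "version": self.version,
                    "runtime_s": self.runtime_s,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _load_fixture_dir(fixture_dir: Path):
    manifest = json.loads((fixture_dir / "manifest.json").read_text())
    genomes: dict[str, Genome] = {}
    annotations = {}
    orf_catalogs = {}
    roles = {}
    for entry in manifest["strains"]:
        name = entry["name"]
        genomes[name] = Genome.from_fasta(fixture_dir / entry["genome"], name)
        annotations[name] = read_gff3(fixture_dir / entry["annotation"])
        orf_catalogs[name] = read_orf_fasta(fixture_dir / entry["orfs"])
        roles[name] = entry["role"]
    library = TyLibrary.read(fixture_dir / "ty_library.fa", fixture_dir / "ty_library.yaml")
    groups = read_ortholog_groups(fixture_dir / "ortholog_groups.tsv")
    return genomes, annotations, orf_catalogs, roles, library, groups


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute the enabled stages in dependency order, failing fast with a
    stage-named error. Writes ``report.json`` and a human-readable summary
    into ``outdir``."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=config.to_dict())
    logger.info("run started (seed=%d)", config.seed)

    # ---- simulate ----------------------------------------------------
    if config.stages["simulate"]:
        fixture_dir = outdir / "fixture"
        sim = dict(config.simulate)
        if "preset" in sim:
            sim_config = PRESETS[sim["preset"]](config.seed)
        elif "config" in sim:
            sim_config = config_from_yaml(sim["config"])
        else:
            raise ConfigError("simulate stage needs 'preset' or 'config'")
        logger.info("[simulate] seed=%d", sim_config.seed)
        manifest = emit_fixture(sim_config, fixture_dir)
        report.outputs["fixture"] = str(fixture_dir)
        report.counts["strains"] = len(manifest["strains"])
    else:
        if not config.input_dir:
            raise ConfigError("stage 'align' enabled but no upstream fixture available")
        fixture_dir = Path(config.input_dir)
    try:
        genomes, annotations, orf_catalogs, roles, library, groups = _load_fixture_dir(
            fixture_dir
        )
    except FileNotFoundError as exc:
        raise ConfigError(f"stage inputs missing under {fixture_dir}: {exc}") from exc
    strains = list(genomes)

    # ---- align -------------------------------------------------------
    if config.stages["align"]:
        align_dir = outdir / "align"
        align_dir.mkdir(exist_ok=True)
        n_blocks = 0
        from .seqalign import align_genomes

        for ref_name, qry_name in enumerate_pairs(strains):
            blocks = align_genomes(genomes[ref_name], genomes[qry_name], **config.align)
            n_blocks += len(blocks)
            write_paf(
                blocks,
                align_dir / f"{ref_name}__{qry_name}.paf",
                ref_lengths={c: len(s) for c, s in genomes[ref_name].chromosomes.items()},
                qry_lengths={c: len(s) for c, s in genomes[qry_name].chromosomes.items()},
            )
        report.outputs["align"] = str(align_dir)
        report.counts["alignment_blocks"] = n_blocks
        report.counts["pairwise_comparisons"] = len(enumerate_pairs(strains))
        logger.info("[align] %d blocks over %d pairs", n_blocks,
                    report.counts["pairwise_comparisons"])

    # ---- sv ----------------------------------------------------------
    if config.stages["sv"]:
        align_dir = outdir / "align"
        if not align_dir.is_dir():
            raise ConfigError("stage 'sv' enabled but no alignment outputs found")
        sv_dir = outdir / "sv"
        sv_dir.mkdir(exist_ok=True)
        rows = []
        n_sv = 0
        for ref_name, qry_name in enumerate_pairs(strains):
            blocks = read_paf(align_dir / f"{ref_name}__{qry_name}.paf")
            svs = call_svs(blocks, min_size=config.sv["min_size"])
            n_sv += len(svs)
            svs_to_frame(svs).to_csv(
                sv_dir / f"{ref_name}__{qry_name}.tsv", sep="\t", index=False
            )
            write_bedpe(svs, sv_dir / f"{ref_name}__{qry_name}.bedpe")
            row = {"ref": ref_name, "qry": qry_name}
            for t in ("DEL", "INS", "DUP", "INV", "TRA"):
                row[t] = sum(1 for e in svs if e.type == t)
            row["total"] = len(svs)
            rows.append(row)
        counts = pd.DataFrame(rows).set_index(["ref", "qry"])
        matrix = SVMatrix(strains=strains, counts=counts)
        counts.to_csv(sv_dir / "matrix.tsv", sep="\t")
        summarize_sv(matrix).to_csv(sv_dir / "summary.tsv", sep="\t")
        report.outputs["sv"] = str(sv_dir)
        report.counts["structural_variants"] = n_sv
        logger.info("[sv] %d events", n_sv)

    # ---- ty ----------------------------------------------------------
    if config.stages["ty"]:
        ty_dir = outdir / "ty"
        ty_dir.mkdir(exist_ok=True)
        per_strain = {}
        for strain in strains:
            elements = annotate_genome(
                genomes[strain],
                library,
                strain,
                min_identity=config.ty["min_identity"],
                min_part_fraction=config.ty["min_part_fraction"],
                pairing_window=config.ty["pairing_window"],
            )
            per_strain[strain] = elements
            elements_to_frame(elements).to_csv(
                ty_dir / f"{strain}.tsv", sep="\t", index=False
            )
            write_elements_gff3(elements, ty_dir / f"{strain}.gff3")
        ty_summary(per_strain).to_csv(ty_dir / "summary.tsv", sep="\t")
        report.outputs["ty"] = str(ty_dir)
        report.counts["ty_elements"] = sum(len(v) for v in per_strain.values())
        logger.info("[ty] %d elements", report.counts["ty_elements"])

    # ---- genes -------------------------------------------------------
    if config.stages["genes"]:
        genes_dir = outdir / "genes"
        genes_dir.mkdir(exist_ok=True)
        matrix = build_matrix(groups, strains, roles)
        matrix.cells.astype(int).to_csv(genes_dir / "presence_absence.tsv", sep="\t")
        focal = set(matrix.strains_with_role("focal"))
        losses = candidate_gene_losses(matrix) if focal and matrix.strains_with_role("outgroup") else []
        core_missing = missing_core_genes(matrix) if focal else []
        pd.Series(losses, name="gene_id").to_csv(
            genes_dir / "candidate_losses.tsv", sep="\t", index=False
        )
        pd.Series(core_missing, name="gene_id").to_csv(
            genes_dir / "missing_core.tsv", sep="\t", index=False
        )
        focal_list = sorted(focal)
        others = [
            s for s in strains
            if roles[s] == "other_conspecific" and s not in focal
        ]
        n_candidates = 0
        if focal_list and others:
            th = FilterThresholds(
                max_mean_identity=config.genes["max_mean_identity"],
                min_query_coverage=config.genes["min_query_coverage"],
                min_low_identity_fraction=config.genes["min_low_identity_fraction"],
            )
            cands = introgression_candidates(orf_catalogs, focal_list, others, th)
            frame = candidates_to_frame(cands)
            frame.to_csv(genes_dir / "introgression.tsv", sep="\t", index=False)
            with open(genes_dir / "introgression.json", "w") as fh:
                json.dump(frame.to_dict("records"), fh, indent=2)
            n_candidates = int(frame["overall_pass"].sum())
        content = {
            s: genome_content_summary(genomes[s], annotations[s]) for s in strains
        }
        pd.DataFrame(content).T.to_csv(genes_dir / "content_summary.tsv", sep="\t")
        report.outputs["genes"] = str(genes_dir)
        report.counts["candidate_gene_losses"] = len(losses)
        report.counts["missing_core_genes"] = len(core_missing)
        report.counts["introgression_candidates"] = n_candidates
        logger.info(
            "[genes] %d losses, %d missing core, %d introgression candidates",
            len(losses), len(core_missing), n_candidates,
        )

    report.runtime_s = round(time.time() - t_start, 3)
    report.to_json(outdir / "report.json")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"comparome {__version__} run (seed={config.seed})\n")
        for key, value in sorted(report.counts.items()):
            fh.write(f"{key}\t{value}\n")
    logger.info("run finished in %.1fs", report.runtime_s)
    return report
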