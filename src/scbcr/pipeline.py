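"""End-to-end pipeline: simulate or ingest -> annotate -> cells -> clones /
clonotypes -> statistics -> cross-cohort search, with a run manifest.

Each stage writes a TSV and reads its predecessor's TSV, so any stage can be
re-run from intermediate files.  All randomness flows from the single config
seed through named substreams; the manifest records the resolved parameters,
per-stage output files with row counts, and the germline set checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationParams, annotate_fasta
from .cells import COMPLETE, assemble_cells
from .clones import (
    cluster_clones, clonotype_table, find_common_clones, find_shared_clonotypes,
    search_cdr3,
)
from .germline import GermlineDatabase, default_germline_paths, read_germline_fasta
from .io import read_clonotype_table, read_rearrangement_tsv, write_rearrangement_tsv
from .simulate import PlantedClone, SimulationConfig, simulate_cohort, write_cohort
from .stats import (
    cdr3_length_distribution, gene_usage, light_chain_class_counts,
    mutation_rate_summary, vj_matrix,
)

logger = logging.getLogger(__name__)

INPUT_MODES = ("fasta", "rearrangement_tsv", "simulate")


@dataclass
class RunConfig:
    """Pipeline run configuration (one input mode, one seed)."""

    mode: str = "simulate"
    out_dir: str = "scbcr_run"
    seed: int = 0
    germline_fasta: str | None = None       # None -> bundled synthetic set
    germline_anchors: str | None = None
    fasta_paths: list[str] = field(default_factory=list)
    rearrangement_path: str | None = None
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    match_level: str = "allele"
    min_patients: int = 2
    usage_level: str = "family"
    control_tables: list[dict] = field(default_factory=list)  # {path, dialect}
    search_targets: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Return findings (field: reason); an empty list means runnable."""
    findings = []
    if config.mode not in INPUT_MODES:
        findings.append(f"mode: must be one of {INPUT_MODES}")
    provided = [
        bool(config.fasta_paths),
        config.rearrangement_path is not None,
        config.mode == "simulate",
    ]
    if config.mode == "fasta" and not config.fasta_paths:
        findings.append("fasta_paths: required in fasta mode")
    if config.mode == "rearrangement_tsv" and config.rearrangement_path is None:
        findings.append("rearrangement_path: required in rearrangement_tsv mode")
    if sum(provided) > 1:
        findings.append("mode: exactly one input mode may provide data")
    for path_attr in ("germline_fasta", "germline_anchors", "rearrangement_path"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            findings.append(f"{path_attr}: path does not exist: {p}")
    for p in config.fasta_paths:
        if not Path(p).exists():
            findings.append(f"fasta_paths: path does not exist: {p}")
    for entry in config.control_tables:
        if not Path(entry.get("path", "")).exists():
            findings.append(f"control_tables: path does not exist: {entry.get('path')}")
        if entry.get("dialect") not in ("airr", "mixcr-like"):
            findings.append(f"control_tables: unknown dialect {entry.get('dialect')!r}")
    if config.match_level not in ("allele", "gene"):
        findings.append(f"match_level: must be allele or gene, got {config.match_level!r}")
    if config.mode == "simulate" and config.simulation:
        sim = dict(config.simulation)
        sim.pop("planted_clones", None)
        try:
            sim_cfg = SimulationConfig(**sim)
        except TypeError as exc:
            findings.append(f"simulation: {exc}")
        else:
            for name in ("v_usage", "j_usage"):
                usage = getattr(sim_cfg, name)
                if usage:
                    for locus, vec in usage.items():
                        total = sum(vec.values())
                        if abs(total - 1.0) > 1e-9:
                            findings.append(
                                f"{name}[{locus}]: probabilities sum to {total}, not 1"
                            )
    return findings


def _load_germline(config: RunConfig) -> tuple[GermlineDatabase, str]:
    if config.germline_fasta is None:
        fasta, anchors = default_germline_paths()
    else:
        fasta = Path(config.germline_fasta)
        anchors = Path(config.germline_anchors or config.germline_fasta)
    db = GermlineDatabase(read_germline_fasta(fasta, anchors))
    checksum = hashlib.sha256(Path(fasta).read_bytes()).hexdigest()[:16]
    return db, checksum


def _build_simulation_config(config: RunConfig, seed: int) -> SimulationConfig:
    sim = dict(config.simulation)
    planted = [
        pc if isinstance(pc, PlantedClone) else PlantedClone(**pc)
        for pc in sim.pop("planted_clones", [])
    ]
    sim.setdefault("seed", seed)
    return SimulationConfig(planted_clones=planted, **sim)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid RunConfig: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "failed_stage": None,
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    def record_stage(name: str, files: dict[str, tuple[Path, int]]) -> None:
        manifest["stages"][name] = {
            k: {"path": str(p), "rows": n} for k, (p, n) in files.items()
        }

    try:
        db, checksum = _load_germline(config)
        manifest["germline_checksum"] = checksum

        # --- input stage -----------------------------------------------
        if config.mode == "simulate":
            sim_cfg = _build_simulation_config(config, int(seeds[0]))
            manifest["config"]["simulation_resolved"] = {
                k: v for k, v in asdict(sim_cfg).items() if k != "planted_clones"
            }
            cohort = simulate_cohort(sim_cfg, db)
            sim_dir = out / "simulation"
            paths = write_cohort(cohort, sim_cfg, sim_dir)
            fasta_paths = [paths[p] for p in sorted(paths) if p.startswith("PA")]
            record_stage("simulate", {
                "truth": (paths["truth"], len(cohort.chain_frame())),
            })
        else:
            fasta_paths = [Path(p) for p in config.fasta_paths]

        # --- annotation --------------------------------------------------
        rearr_path = out / "rearrangements.tsv"
        if config.mode == "rearrangement_tsv":
            records = read_rearrangement_tsv(config.rearrangement_path)
            write_rearrangement_tsv(records, rearr_path)
        else:
            records = []
            n_failed = 0
            for fasta in fasta_paths:
                recs, failed = annotate_fasta(fasta, db, AnnotationParams())
                records.extend(recs)
                n_failed += len(failed)
            write_rearrangement_tsv(records, rearr_path)
            manifest["unannotatable"] = n_failed
        record_stage("annotate", {"rearrangements": (rearr_path, len(records))})

        # --- cells -------------------------------------------------------
        records = read_rearrangement_tsv(rearr_path)
        cells = assemble_cells(records)
        cells_path = out / "cells.tsv"
        pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id, "cell_id": c.cell_id,
                    "n_heavy": c.n_heavy, "n_light": c.n_light,
                    "completeness": c.completeness,
                }
                for c in cells
            ]
        ).to_csv(cells_path, sep="\t", index=False)
        n_complete = sum(c.completeness == COMPLETE for c in cells)
        logger.info("cells: %d total, %d complete, %d incomplete",
                    len(cells), n_complete, len(cells) - n_complete)
        record_stage("cells", {"cells": (cells_path, len(cells))})

        # --- clones ------------------------------------------------------
        productive = [r for r in records if r.productive]
        heavy = [r for r in productive if r.locus == "IGH"]
        light = [r for r in productive if r.locus in ("IGK", "IGL")]
        stage_files = {}
        for label, recs in (("heavy", heavy), ("light", light)):
            clones = cluster_clones(recs, level=config.match_level)
            common = find_common_clones(clones, min_patients=config.min_patients)
            path = out / f"{label}_common_clones.tsv"
            common.to_csv(path, sep="\t", index=False)
            stage_files[f"{label}_common_clones"] = (path, len(common))
            all_path = out / f"{label}_clones.tsv"
            pd.DataFrame(
                [
                    {"clone_key": c.key_str(), "n_members": len(c.members),
                     "n_patients": len(c.patients)}
                    for c in clones
                ]
            ).to_csv(all_path, sep="\t", index=False)
            stage_files[f"{label}_clones"] = (all_path, len(clones))
        record_stage("clones", stage_files)

        # --- clonotypes ---------------------------------------------------
        clonotypes = find_shared_clonotypes(
            cells, min_patients=config.min_patients, level=config.match_level
        )
        ct_table = clonotype_table(clonotypes)
        ct_path = out / "clonotypes.tsv"
        ct_table.to_csv(ct_path, sep="\t", index=False)
        record_stage("clonotypes", {"clonotypes": (ct_path, len(ct_table))})

        # --- statistics ---------------------------------------------------
        stat_files = {}
        if heavy:
            for st in ("V", "D", "J"):
                table = gene_usage(heavy, st, level=config.usage_level)
                path = out / f"usage_{st}.tsv"
                table.to_frame().to_csv(path, sep="\t", index=False)
                stat_files[f"usage_{st}"] = (path, len(table.entries))
            mat = vj_matrix(heavy, level=config.match_level)
            path = out / "vj_matrix.tsv"
            mat.matrix.to_csv(path, sep="\t")
            stat_files["vj_matrix"] = (path, len(mat.matrix))
            dist = cdr3_length_distribution(heavy)
            path = out / "cdr3_lengths.tsv"
            pd.DataFrame(
                [{"length": k, "count": v} for k, v in dist.histogram.items()]
            ).to_csv(path, sep="\t", index=False)
            stat_files["cdr3_lengths"] = (path, len(dist.histogram))
            manifest["cdr3_length_modes"] = dist.modes
            manifest["cdr3_shapiro_p"] = dist.shapiro_p
            summary = mutation_rate_summary(heavy)
            path = out / "mutation_rates.tsv"
            pd.DataFrame({"rate": summary.rates}).to_csv(path, sep="\t", index=False)
            stat_files["mutation_rates"] = (path, len(summary.rates))
            manifest["mutation_rate_five_number"] = summary.five_number
        if light:
            lc = light_chain_class_counts(light)
            manifest["light_chain_counts"] = {
                "kappa": lc.kappa, "lambda": lc.lambda_, "p_value": lc.p_value,
            }
        record_stage("stats", stat_files)

        # --- cross-cohort search -------------------------------------------
        if config.search_targets and config.control_tables:
            rows = []
            for entry in config.control_tables:
                table = read_clonotype_table(entry["path"], entry["dialect"])
                for target in config.search_targets:
                    hits = search_cdr3(target, table, max_mismatch=0)
                    rows.append(
                        {"control": entry["path"], "target": target, "n_hits": len(hits)}
                    )
            path = out / "search_results.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            record_stage("search", {"search_results": (path, len(rows))})
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
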