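"""End-to-end orchestration: simulate, scan, call origins, score, contrast.

A single YAML-configurable entry point runs every stage on one seeded
synthetic dataset and writes a checksum manifest, so a full run is
reproducible from the config alone. Stage parameters default to the
package-wide conventions (MD radii r=150 / R=1500, MD significance alpha
1e-4, scan p-value 1e-5, caller defaults).
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import md as md_mod
from . import mnase as mnase_mod
from . import origins as origins_mod
from . import plots as plots_mod
from . import pwm as pwm_mod
from . import sn as sn_mod
from . import synthetic as synth_mod

logger = logging.getLogger("enhancerkit.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "scan": True,
        "call_origins": True,
        "md": True,
        "diff_md": True,
        "sn_compare": True,
        "mnase": True,
        "plots": True,
    },
    "simulate": {
        "genome_length": 60_000,
        "gc_fraction": 0.45,
        "n_origins": 12,
        "origin_min_spacing": 3000,
        "n_motif_instances": 300,
        "colocalized_fraction": 0.5,
        "placement_radius": 150,
        "reads_per_origin": 500,
        "read_offset_scale": 60.0,
        "noise_read_rate": 0.0002,
    },
    "scan": {
        "pvalue": 1e-5,
        "motifs_path": None,  # external MEME file overrides the generated one
    },
    "caller": {
        "min_reads": 20,
        "max_separation": 300,
        "smoothing_halfwidth": 30,
        "merge_distance": 150,
    },
    "md": {"r": 150, "R": 1500, "alpha": 1e-4, "n_bins": 100},
    "sn": {
        "n_nuclei_per_group": 400,
        "access_fold_change": 1.52,
        "expr_fold_change": 1.91,
        "baseline_access_rate": 0.25,
        "baseline_expr_mean": 4.0,
        "nb_dispersion": 0.5,
        "depth_log_mean": 7.5,
        "depth_log_sd": 0.4,
    },
    "mnase": {
        "profile": [1.0, 1.6, 2.6, 1.4, 0.45, 0.3, 0.5, 1.2, 2.2, 1.7],
        "noise_sd": 0.15,
        "n_replicates": 4,
        "reference": "amp01",
    },
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge_validated(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key != "stages":
            if not isinstance(value, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validated(defaults[key], value, path + key + ".")
        elif key == "stages":
            for stage in value:
                if stage not in defaults["stages"]:
                    raise ValueError(f"unknown stage {stage!r}")
            out["stages"].update(value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and/or an overrides dict; unknown keys
    are rejected."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        config = _merge_validated(config, loaded)
    if overrides:
        config = _merge_validated(config, overrides)
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _consensus_pwm(consensus: str, motif_id: str = "planted") -> pwm_mod.PositionWeightMatrix:
    """Near-deterministic PWM for a planted consensus (0.91 / 0.03 rows)."""
    probs = np.full((len(consensus), 4), 0.03)
    for i, base in enumerate(consensus):
        probs[i, pwm_mod.BASES.index(base)] = 0.91
    return pwm_mod.PositionWeightMatrix(motif_id, probs)


def run_demo(config: dict | None = None, outdir="demo_out") -> dict:
    """Run every enabled stage on one seeded synthetic dataset.

    Two motif-placement conditions are simulated: condition A with the
    configured co-localization and condition B with none (the null). The
    stages chain: simulate -> scan -> call-origins -> md -> diff-md ->
    sn-compare -> mnase, and a manifest of every written file with SHA-256
    checksums plus a JSON summary of the headline numbers is written at the
    end. Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config = config or load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    summary: dict = {"seed": seed}
    written: list[Path] = []
    state: dict = {}

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)

        return _Ctx()

    if stages["simulate"]:
        with stage("synthetic_data"):
            sim_a = synth_mod.SimulationConfig(seed=seed, **config["simulate"])
            sim_b = replace(sim_a, colocalized_fraction=0.0, seed=seed + 1)
            state["sims"] = {}
            for label, sim in (("A", sim_a), ("B", sim_b)):
                genome = synth_mod.simulate_genome(sim)
                origins_truth = synth_mod.place_origins(sim)
                truth, genome = synth_mod.plant_motifs(genome, origins_truth, sim)
                cov = synth_mod.simulate_nascent_coverage(origins_truth, sim)
                synth_mod.write_fasta(genome, emit(f"genome_{label}.fa"), name=sim.chrom)
                synth_mod.write_truth_bed(truth, emit(f"motif_truth_{label}.bed"))
                origins_mod.write_origins_audit(origins_truth, emit(f"origins_truth_{label}.tsv"))
                origins_mod.write_strand_coverage(
                    cov, emit(f"coverage_{label}_plus.bedGraph"), emit(f"coverage_{label}_minus.bedGraph")
                )
                synth_mod.write_chrom_sizes(cov.lengths, emit(f"chrom_{label}.sizes"))
                state["sims"][label] = {
                    "config": sim, "genome": genome, "origins_truth": origins_truth,
                    "truth": truth, "coverage": cov,
                }
            pwm = _consensus_pwm(sim_a.motif_consensus)
            pwm_mod.write_meme([pwm], emit("motifs.meme"))
            state["motifs_meme"] = outdir / "motifs.meme"
            with open(emit("config_used.yaml"), "w") as fh:
                yaml.safe_dump(config, fh, sort_keys=True)

    if stages["scan"]:
        with stage("pwm_scan"):
            motifs_path = config["scan"]["motifs_path"] or state["motifs_meme"]
            pwms = pwm_mod.read_meme(motifs_path)
            state["hits"] = {}
            for label, sim_state in state["sims"].items():
                genome = sim_state["genome"]
                chrom = sim_state["config"].chrom
                all_hits = []
                for pwm in pwms:
                    table = pwm_mod.log_odds(pwm)
                    thr = pwm_mod.threshold_from_pvalue(
                        table, pwm.background, config["scan"]["pvalue"]
                    )
                    all_hits.append(
                        pwm_mod.scan({chrom: genome}, table, thr, motif_id=pwm.motif_id)
                    )
                hits = all_hits[0] if len(all_hits) == 1 else pd.concat(all_hits, ignore_index=True)
                pwm_mod.write_hits_bed(hits, emit(f"hits_{label}.bed"))
                state["hits"][label] = hits
            summary["n_hits_A"] = int(len(state["hits"]["A"]))
            summary["n_hits_B"] = int(len(state["hits"]["B"]))

    if stages["call_origins"]:
        with stage("erna_caller"):
            state["called"] = {}
            for label, sim_state in state["sims"].items():
                called = origins_mod.call_origins(sim_state["coverage"], **config["caller"])
                origins_mod.write_origins_bed(called, emit(f"origins_called_{label}.bed"))
                origins_mod.write_origins_audit(called, emit(f"origins_called_{label}.tsv"))
                state["called"][label] = called
            summary["n_origins_A"] = int(len(state["called"]["A"]))
            summary["n_origins_B"] = int(len(state["called"]["B"]))

    if stages["md"]:
        with stage("md_score"):
            md_cfg = config["md"]
            state["md_tables"] = {}
            for label in state["sims"]:
                table = md_mod.md_table(
                    state["hits"][label], state["called"][label], r=md_cfg["r"], R=md_cfg["R"]
                )
                table.to_csv(emit(f"md_{label}.tsv"), sep="\t", index=False)
                state["md_tables"][label] = table
            dists = md_mod.motif_distances(
                state["hits"]["A"], state["called"]["A"], R=md_cfg["R"]
            )
            state["barcode"] = md_mod.barcode_matrix(
                dists["planted"], R=md_cfg["R"], n_bins=md_cfg["n_bins"], motif_id="planted"
            )
            md_mod.write_barcode_tsv(state["barcode"], emit("barcode_A.tsv"))
            summary["md_A"] = float(state["md_tables"]["A"]["md"].iloc[0])
            summary["md_B"] = float(state["md_tables"]["B"]["md"].iloc[0])

    if stages["diff_md"]:
        with stage("diff_md"):
            md_cfg = config["md"]
            diff = md_mod.diff_md_table(
                state["md_tables"]["A"], state["md_tables"]["B"],
                alpha=md_cfg["alpha"], r=md_cfg["r"], R=md_cfg["R"],
            )
            diff.to_csv(emit("diff_md.tsv"), sep="\t", index=False)
            summary["diff_md_z"] = float(diff["z"].iloc[0])
            summary["diff_md_p"] = float(diff["p"].iloc[0])
            summary["diff_md_significant"] = bool(diff["significant"].iloc[0])

    if stages["sn_compare"]:
        with stage("sn_compare"):
            ncfg = synth_mod.NucleusSimConfig(seed=seed, **config["sn"])
            table, truth = synth_mod.simulate_nucleus_table(ncfg)
            sn_mod.write_nucleus_table(table, emit("nucleus_table.tsv"))
            subset = sn_mod.select_nuclei(table, cell_types=[ncfg.cell_type])
            groups = list(ncfg.group_labels)
            access = sn_mod.diff_accessibility(
                subset, ncfg.access_feature, ncfg.group_variable, groups=groups
            )
            expr = sn_mod.diff_expression(
                subset, ncfg.expr_feature, ncfg.group_variable, groups=groups
            )
            results = sn_mod.adjust_bonferroni([access, expr])
            sn_mod.results_table(results).to_csv(emit("sn_results.tsv"), sep="\t", index=False)
            state["nucleus_table"] = table
            state["sn_config"] = ncfg
            summary["accessibility_fold_change"] = access.fold_change
            summary["accessibility_p_adj"] = access.p_adj
            summary["expression_fold_change"] = expr.fold_change
            summary["expression_p_adj"] = expr.p_adj

    if stages["mnase"]:
        with stage("mnase_profile"):
            mcfg = config["mnase"]
            ct = synth_mod.simulate_mnase_ct(
                mcfg["profile"], noise_sd=mcfg["noise_sd"], seed=seed,
                n_replicates=mcfg["n_replicates"],
            )
            mnase_mod.write_ct_table(ct, emit("mnase_ct.tsv"))
            protection = mnase_mod.relative_protection(ct, mcfg["reference"])
            protection.to_csv(emit("mnase_protection.tsv"), sep="\t", index=False)
            state["protection"] = protection
            summary["mnase_min_protection"] = float(protection["protection_mean"].min())
            summary["mnase_max_protection"] = float(protection["protection_mean"].max())

    if stages["plots"]:
        with stage("plots"):
            if "barcode" in state:
                plots_mod.barcode_plot(state["barcode"], emit("barcode_A.svg"))
            if "protection" in state:
                plots_mod.mnase_plot(state["protection"], emit("mnase_protection.svg"))
            if "nucleus_table" in state:
                ncfg = state["sn_config"]
                plots_mod.sn_dotplot(
                    state["nucleus_table"],
                    [ncfg.access_feature, ncfg.expr_feature],
                    emit("sn_dotplot.svg"),
                    group_variable=ncfg.group_variable,
                )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(outdir / "summary.json")
    manifest = {
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
        "stages_run": [name for name, on in stages.items() if on],
        "seed": seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"manifest": manifest, "summary": summary, "outdir": str(outdir)}
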