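"""End-to-end pipeline: simulate/load -> QC -> ssGREML -> weighted iterations
-> window scan -> annotation, with a reproducible run manifest.

Configuration is a single YAML file with sections ``simulate`` (omitted when
real files are supplied under ``io.inputs``), ``qc``, ``model``, ``wssgwas``
and ``io``.  All QC and scan thresholds default to the standard analysis
settings (MAF 0.01, individual call rate 0.90, 1-Mb windows, 1% selection)
and are overridable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomics import qc_filter, read_plink_text
from .mixed_model import PhenotypeTable, TraitModelSpec, VarianceComponents
from .pedigree import read_pedigree
from .simulate import SimConfig, simulate_herd, write_fixtures
from .wssgwas import (
    SELECT_THRESHOLD_PCT,
    WINDOW_BP,
    read_bed,
    annotate_windows,
    run_wssgblup,
    scan_windows,
    windows_to_frame,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "simulate": None,
    "qc": {"maf_min": 0.01, "ind_callrate_min": 0.90},
    "model": {"trait": "AFC", "blend_alpha": 0.05, "reml_tol": 1e-8},
    "wssgwas": {
        "n_iterations": 2,
        "window_bp": WINDOW_BP,
        "threshold_pct": SELECT_THRESHOLD_PCT,
    },
    "io": {"out_dir": "wssgwas_run", "inputs": None, "bed": None},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULT_CONFIG, user)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config_path=None, config: dict | None = None, seed: int | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Stages: simulate (skipped when ``io.inputs`` points at real files), QC,
    first-iteration single-step REML, weighted re-analyses, window scan,
    selection, optional BED annotation.
    """
    if config is None:
        config = load_config(config_path)
    else:
        config = _deep_update(DEFAULT_CONFIG, config)
    out_dir = Path(config["io"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "config": config, "stages": {}, "files": {}}

    inputs = config["io"].get("inputs")
    if inputs:
        ped = read_pedigree(inputs["pedigree"])
        from .pedigree import compute_inbreeding

        compute_inbreeding(ped)
        genotypes = read_plink_text(inputs["ped"], inputs["map"])
        trait = config["model"]["trait"]
        phenotypes = PhenotypeTable.read_csv(inputs["phenotypes"], trait=trait)
        manifest["stages"]["simulate"] = "skipped (real inputs)"
        in_files = {k: Path(v) for k, v in inputs.items()}
    else:
        sim_cfg = dict(config.get("simulate") or {})
        if seed is not None:
            sim_cfg["seed"] = seed
        if "founder_maf_range" in sim_cfg:
            sim_cfg["founder_maf_range"] = tuple(sim_cfg["founder_maf_range"])
        cfg = SimConfig(**sim_cfg)
        sim = simulate_herd(cfg)
        fixture_paths = write_fixtures(sim, out_dir / "simulated")
        ped = sim.ped
        genotypes = sim.genotypes
        phenotypes = sim.phenotypes
        manifest["stages"]["simulate"] = {
            "n_animals": ped.n,
            "n_genotyped": len(sim.genotyped_ids),
            "n_records": phenotypes.n_records,
            "seed": cfg.seed,
        }
        in_files = fixture_paths

    manifest["files"]["inputs"] = {k: str(p) for k, p in in_files.items()}
    manifest["input_hashes"] = {k: _hash_file(Path(p)) for k, p in in_files.items()}

    genotypes, qc_report = qc_filter(
        genotypes,
        maf_min=config["qc"]["maf_min"],
        ind_callrate_min=config["qc"]["ind_callrate_min"],
    )
    qc_path = out_dir / "qc_report.tsv"
    qc_report.to_frame().to_csv(qc_path, sep="\t", index=False)
    manifest["stages"]["qc"] = qc_report.to_frame().set_index("stage")["count"].to_dict()

    model_cfg = config["model"]
    spec = TraitModelSpec.for_trait(model_cfg["trait"])
    vc_fixed = None
    if model_cfg.get("variance_components"):
        v = model_cfg["variance_components"]
        vc_fixed = VarianceComponents(v["sigma2_a"], v.get("sigma2_hys", 0.0), v["sigma2_e"])
    from .mixed_model import SingleStepModel

    model = SingleStepModel(
        spec, phenotypes, ped, genotypes, blend_alpha=model_cfg["blend_alpha"]
    )
    history = run_wssgblup(
        spec,
        phenotypes,
        ped,
        genotypes,
        n_iterations=config["wssgwas"]["n_iterations"],
        vc=vc_fixed,
        blend_alpha=model_cfg["blend_alpha"],
        reml_tol=model_cfg["reml_tol"],
        model=model,
        verbose=model_cfg.get("verbose", False),
    )
    vc = history[0].vc
    comp_path = out_dir / "variance_components.json"
    with open(comp_path, "w") as fh:
        json.dump(vc.to_dict(), fh, indent=1)

    final = history[-1]
    # window scan on the final iteration's effects over genotyped animals
    results, selected = scan_windows(
        model.Z_centered,
        final.effects,
        genotypes,
        vc.sigma2_a,
        span_bp=config["wssgwas"]["window_bp"],
        threshold_pct=config["wssgwas"]["threshold_pct"],
    )
    windows_df = windows_to_frame(results)
    windows_path = out_dir / "windows.tsv"
    windows_df.to_csv(windows_path, sep="\t", index=False)
    selected_df = windows_to_frame(selected)
    selected_path = out_dir / "selected_windows.tsv"
    selected_df.to_csv(selected_path, sep="\t", index=False)
    manhattan_path = out_dir / "manhattan.tsv"
    windows_df.sort_values(["chrom", "start_bp"]).to_csv(manhattan_path, sep="\t", index=False)

    manifest["stages"]["wssgwas"] = {
        "iterations": [
            {
                "iteration": h.iteration,
                "h2": h.vc.h2,
                "max_weight": float(h.weights.d.max()),
            }
            for h in history
        ],
        "top_windows": windows_df.nsmallest(10, "rank").to_dict("records"),
        "n_selected": len(selected),
    }

    bed_path = config["io"].get("bed")
    if bed_path:
        annot = annotate_windows(selected, read_bed(bed_path))
        annot_path = out_dir / "annotated_windows.tsv"
        annot.to_csv(annot_path, sep="\t", index=False)
        manifest["files"]["annotated_windows"] = str(annot_path)

    for name, p in [
        ("qc_report", qc_path),
        ("variance_components", comp_path),
        ("windows", windows_path),
        ("selected_windows", selected_path),
        ("manhattan", manhattan_path),
    ]:
        manifest["files"][name] = str(p)
    manifest["output_hashes"] = {
        name: _hash_file(Path(p))
        for name, p in manifest["files"].items()
        if name != "inputs" and Path(p).is_file()
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
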