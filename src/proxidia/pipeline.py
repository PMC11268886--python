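"""Config-driven end-to-end runs with a reproducible manifest.

A run config is a plain mapping (usually YAML) with either real input
paths or a ``synthetic`` block, the module parameters, an output
directory and one seed.  All stochastic steps (simulation, imputation)
derive their generators from that seed, and the manifest written with
the bundle suffices to replay the run exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .containers import ValidationError
from .model import ProximityEnrichmentModel
from .preprocess import ImputationParams
from .rollup import ThresholdParams
from .simulate import (
    ProteomicsSimConfig,
    design_for,
    simulate_peptide_report,
    simulate_phospho_sites,
    simulate_pssms,
)

#: every parameter default in one place (the published analysis settings)
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "proxidia_run",
    "inputs": {},          # report, design, edges, pssms, background, annotation
    "synthetic": None,     # ProteomicsSimConfig overrides, or {} for defaults
    "imputation": {},      # ImputationParams overrides
    "normalize": {"trim_fraction": 0.10},
    "thresholds": {"fc_threshold": 1.5, "q_threshold": 0.05},
    "network": {"score_cutoff": 0.7, "bait": "Rac1", "include_bait_edges": True},
    "kinase": {"percentile_cutoff": 90.0},
    "fc_mode": "linear_means",
}


def load_config(source: str | Path | Mapping) -> dict:
    """Load and merge a run config over the defaults."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    if not config["inputs"].get("report") and config["synthetic"] is None:
        raise ValidationError(
            "config needs either inputs.report/inputs.design or a "
            "'synthetic' block"
        )
    return config


def run_pipeline(config: str | Path | Mapping) -> Path:
    """Execute the full pipeline and write the results bundle.

    Returns the output directory.  With a fixed seed the bundle is
    byte-identical across runs.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    sites = None
    pssms = background = None
    truth = None
    if cfg["synthetic"] is not None:
        sim_kwargs = dict(cfg["synthetic"])
        for key in ("peptides_per_protein", "charge_states", "group_labels"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_kwargs.setdefault("seed", seed)
        sim_config = ProteomicsSimConfig(**sim_kwargs)
        matrix, truth = simulate_peptide_report(sim_config)
        design = design_for(sim_config)
        pio.write_peptide_report(matrix, out / "peptide_report.tsv")
        pio.write_design(design, out / "design.tsv")
        pio.write_results(truth, out / "truth.tsv")
        sites = simulate_phospho_sites(matrix, seed=seed + 1)
        raw_pssms, background = simulate_pssms(seed=seed + 2)
        pssms = raw_pssms
    else:
        inputs = cfg["inputs"]
        for key in ("report", "design"):
            if not inputs.get(key):
                raise ValidationError(f"inputs.{key} is required")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(
                    f"inputs.{key} not found: {inputs[key]}"
                )
        matrix = pio.read_peptide_report(
            inputs["report"], columns=inputs.get("columns")
        )
        design = pio.read_design(
            inputs["design"], inputs.get("experimental"), inputs.get("control")
        )
        if inputs.get("pssms"):
            pssms = pio.read_pssms(inputs["pssms"])
        if inputs.get("background"):
            background = pio.read_background_windows(inputs["background"])
        if inputs.get("sites"):
            sites = pio.read_results(inputs["sites"])

    annotation = None
    if cfg["inputs"].get("annotation"):
        annotation = pio.read_results(cfg["inputs"]["annotation"])

    imp_kwargs = dict(cfg["imputation"])
    imp_kwargs.setdefault("seed", seed + 10)
    model = ProximityEnrichmentModel(
        matrix,
        design,
        imputation=ImputationParams(**imp_kwargs),
        thresholds=ThresholdParams(**cfg["thresholds"]),
        trim_fraction=cfg["normalize"]["trim_fraction"],
        annotation=annotation,
        fc_mode=cfg["fc_mode"],
    )
    results = model.fit()
    results.to_directory(out)

    # network
    external = None
    if cfg["inputs"].get("edges"):
        external = pio.read_edge_table(cfg["inputs"]["edges"])
    net_cfg = cfg["network"]
    graph, nodes, _ = results.build_network(
        external,
        score_cutoff=net_cfg["score_cutoff"],
        bait=net_cfg["bait"],
        include_bait_edges=net_cfg["include_bait_edges"],
    )
    pio.write_network_sif(graph, out / "network.sif")
    pio.write_network_graphml(graph, out / "network.graphml")
    if len(nodes):
        pio.write_results(nodes, out / "network_nodes.tsv")

    # phosphopeptide chain + kinase gate
    phospho = results.phospho_peptide_results()
    chain = results.phospho_chain(phospho)
    pio.write_results(chain.all_peptides, out / "phospho_all.tsv")
    pio.write_results(chain.enriched_peptides, out / "phospho_enriched.tsv")
    pio.write_results(
        chain.biotinylated_protein_peptides, out / "phospho_high_confidence.tsv"
    )
    stage_sets = {
        "phospho_total": chain.counts[0],
        "phospho_enriched": chain.counts[1],
        "phospho_biotinylated_protein": chain.counts[2],
    }
    if sites is not None and pssms:
        keep = sites["sequence"].isin(
            set(chain.biotinylated_protein_peptides.get("sequence", []))
        )
        gated = results.kinase_pairs(
            sites.loc[keep],
            pssms,
            background=background,
            percentile_cutoff=cfg["kinase"]["percentile_cutoff"],
        )
        pio.write_results(gated, out / "kinase_pairs.tsv")
        stage_sets["kinase_pairs"] = len(gated)

    manifest_cfg = dict(cfg)
    manifest_cfg["output_dir"] = ""  # replay may choose its own directory
    manifest = {
        "package": "proxidia",
        "version": __version__,
        "seed": seed,
        "config": manifest_cfg,
        "stage_counts": results.stage_counts,
        "imputation_counts": results.imputation_counts,
        "phospho_counts": stage_sets,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
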