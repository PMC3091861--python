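"""End-to-end orchestration of the analysis workflow.

``run_all`` takes one panel (a CSV on disk or a synthetic configuration) and
runs every stage on it — univariate screening, logistic discrimination,
hierarchical clustering, PCA driver scoring, and DyNA — writing each stage's
tables under an output directory together with a provenance manifest
(package version, seed, configuration hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import cluster_panel
from .discriminate import fit_pair_model, hypergeometric_null, rank_single_mediators
from .dyna import dyna_series, export_network, window_label
from .errors import DynacytError
from .panel import MediatorPanel, load_panel, validate_panel
from .pca import pca_driver_scores
from .simulate import SyntheticConfig, generate_panel, study_mimic_config
from .univariate import percent_modulated, t_difference_table

log = logging.getLogger("dynacyt")


@dataclass
class RunConfig:
    """Everything a full run depends on; hashed into output provenance."""

    input_csv: str | None = None  # mutually exclusive with synthetic
    synthetic: str | None = "study_mimic"  # preset name or config YAML path
    alpha: float = 0.05
    r_threshold: float = 0.7
    pca_top_k: int = 3
    linkage: str = "average"
    split: str = "all_data"
    pair: tuple[str, str] = ("IL-12.total", "MIG")
    out_dir: str = "dynacyt_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _load_input(config: RunConfig) -> MediatorPanel:
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise DynacytError(f"input file not found: {path}")
        return load_panel(path)
    if config.synthetic == "study_mimic":
        syn = study_mimic_config(seed=config.seed)
    elif config.synthetic is not None and Path(config.synthetic).exists():
        syn = SyntheticConfig.from_yaml(config.synthetic)
    else:
        raise DynacytError(f"no input: {config.synthetic!r} is not a preset or file")
    panel, _ = generate_panel(syn, seed=config.seed)
    return panel


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest written to the output dir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        panel = _load_input(config)
        panel.write_csv(out / "panel.csv")
        report = validate_panel(panel)
        (out / "validation.json").write_text(
            json.dumps([dataclasses.asdict(v) for v in report], indent=2)
        )

        stage = "univariate"
        log.info("univariate screening")
        tdiff = t_difference_table(panel)
        tdiff.summary().to_csv(out / "t_difference.csv")
        pm = percent_modulated(panel, config.alpha)
        pm.to_csv(out / "percent_modulated.csv", index=False)

        stage = "discriminant"
        log.info("logistic discrimination")
        ranking = rank_single_mediators(panel)
        ranking.to_csv(out / "mediator_ranking.csv", index=False)
        fit, cls = fit_pair_model(
            panel, *config.pair, split=config.split, seed=config.seed
        )
        cls.frame.to_csv(out / "pair_model_predictions.csv")
        null = hypergeometric_null(cls.n_samples // 2)
        (out / "pair_model.json").write_text(
            json.dumps(
                {
                    "predictors": list(config.pair),
                    "coefficients": fit.coef.to_dict(),
                    "coefficient_p": fit.p.to_dict(),
                    "n_correct": cls.n_correct,
                    "n_samples": cls.n_samples,
                    "success_ratio": cls.success_ratio,
                    "null_expected_correct": null.expected_correct,
                    "null_tail_p": null.tail(cls.n_correct),
                },
                indent=2,
            )
        )

        stage = "cluster"
        log.info("hierarchical clustering")
        tree, groups, (chi2, dof, p, table) = cluster_panel(panel, config.linkage)
        (out / "cluster_tree.nwk").write_text(tree.to_newick())
        groups.labels.rename("group").to_csv(out / "cluster_groups.csv")
        (out / "cluster_chi2.json").write_text(
            json.dumps(
                {
                    "chi2": chi2,
                    "df": dof,
                    "p": p,
                    "contingency": table.to_dict(),
                },
                indent=2,
            )
        )

        stage = "pca"
        log.info("PCA driver scores")
        for proc in ("ST", "ST_HS"):
            _, drivers = pca_driver_scores(panel, proc, k=config.pca_top_k)
            drivers.scores.rename("score").to_csv(out / f"pca_scores_{proc}.csv")

        stage = "dyna"
        log.info("dynamic network analysis")
        traj_parts = []
        for proc in ("ST", "ST_HS"):
            nets, traj = dyna_series(panel, proc, config.r_threshold, config.alpha)
            traj_parts.append(traj)
            for net in nets:
                tag = window_label(net.window).replace(" ", "").replace("-", "to")
                export_network(net, out / f"dyna_{proc}_{tag}.tsv")
        pd.concat(traj_parts, ignore_index=True).to_csv(
            out / "dyna_density.csv", index=False
        )
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.error("run failed during stage %s", stage)
        raise

    manifest = {
        "package": "dynacyt",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": ["univariate", "discriminant", "cluster", "pca", "dyna"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
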