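"""End-to-end orchestration: simulate -> indices -> composite -> screen ->
fit -> evaluate, with a manifest for reproducibility.

Every stage writes its artifact as CSV/JSON into the run directory and
never mutates an upstream file, so stages can be rerun independently.
All randomness derives from one master seed expanded per stage by a
stable hash of the stage name.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composite import build_composite
from .evaluation import EvalReport, score_predictions, split_data
from .models import MODEL_NAMES, ModelConfig, fit_model, predict
from .screening import PAPER_PROTOCOL_INDICES, correlation_report, select_indices
from .synthetic_data import SyntheticConfig, generate_plots, read_plot_table, write_plot_table
from .vegindex import compute_all
from .woa import WOAConfig, woa_bpnn

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Expand the master seed per stage; stable across runs and platforms."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Run-level configuration for the full inversion pipeline."""

    out_dir: str | Path = "cgmi_run"
    seed: int = 0
    input_table: str | Path | None = None  # None -> simulate
    n_plots: int = 66
    formulas: str = "literature"
    weighting: str = "both"
    target: str = "CGMI2"
    screen: bool = True
    selection_k: int = 5
    selection_alpha: float = 0.01
    paper_protocol: bool = False  # fix inputs to the five canonical indices
    models: tuple[str, ...] = MODEL_NAMES + ("WOA-BPNN",)
    n_train: int = 52
    woa_pop: int = 10
    woa_iterations: int = 60

    def config_hash(self) -> str:
        doc = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute all stages, write artifacts + manifest, return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # --- simulate | ingest -------------------------------------------------
    if config.input_table is None:
        plots = generate_plots(
            SyntheticConfig(n_plots=config.n_plots, seed=stage_seed(config.seed, "simulate"))
        )
    else:
        plots = read_plot_table(config.input_table)
    write_plot_table(plots, out / "plots.csv")

    # --- vegetation indices ------------------------------------------------
    indices = compute_all(plots, formulas=config.formulas)
    indices.to_csv(out / "indices.csv", index=False)

    # --- composite growth index --------------------------------------------
    table, weights, bounds = build_composite(plots, weighting="both")
    table.to_csv(out / "cgmi.csv", index=False)
    (out / "cgmi_weights.json").write_text(
        json.dumps(
            {
                "weights": dict(zip(("spad", "ph", "lai", "agb"), weights.weights)),
                "cv": dict(zip(("spad", "ph", "lai", "agb"), weights.cv)),
                "bounds": bounds,
            },
            indent=2,
        )
    )

    # --- screening ----------------------------------------------------------
    growth = plots[["plot_id", "spad", "ph", "lai", "agb"]].merge(
        table[["plot_id", "CGMI1", "CGMI2"]], on="plot_id"
    )
    report_corr = correlation_report(indices, growth)
    report_corr.to_long().to_csv(out / "correlations.csv", index=False)
    if config.paper_protocol:
        selected = list(PAPER_PROTOCOL_INDICES)
    elif config.screen:
        selected = select_indices(
            report_corr, target=config.target, k=config.selection_k,
            alpha=config.selection_alpha,
        )
    else:
        selected = list(indices.columns[1:])
        notes.append("screening disabled: all 12 indices used as model inputs")
    (out / "selected_indices.json").write_text(json.dumps(selected, indent=2))

    # --- fit + evaluate ------------------------------------------------------
    X = indices[selected].to_numpy(dtype=float)
    y = table[config.target].to_numpy(dtype=float)
    split_s = stage_seed(config.seed, "split")
    train_ids, test_ids = split_data(len(y), config.n_train, split_s)
    report = EvalReport(
        n_train=len(train_ids), n_test=len(test_ids), seed=config.seed,
        target=config.target,
    )
    fit_s = stage_seed(config.seed, "fit")
    for name in config.models:
        if name == "WOA-BPNN":
            model, _ = woa_bpnn(
                X[train_ids], y[train_ids],
                woa_config=WOAConfig(
                    pop=config.woa_pop, iterations=config.woa_iterations, seed=fit_s
                ),
                bpnn_config=ModelConfig("BPNN", seed=fit_s),
            )
        else:
            model = fit_model(name, X[train_ids], y[train_ids], ModelConfig(name, seed=fit_s))
        for subset, ids in (("train", train_ids), ("test", test_ids)):
            report.add(name, subset, score_predictions(predict(model, X[ids]), y[ids], strict=False))

    frame = report.to_frame()
    frame.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    report.summary().to_csv(out / "summary.csv")

    manifest = {
        "version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_hash": config.config_hash(),
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("simulate", "split", "fit")
        },
        "selected_indices": selected,
        "notes": notes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
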