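"""End-to-end orchestration: data -> QC -> GRM -> CV1 -> models -> report.

Runs the six-way experiment (GBLUP / UDL / MTDL, each with and without the
genotype x environment term) over CV1 partitions and collects per-cell
predictions into a :class:`~mtgp.evaluation.PredictionReport`.  All
randomness derives from one master seed through a stable hash, so a run is
reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deep import (
    EncodedInputs,
    HyperGrid,
    NetworkSpec,
    encode_features,
    grid_search,
    predict_network,
    train_network,
)
from .evaluation import CVPartition, PredictionReport, cv1_partition, summarize
from .gblup import GBLUPSpec, build_design_matrices, fit_gblup, predict_gblup
from .genotypes import GRM, MarkerMatrix, cholesky_factor, compute_grm, impute_missing, qc_markers
from .simulate import SimulationConfig, make_incomplete_design, simulate_markers, simulate_phenotypes

__all__ = ["RunConfig", "run_experiment", "derive_seed", "DESK_GRID", "PAPER_GRID"]

logger = logging.getLogger(__name__)

# Desk-scale grid: runs in minutes; the full study-size grid (10 x 200 x 3
# = 6,000 combinations) is available as PAPER_GRID.
DESK_GRID = HyperGrid(units_values=(20, 60, 100), epoch_values=tuple(range(1, 51)),
                      layer_values=(1, 2))
PAPER_GRID = HyperGrid()

MODELS = ("GBLUP", "UDL", "MTDL")
MODES = ("I", "WI")


def derive_seed(master: int, *tokens) -> int:
    """Stable child seed below 2^31 from a master seed and context tokens."""
    key = "|".join([str(master), *map(str, tokens)])
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    simulation: SimulationConfig | None = None
    genotype_csv: str | None = None
    phenotype_csv: str | None = None
    models: tuple[str, ...] = MODELS
    interaction_modes: tuple[str, ...] = MODES
    p_testing: float = 0.20
    n_partitions: int = 5
    seed: int = 0
    center_grm: bool = True
    gblup: GBLUPSpec = field(default_factory=GBLUPSpec)
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(dropout_rate=0.30))
    grid: HyperGrid = field(default_factory=lambda: DESK_GRID)
    grid_validation_fraction: float = 0.2
    output_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.models) - set(MODELS)
        if bad or not self.models:
            raise ValueError(f"models must be a non-empty subset of {MODELS}")
        bad = set(self.interaction_modes) - set(MODES)
        if bad or not self.interaction_modes:
            raise ValueError(f"interaction_modes must be a non-empty subset of {MODES}")
        if self.simulation is None and (self.genotype_csv is None or self.phenotype_csv is None):
            raise ValueError("provide either a simulation block or genotype+phenotype paths")


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = replace(config.simulation, seed=derive_seed(config.seed, "simulation"))
        markers = simulate_markers(sim)
        markers_qc = impute_missing(qc_markers(markers))
        grm = compute_grm(markers_qc, center=config.center_grm)
        design = make_incomplete_design(sim)
        pheno, effects = simulate_phenotypes(design, grm, sim)
        return markers_qc, grm, pheno, effects
    markers = MarkerMatrix.from_csv(config.genotype_csv)
    markers_qc = impute_missing(qc_markers(markers))
    grm = compute_grm(markers_qc, center=config.center_grm)
    pheno = pd.read_csv(config.phenotype_csv)
    return markers_qc, grm, pheno, None


def _cells_frame(cells, trait_wide: pd.DataFrame) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(cells, names=["line", "environment"])
    return trait_wide.reindex(idx)


def _run_gblup(pheno, grm, partition, interaction, config, records):
    traits = sorted(pheno["trait"].unique())
    env_ids = sorted(pheno["environment"].unique())
    train_cells = set(partition.train_cells)
    key = pheno.set_index(["line", "environment"])
    for trait in traits:
        sub = pheno[pheno["trait"] == trait]
        mask = [tuple(c) in train_cells for c in sub[["line", "environment"]].itertuples(index=False)]
        train = sub[np.asarray(mask)]
        spec = replace(
            config.gblup,
            include_interaction=(interaction == "I"),
            seed=derive_seed(config.seed, "gblup", partition.partition_id, interaction, trait),
        )
        fit = fit_gblup(train, grm, spec, env_ids=env_ids)
        preds = predict_gblup(fit, partition.test_cells)
        obs = sub.set_index(["line", "environment"])["value"]
        for cell, yhat in zip(partition.test_cells, preds):
            if cell in obs.index:
                records.append({
                    "partition": partition.partition_id, "model": "GBLUP",
                    "interaction": interaction, "trait": trait,
                    "line": cell[0], "environment": cell[1],
                    "observed": float(obs.loc[cell]), "predicted": float(yhat),
                })


def _run_deep(pheno, factor, partition, interaction, config, records, multi_trait: bool):
    model_name = "MTDL" if multi_trait else "UDL"
    traits = sorted(pheno["trait"].unique())
    wide = pheno.pivot_table(index=["line", "environment"], columns="trait",
                             values="value", aggfunc="mean")[traits]
    line_ids = factor.line_ids
    env_ids = sorted(pheno["environment"].unique())

    train_tbl = _cells_frame(partition.train_cells, wide).reset_index()
    test_tbl = _cells_frame(partition.test_cells, wide).reset_index()
    both = pd.concat([train_tbl, test_tbl], ignore_index=True)
    Z_E, Z_G, Z_GE = build_design_matrices(both, line_ids=line_ids, env_ids=env_ids)
    enc = encode_features(Z_E, Z_G, Z_GE, factor,
                          include_interaction=(interaction == "I"))
    n_train = len(train_tbl)
    X_train, X_test = enc.X[:n_train], enc.X[n_train:]

    target_sets = [traits] if multi_trait else [[t] for t in traits]
    for tset in target_sets:
        Y_train = train_tbl[tset].to_numpy(dtype=float)
        seed = derive_seed(config.seed, model_name, partition.partition_id, interaction, *tset)
        template = replace(config.network, n_outputs=len(tset), seed=seed)
        best_spec, _scores = grid_search(
            X_train, Y_train, config.grid, template,
            validation_fraction=config.grid_validation_fraction,
        )
        model = train_network(X_train, Y_train, best_spec)
        preds = predict_network(model, X_test)
        for t_i, trait in enumerate(tset):
            obs_col = test_tbl[trait].to_numpy(dtype=float)
            for r, cell in enumerate(partition.test_cells):
                if np.isfinite(obs_col[r]):
                    records.append({
                        "partition": partition.partition_id, "model": model_name,
                        "interaction": interaction, "trait": trait,
                        "line": cell[0], "environment": cell[1],
                        "observed": float(obs_col[r]), "predicted": float(preds[r, t_i]),
                    })


def run_experiment(config: RunConfig) -> PredictionReport:
    """Execute the configured experiment and return the prediction report."""
    t0 = time.time()
    markers, grm, pheno, effects = _load_inputs(config)
    factor = cholesky_factor(grm)
    logger.info("data ready: %d lines, %d markers post-QC, %d records (%.1fs)",
                grm.n_lines, markers.n_markers, len(pheno), time.time() - t0)

    partitions = cv1_partition(
        pheno, p_testing=config.p_testing, n_partitions=config.n_partitions,
        seed=derive_seed(config.seed, "cv1"),
    )
    records: list[dict] = []
    failures: list[dict] = []
    for partition in partitions:
        for interaction in config.interaction_modes:
            for model in config.models:
                t1 = time.time()
                try:
                    if model == "GBLUP":
                        _run_gblup(pheno, grm, partition, interaction, config, records)
                    else:
                        _run_deep(pheno, factor, partition, interaction, config, records,
                                  multi_trait=(model == "MTDL"))
                except Exception as exc:  # partial failure: record, keep going
                    logger.error("%s/%s partition %d failed: %s",
                                 model, interaction, partition.partition_id, exc)
                    failures.append({"model": model, "interaction": interaction,
                                     "partition": partition.partition_id, "error": str(exc)})
                else:
                    logger.info("%s/%s partition %d done (%.1fs)",
                                model, interaction, partition.partition_id, time.time() - t1)

    report = summarize(pd.DataFrame.from_records(records))
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "models": list(config.models),
            "interaction_modes": list(config.interaction_modes),
            "n_partitions": config.n_partitions,
            "p_testing": config.p_testing,
            "config_hash": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "failures": failures,
            "wall_time_s": round(time.time() - t0, 1),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if effects is not None:
            effects.to_csv(out / "true_effects.csv")
        markers.to_csv(out / "markers_qc.csv")
        grm.to_csv(out / "grm.csv")
        pheno.to_csv(out / "phenotypes.csv", index=False)
    if failures:
        logger.warning("%d model runs failed; see manifest", len(failures))
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
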