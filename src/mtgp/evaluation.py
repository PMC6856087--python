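"""CV1 cross-validation and the MAAPE prediction-error metric.

CV1 mimics the incomplete-trial prediction problem: random observed
(line, environment) cells are hidden, so every tested line keeps phenotypes
in other environments.  Each partition hides 20% of the observed cells by
drawing a line (without replacement when the number of lines exceeds the
target cell count, with replacement otherwise) and then one of that line's
observed environments; collisions are redrawn so the test set is a set of
distinct cells, and every environment keeps at least one training record.

Prediction error is summarized with MAAPE, the mean arctangent absolute
percentage error mean_i arctan(|(y_i - yhat_i) / y_i|) — scale-free,
bounded in [0, pi/2], and defined at zero observations (a zero observed
value with a nonzero prediction contributes pi/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CVPartition", "PredictionReport", "cv1_partition", "maape", "summarize"]

logger = logging.getLogger(__name__)

Cell = tuple[str, str]  # (line, environment)


@dataclass
class CVPartition:
    """One train/test split over the observed cells."""

    partition_id: int
    test_cells: list[Cell]
    train_cells: list[Cell]


def _observed_cells(pheno: pd.DataFrame) -> list[Cell]:
    cells = pheno[["line", "environment"]].drop_duplicates()
    return list(map(tuple, cells.itertuples(index=False)))


def cv1_partition(
    pheno: pd.DataFrame,
    p_testing: float = 0.20,
    n_partitions: int = 5,
    seed: int = 0,
    max_tries: int = 100_000,
) -> list[CVPartition]:
    """Random CV1 partitions over the observed (line, environment) cells.

    Each partition's test set holds ``round(p_testing * N)`` distinct cells,
    N being the number of observed cells.  Partitions are drawn
    independently, so a cell can be tested in several partitions.
    """
    if not 0.0 < p_testing < 1.0:
        raise ValueError("p_testing must be in (0, 1)")
    cells = _observed_cells(pheno)
    N = len(cells)
    target = int(np.floor(p_testing * N + 0.5))
    if target >= N:
        raise ValueError(f"test target {target} leaves no training cells")
    lines = sorted({c[0] for c in cells})
    J = len(lines)
    envs_of_line = {l: [] for l in lines}
    cells_per_env: dict[str, int] = {}
    for l, e in cells:
        envs_of_line[l].append(e)
        cells_per_env[e] = cells_per_env.get(e, 0) + 1
    rng = np.random.default_rng(seed)

    partitions = []
    for pid in range(1, n_partitions + 1):
        test: set[Cell] = set()
        in_test_per_env: dict[str, int] = {e: 0 for e in cells_per_env}

        def admissible(cell: Cell) -> bool:
            # keep >= 1 training record per environment
            return (
                cell not in test
                and in_test_per_env[cell[1]] + 1 < cells_per_env[cell[1]]
            )

        if J >= target:
            # sample lines without replacement
            order = rng.permutation(J)
            for j in order:
                if len(test) == target:
                    break
                line = lines[j]
                env_pool = list(envs_of_line[line])
                rng.shuffle(env_pool)
                env = env_pool[int(rng.integers(len(env_pool)))]
                cell = (line, env)
                if not admissible(cell):
                    cell = next(((line, e) for e in env_pool if admissible((line, e))), None)
                    if cell is None:
                        logger.debug("partition %d: line %s skipped (no admissible env)", pid, line)
                        continue
                test.add(cell)
                in_test_per_env[cell[1]] += 1
        else:
            # with replacement at the line level; cell collisions are redrawn
            tries = 0
            while len(test) < target:
                tries += 1
                if tries > max_tries:
                    raise ValueError(
                        f"could not reach {target} distinct admissible test cells"
                    )
                line = lines[int(rng.integers(J))]
                env_list = envs_of_line[line]
                env = env_list[int(rng.integers(len(env_list)))]
                cell = (line, env)
                if admissible(cell):
                    test.add(cell)
                    in_test_per_env[env] += 1
                elif cell in test:
                    logger.debug("partition %d: duplicate cell %s redrawn", pid, cell)
        if len(test) < target:
            raise ValueError(
                f"partition {pid}: only {len(test)} of {target} test cells reachable"
            )
        train = [c for c in cells if c not in test]
        test_list = sorted(test)
        partitions.append(CVPartition(pid, test_list, train))
    return partitions


def maape(observed, predicted) -> float:
    """Mean arctangent absolute percentage error, in [0, pi/2]."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(y) == 0:
        raise ValueError("empty vectors")
    terms = np.empty(len(y))
    zero = y == 0
    terms[zero] = np.where(yhat[zero] == 0, 0.0, np.pi / 2)
    nz = ~zero
    terms[nz] = np.arctan(np.abs((y[nz] - yhat[nz]) / y[nz]))
    return float(terms.mean())


@dataclass
class PredictionReport:
    """Observed-vs-predicted records with MAAPE summaries.

    ``per_env_maape`` has one row per (model, interaction, trait,
    environment) with the MAAPE averaged over partitions; ``summaries``
    aggregates across environments; ``winner_counts`` tallies, per
    (interaction, trait), the environments in which each model achieved the
    lowest MAAPE.
    """

    records: pd.DataFrame
    per_env_maape: pd.DataFrame
    summaries: pd.DataFrame
    winner_counts: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "predictions.csv", index=False)
        self.per_env_maape.to_csv(out / "maape_per_environment.csv", index=False)
        self.summaries.to_csv(out / "maape_summaries.csv", index=False)
        self.winner_counts.to_csv(out / "winner_counts.csv", index=False)


_KEY = ["model", "interaction", "trait"]


def summarize(records: pd.DataFrame) -> PredictionReport:
    """Aggregate per-cell predictions into the per-environment MAAPE report."""
    required = {"partition", "model", "interaction", "trait", "line",
                "environment", "observed", "predicted"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("no prediction records")
    recs = records.dropna(subset=["observed", "predicted"])

    per_part = (
        recs.groupby(_KEY + ["environment", "partition"])
        .apply(lambda d: maape(d["observed"], d["predicted"]), include_groups=False)
        .rename("maape")
        .reset_index()
    )
    per_env = (
        per_part.groupby(_KEY + ["environment"])["maape"].mean().rename("maape").reset_index()
    )
    all_envs = records["environment"].unique()
    covered = per_env["environment"].unique()
    skipped = sorted(set(all_envs) - set(covered))
    if skipped:
        logger.info("environments with no test cells in any partition: %s", skipped)

    summaries = (
        per_env.groupby(_KEY)["maape"]
        .agg(min="min", max="max", mean="mean", median="median", n_environments="count")
        .reset_index()
    )

    idx = per_env.groupby(["interaction", "trait", "environment"])["maape"].idxmin()
    winners = per_env.loc[idx]
    winner_counts = (
        winners.groupby(["interaction", "trait", "model"])
        .size()
        .rename("environments_won")
        .reset_index()
    )
    return PredictionReport(records, per_env, summaries, winner_counts)
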