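"""Leave-one-out cross-validation and grid search over (family, k, x, y).

Every training chemical is predicted from all the others, and the
collected estimates are scored with the composite metric (balanced
accuracy x accuracy x ROC AUC). The grid sweep evaluates every admissible
(k, x, y) combination for each estimator family and ranks rows by score.

The engineering decision that makes full grids tractable: the
self-similarity matrix and the per-chemical descending neighbor ordering
are computed once per fingerprint configuration and shared across all
held-out chemicals and all grid points, so each combination reduces to
slicing the top-k neighbor columns and applying the (vectorized)
estimator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Dataset
from .chemspace import FingerprintConfig, SimilarityMatrix, similarity_matrix
from .errors import ConfigError
from .evaluation import DEFAULT_THRESHOLD, MetricsReport, metrics
from .models import ModelParams, _estimate_rows

logger = logging.getLogger(__name__)

# the conventional sweep lists for k and the two non-linearity exponents
DEFAULT_K = (1, 2, 3, 5, 7, 10, 15, 20, 30, 50)
DEFAULT_XY = (
    0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0,
    5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 50.0,
)


@dataclass(frozen=True)
class GridSpec:
    """Admissible parameter values per axis and the families to sweep.

    Families whose estimator ignores x and/or y are swept only over their
    relevant axes (the irrelevant parameter is pinned), so the realized
    combination count reflects distinct models, not redundant re-runs.
    """

    k_values: tuple[int, ...] = DEFAULT_K
    x_values: tuple[float, ...] = DEFAULT_XY
    y_values: tuple[float, ...] = DEFAULT_XY
    families: tuple[str, ...] = ("gknn",)

    def combinations(self) -> list[tuple[str, int, float, float]]:
        if not (self.k_values and self.x_values and self.y_values and self.families):
            raise ConfigError("grid axes and families must be non-empty")
        combos = []
        for fam in self.families:
            if fam == "gknn":
                axes = itertools.product(self.k_values, self.x_values, self.y_values)
            elif fam == "knn_exponential":
                axes = ((k, x, 0.0) for k, x in itertools.product(self.k_values, self.x_values))
            elif fam in ("knn_arithmetic", "knn_geometric"):
                axes = ((k, 1.0, 0.0) for k in self.k_values)
            else:
                raise ConfigError(f"unknown family {fam!r} in grid")
            combos.extend((fam, k, x, y) for k, x, y in axes)
        return combos


@dataclass
class TuningResult:
    """Full grid table sorted by descending score, with the winner."""

    table: pd.DataFrame
    best: pd.Series
    ties: pd.DataFrame
    realized_combinations: int

    def export(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


class LooPredictor:
    """Precomputed leave-one-out machinery for one training set.

    Caches the self-similarity matrix and, for each chemical, its
    neighbors sorted by descending similarity (self excluded, ties by
    dataset order), so estimates for any (family, k, x, y) are a slice
    plus a vectorized estimator call.
    """

    def __init__(
        self,
        training: Dataset,
        fp_config: FingerprintConfig = FingerprintConfig(),
        endpoint: str | None = None,
        sim: SimilarityMatrix | None = None,
    ):
        if sim is None:
            sim = similarity_matrix(training, training, fp_config)
        elif not sim.is_self or sim.row_ids != training.ids:
            raise ValueError("supplied matrix is not the self-similarity of the training set")
        self.training = training
        self.sim = sim
        self.activities = training.activities(endpoint)
        n = len(training)
        if n < 2:
            raise ValueError("leave-one-out needs at least 2 chemicals")
        order = np.empty((n, n - 1), dtype=np.intp)
        sims = np.empty((n, n - 1), dtype=float)
        others = np.array(
            [[j for j in range(n) if j != i] for i in range(n)], dtype=np.intp
        )
        for i in range(n):
            row = self.sim.values[i, others[i]]
            o = np.argsort(-row, kind="stable")
            order[i] = others[i][o]
            sims[i] = row[o]
        self._nbr_idx = order  # (n, n-1) training indices, best first
        self._nbr_sim = sims
        self._nbr_act = self.activities[order]

    def estimates(self, params: ModelParams) -> np.ndarray:
        """LOO activity estimates for every training chemical."""
        n = len(self.training)
        if params.k + 1 > n:
            raise ValueError(f"k={params.k} needs at least {params.k + 1} chemicals, have {n}")
        A = self._nbr_act[:, : params.k]
        S = self._nbr_sim[:, : params.k]
        return _estimate_rows(A, S, params)

    def confidences(self) -> np.ndarray:
        """q_i = max similarity to the rest of the training set."""
        return self._nbr_sim[:, 0].copy()


def loo_cv(
    training: Dataset,
    params: ModelParams,
    endpoint: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    sim: SimilarityMatrix | None = None,
    predictor: LooPredictor | None = None,
) -> MetricsReport:
    """Leave-one-out cross-validation metrics for one parameterization."""
    if predictor is None:
        predictor = LooPredictor(training, params.fp_config, endpoint, sim)
    est = predictor.estimates(params)
    return metrics(predictor.activities, est, threshold)


def grid_search(
    training: Dataset,
    grid: GridSpec = GridSpec(),
    endpoint: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    fp_config: FingerprintConfig = FingerprintConfig(),
    sim: SimilarityMatrix | None = None,
    progress: bool = False,
) -> TuningResult:
    """LOO-CV over every grid combination, ranked by composite score.

    Rows with an undefined score sort below all defined ones; ties (and
    failures, recorded per-row) keep a deterministic (k, x, y) order.
    """
    predictor = LooPredictor(training, fp_config, endpoint, sim)
    combos = grid.combinations()
    logger.info("grid search over %d combinations", len(combos))
    rows = []
    for idx, (fam, k, x, y) in enumerate(combos):
        params = ModelParams(family=fam, k=k, x=x, y=y, fp_config=fp_config)
        row: dict = {"family": fam, "k": k, "x": x, "y": y, "error": ""}
        try:
            report = loo_cv(training, params, endpoint, threshold, predictor=predictor)
            row.update(report.as_dict())
        except Exception as exc:  # record and continue the sweep
            logger.warning("grid point %s failed: %s", (fam, k, x, y), exc)
            row.update({m: np.nan for m in (
                "sensitivity", "specificity", "balanced_accuracy", "accuracy",
                "precision", "npv", "roc_auc", "score")})
            row["error"] = str(exc)
        rows.append(row)
        if progress and (idx + 1) % 100 == 0:
            logger.info("grid progress: %d / %d", idx + 1, len(combos))
    table = pd.DataFrame(rows)
    # descending score with NaN (undefined) last; ties by k, x, y ascending
    table = table.sort_values(
        by=["score", "k", "x", "y"],
        ascending=[False, True, True, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    best = table.iloc[0]
    if np.isnan(best["score"]):
        logger.warning("every grid point has an undefined composite score")
    ties = table[np.isclose(table["score"], best["score"], atol=1e-12)]
    return TuningResult(
        table=table, best=best, ties=ties, realized_combinations=len(combos)
    )
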