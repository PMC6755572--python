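"""k-nearest-neighbor activity estimators, including the generalized
power-mean (GkNN) model.

The GkNN estimate for a query chemical is a similarity-weighted power mean
of its k nearest training activities,

    A_hat = ( sum_j A_j^x S_j^y / sum_j S_j^y )^(1/x),

where x >= 0 tunes non-linearity in activity space and y >= 0 in structure
space. Special cases recover the classical variants: x=1, y=0 is the plain
arithmetic kNN mean; the x -> 0 limit is the similarity-weighted geometric
mean (and is how x = 0 is defined here, since tuning grids include it);
large x pushes the estimate toward the largest neighbor activity and large
y toward the single most similar neighbor.

The exponential variant weights neighbor activities by exp(-x * d) with
the distance d = 1/S - 1 induced by Tanimoto similarity.

All estimators are evaluated in the log domain so that exponents up to 50
(the top of the usual tuning grids) remain numerically exact: the power
mean is computed as exp((logsumexp(x log A_j + y log S_j) -
logsumexp(y log S_j)) / x), with zero-activity neighbors handled by
exclusion from the numerator (0^x = 0 for x > 0) while their similarity
weight stays in the denominator.

Conventions: 0^0 = 1, so y = 0 gives every neighbor unit weight even at
S = 0; for y > 0 an S = 0 neighbor carries zero weight. The confidence of
an estimate is q = max_j S_j over the whole training set, the standard
similarity-based applicability-domain proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .chemio import Dataset
from .chemspace import FingerprintConfig, SimilarityMatrix, neighbor_order, similarity_matrix

logger = logging.getLogger(__name__)

FAMILIES = ("gknn", "knn_arithmetic", "knn_geometric", "knn_exponential")


@dataclass(frozen=True)
class ModelParams:
    """Estimator family plus its tunable parameters.

    ``x`` is the activity-space exponent (also the decay rate of the
    exponential family); ``y`` is the structure-space exponent (gknn
    only). Parameters irrelevant to a family are ignored but preserved
    for provenance.
    """

    family: Literal["gknn", "knn_arithmetic", "knn_geometric", "knn_exponential"] = "gknn"
    k: int = 10
    x: float = 1.0
    y: float = 1.0
    fp_config: FingerprintConfig = FingerprintConfig()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("x and y must be nonnegative")


@dataclass
class Prediction:
    chem_id: str
    estimate: float
    confidence: float
    neighbors: list[tuple[str, float, float]]  # (chem_id, similarity, activity)


def _validate_pair(activities, similarities) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(activities, dtype=float)
    S = np.asarray(similarities, dtype=float)
    if A.shape != S.shape or A.ndim != 1 or A.size == 0:
        raise ValueError("activities and similarities must be equal-length, non-empty 1-D")
    if A.min() < 0 or A.max() > 1 or S.min() < 0 or S.max() > 1:
        raise ValueError("activities and similarities must lie in [0, 1]")
    return A, S


def _log_weights(S: np.ndarray, y: float) -> np.ndarray:
    """y * log(S) with the 0^0 = 1 convention; rows with no usable weight
    (all S = 0 at y > 0) fall back to the unweighted mean with a warning."""
    if y == 0:
        return np.zeros_like(S)
    with np.errstate(divide="ignore"):
        logw = y * np.log(S)
    dead = np.all(np.isneginf(logw), axis=-1)
    if np.any(dead):
        warnings.warn(
            "all neighbor similarities are zero with y > 0; "
            "falling back to the unweighted power mean",
            RuntimeWarning,
            stacklevel=3,
        )
        dead_mask = np.broadcast_to(np.expand_dims(dead, -1), logw.shape)
        logw = np.where(dead_mask, 0.0, logw)
    return logw


def _gknn_rows(A: np.ndarray, S: np.ndarray, x: float, y: float) -> np.ndarray:
    """Vectorized GkNN power mean over rows of (n, k) neighbor arrays."""
    logw = _log_weights(S, y)
    usable = ~np.isneginf(logw)
    log_den = logsumexp(logw, axis=-1)
    with np.errstate(divide="ignore"):
        logA = np.log(A)
    if x == 0:
        # weighted geometric mean: exp(sum w_j log A_j); any zero-activity
        # neighbor with positive weight annihilates the product
        w = np.exp(logw - log_den[..., None])
        zero_hit = np.any((A == 0) & (w > 0), axis=-1)
        prod = np.exp(np.sum(np.where(w > 0, w * np.where(A > 0, logA, 0.0), 0.0), axis=-1))
        est = np.where(zero_hit, 0.0, prod)
    else:
        log_num = logsumexp(x * logA + logw, axis=-1)  # -inf rows -> estimate 0
        est = np.exp((log_num - log_den) / x)
    lo = np.min(np.where(usable, A, np.inf), axis=-1)
    hi = np.max(np.where(usable, A, -np.inf), axis=-1)
    return np.clip(est, lo, hi)


def gknn_estimate(
    neighbor_activities: Sequence[float],
    neighbor_similarities: Sequence[float],
    x: float,
    y: float,
) -> float:
    """Similarity-weighted power mean of neighbor activities (the GkNN
    estimator); x = 0 is defined as its geometric-mean limit."""
    if x < 0 or y < 0:
        raise ValueError("x and y must be nonnegative")
    A, S = _validate_pair(neighbor_activities, neighbor_similarities)
    return float(_gknn_rows(A[None, :], S[None, :], x, y)[0])


def knn_arithmetic(neighbor_activities: Sequence[float]) -> float:
    """Plain arithmetic mean of neighbor activities."""
    A = np.asarray(neighbor_activities, dtype=float)
    if A.size == 0:
        raise ValueError("need at least one neighbor activity")
    return float(A.mean())


def knn_geometric(neighbor_activities: Sequence[float]) -> float:
    """Geometric mean of neighbor activities; any zero gives zero."""
    A = np.asarray(neighbor_activities, dtype=float)
    if A.size == 0:
        raise ValueError("need at least one neighbor activity")
    if np.any(A == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(A))))


def _exponential_rows(A: np.ndarray, S: np.ndarray, x: float) -> np.ndarray:
    if x == 0:
        return A.mean(axis=-1)
    with np.errstate(divide="ignore"):
        d = 1.0 / S - 1.0  # S = 0 -> infinite distance -> zero weight
    logw = -x * d
    dead = np.all(np.isneginf(logw), axis=-1)
    if np.any(dead):
        warnings.warn(
            "all exponential weights vanished (every similarity is zero); "
            "using the most similar neighbor's activity",
            RuntimeWarning,
            stacklevel=3,
        )
    shift = np.max(logw, axis=-1, keepdims=True)
    w = np.exp(logw - np.where(np.isneginf(shift), 0.0, shift))
    with np.errstate(invalid="ignore"):
        est = np.sum(w * A, axis=-1) / np.sum(w, axis=-1)
    # columns are sorted by descending similarity upstream; for scalar use,
    # fall back to the highest-similarity entry
    fallback = A[..., np.argmax(S, axis=-1)] if A.ndim == 1 else np.take_along_axis(
        A, np.argmax(S, axis=-1)[..., None], axis=-1
    ).squeeze(-1)
    return np.where(dead, fallback, est)


def knn_exponential(
    neighbor_activities: Sequence[float],
    neighbor_similarities: Sequence[float],
    x: float,
) -> float:
    """Distance-weighted mean with weights exp(-x (1/S - 1))."""
    if x < 0:
        raise ValueError("x must be nonnegative")
    A, S = _validate_pair(neighbor_activities, neighbor_similarities)
    return float(_exponential_rows(A[None, :], S[None, :], x)[0])


def _estimate_rows(A: np.ndarray, S: np.ndarray, params: ModelParams) -> np.ndarray:
    """Apply the chosen family to (n, k) arrays of neighbor activities and
    similarities, columns sorted by descending similarity."""
    if params.family == "gknn":
        return _gknn_rows(A, S, params.x, params.y)
    if params.family == "knn_arithmetic":
        return A.mean(axis=-1)
    if params.family == "knn_geometric":
        out = np.where(
            np.any(A == 0, axis=-1),
            0.0,
            np.exp(np.mean(np.log(np.where(A > 0, A, 1.0)), axis=-1)),
        )
        return out
    return _exponential_rows(A, S, params.x)


def predict(
    query: Dataset,
    training: Dataset,
    params: ModelParams,
    endpoint: str | None = None,
    sim: SimilarityMatrix | None = None,
) -> list[Prediction]:
    """Estimate activities for query chemicals from their k nearest
    training neighbors.

    A query chemical whose id appears in the training set never uses
    itself as a neighbor (leave-one-out semantics). The confidence q is
    the maximum similarity to the (self-excluded) training set.
    ``sim`` may supply a precomputed query-by-training similarity matrix,
    e.g. for abstract fixtures without structures.
    """
    if len(training) == 0:
        raise ValueError("training set is empty")
    ep = endpoint or training.endpoint
    if sim is None:
        sim = similarity_matrix(query, training, params.fp_config)
    train_act = training.activities(ep)
    train_ids = training.ids
    preds: list[Prediction] = []
    for qi, rec in enumerate(query):
        sims = sim.values[qi]
        cand = np.arange(len(train_ids))
        if rec.chem_id in train_ids:
            cand = cand[cand != train_ids.index(rec.chem_id)]
        if cand.size == 0:
            raise ValueError(
                f"no training neighbors available for {rec.chem_id!r}"
            )
        s_cand = sims[cand]
        k = min(params.k, cand.size)
        if k < params.k:
            logger.warning(
                "only %d neighbors available for %r (k=%d)", k, rec.chem_id, params.k
            )
        top = cand[neighbor_order(s_cand)[:k]]
        A_nb, S_nb = train_act[top], sims[top]
        est = float(_estimate_rows(A_nb[None, :], S_nb[None, :], params)[0])
        preds.append(
            Prediction(
                chem_id=rec.chem_id,
                estimate=est,
                confidence=float(s_cand.max()),
                neighbors=[
                    (train_ids[j], float(sims[j]), float(train_act[j])) for j in top
                ],
            )
        )
    return preds


def predictions_to_frame(preds: list[Prediction]):
    """Tabulate predictions for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chem_id": [p.chem_id for p in preds],
            "estimate": [p.estimate for p in preds],
            "confidence": [p.confidence for p in preds],
            "neighbor_ids": [";".join(n[0] for n in p.neighbors) for p in preds],
            "neighbor_sims": [
                ";".join(format(n[1], ".6g") for n in p.neighbors) for p in preds
            ],
        }
    )
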