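"""Structure-activity landscape ruggedness via the SALI index.

For a pair of chemicals with activities A_i, A_j and Tanimoto similarity
S_ij, the structure-activity landscape index is

    SALI_ij = |A_i - A_j| / (1 - S_ij).

Large values flag activity cliffs: structurally similar chemicals with
very different activities. The distribution of pairwise SALI values
characterizes the whole landscape, while max_j SALI_ij pinpoints the
chemicals that form cliffs. Pairs with S_ij = 1 (identical fingerprints)
have an undefined, effectively infinite index; they are excluded from
distributions and maxima and reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Dataset
from .chemspace import SimilarityMatrix


@dataclass
class SaliResult:
    """Pairwise SALI values (finite pairs only), per-chemical maxima, and
    the similarity-1 pairs whose index is undefined."""

    pairwise: pd.DataFrame  # columns chem_i, chem_j, sali; i < j in dataset order
    max_per_chemical: dict[str, float]
    capped_pairs: list[tuple[str, str]]

    def value(self, chem_i: str, chem_j: str) -> float:
        m = self.pairwise[
            ((self.pairwise.chem_i == chem_i) & (self.pairwise.chem_j == chem_j))
            | ((self.pairwise.chem_i == chem_j) & (self.pairwise.chem_j == chem_i))
        ]
        if m.empty:
            raise KeyError((chem_i, chem_j))
        return float(m.sali.iloc[0])

    def histogram(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        """Log-spaced histogram of the positive finite SALI values
        (the values span orders of magnitude)."""
        vals = self.pairwise.sali.to_numpy()
        vals = vals[vals > 0]
        if vals.size == 0:
            edges = np.logspace(-3, 1, bins + 1)
            return edges, np.zeros(bins)
        edges = np.logspace(
            math.floor(math.log10(vals.min())), math.ceil(math.log10(vals.max())), bins + 1
        )
        counts, edges = np.histogram(vals, bins=edges)
        return edges, counts / counts.sum()

    def export(self, pairwise_path: str | Path, per_chemical_path: str | Path) -> None:
        self.pairwise.to_csv(pairwise_path, index=False)
        pd.DataFrame(
            {
                "chem_id": list(self.max_per_chemical),
                "max_sali": list(self.max_per_chemical.values()),
            }
        ).to_csv(per_chemical_path, index=False)


def sali(activity_i: float, activity_j: float, s_ij: float) -> float:
    """SALI for one pair; similarity 1 gives +inf (undefined index)."""
    if not (0.0 <= activity_i <= 1.0 and 0.0 <= activity_j <= 1.0):
        raise ValueError("activities must lie in [0, 1]")
    if not 0.0 <= s_ij <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    if s_ij == 1.0:
        return math.inf
    return abs(activity_i - activity_j) / (1.0 - s_ij)


def sali_analysis(
    ds: Dataset, sm: SimilarityMatrix, endpoint: str | None = None
) -> SaliResult:
    """SALI over all unordered pairs of a chemical set.

    ``sm`` must be the self-similarity matrix of ``ds``. Chemicals whose
    finite pairs are all zero-gap get a per-chemical maximum of 0.
    """
    if len(ds) < 2:
        raise ValueError("SALI analysis needs at least 2 chemicals")
    if not sm.is_self or sm.row_ids != ds.ids:
        raise ValueError("similarity matrix does not match the dataset (self-set required)")
    act = ds.activities(endpoint)
    ids = ds.ids
    n = len(ds)
    iu, ju = np.triu_indices(n, k=1)
    s = sm.values[iu, ju]
    gap = np.abs(act[iu] - act[ju])
    capped = s >= 1.0
    with np.errstate(divide="ignore"):
        vals = np.where(capped, np.inf, gap / (1.0 - s))
    fin = ~capped
    pairwise = pd.DataFrame(
        {
            "chem_i": [ids[i] for i in iu[fin]],
            "chem_j": [ids[j] for j in ju[fin]],
            "sali": vals[fin],
        }
    )
    max_per: dict[str, float] = {cid: 0.0 for cid in ids}
    for i, j, v in zip(iu[fin], ju[fin], vals[fin]):
        if v > max_per[ids[i]]:
            max_per[ids[i]] = float(v)
        if v > max_per[ids[j]]:
            max_per[ids[j]] = float(v)
    capped_pairs = [(ids[i], ids[j]) for i, j in zip(iu[capped], ju[capped])]
    return SaliResult(pairwise=pairwise, max_per_chemical=max_per, capped_pairs=capped_pairs)
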