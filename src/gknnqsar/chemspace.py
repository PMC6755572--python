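"""Chemical-space geometry: fingerprints, Tanimoto similarity, projections.

The structure space is described entirely through binary fingerprints and
Tanimoto similarity S = |a AND b| / |a OR b|. A low-dimensional picture of
a chemical set comes from the eigendecomposition of its double-centered
self-similarity matrix (the kernel-PCA convention), and the sensitivity of
neighborhoods to the fingerprint choice is quantified by the overlap of
nearest-neighbor lists computed under different backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import Dataset
from .errors import FingerprintError

logger = logging.getLogger(__name__)

FP_KINDS = ("morgan", "maccs", "path")


@dataclass(frozen=True)
class FingerprintConfig:
    """Which fingerprint backend to use and how to fold it.

    Morgan (circular, ECFP-like) at radius 2 folded to 1024 bits is the
    default; folding beyond ~1000 bits has negligible influence on the
    resulting similarities. ``maccs`` is the fixed 167-key dictionary and
    ignores ``n_bits``; ``path`` is a hashed topological-path (Daylight-
    style) fingerprint. The backend set is pluggable via `fingerprint`.
    """

    kind: str = "morgan"
    n_bits: int = 1024
    radius: int = 2


@dataclass
class Fingerprint:
    bits: np.ndarray  # uint8 0/1 vector
    kind: str
    n_bits: int

    @property
    def popcount(self) -> int:
        return int(np.count_nonzero(self.bits))


def fingerprint(structure: str, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Compute a binary fingerprint for a SMILES string (deterministic)."""
    from rdkit import Chem

    if config.kind not in FP_KINDS:
        raise FingerprintError(f"unknown fingerprint kind {config.kind!r}")
    if config.kind != "maccs" and config.n_bits < 64:
        raise FingerprintError("folded fingerprints need n_bits >= 64")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise FingerprintError(f"unparsable SMILES: {structure!r}")
    if config.kind == "morgan":
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=config.radius, fpSize=config.n_bits
        )
        bv = gen.GetFingerprint(mol)
        n_bits = config.n_bits
    elif config.kind == "path":
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=config.n_bits)
        bv = gen.GetFingerprint(mol)
        n_bits = config.n_bits
    else:  # maccs: fixed key set, n_bits ignored
        from rdkit.Chem import MACCSkeys

        bv = MACCSkeys.GenMACCSKeys(mol)
        n_bits = bv.GetNumBits()
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=arr, kind=config.kind, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are treated as identical (similarity 1.0);
    all-zero against nonzero gives 0.0.
    """
    if a.kind != b.kind or a.n_bits != b.n_bits:
        raise FingerprintError(
            f"incompatible fingerprints: {a.kind}/{a.n_bits} vs {b.kind}/{b.n_bits}"
        )
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class SimilarityMatrix:
    """Pairwise Tanimoto similarities between a query and a reference set."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("similarity matrix shape does not match id lists")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def is_self(self) -> bool:
        return self.row_ids == self.col_ids

    def row(self, chem_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(chem_id)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            values=frame.to_numpy(dtype=float),
            row_ids=[str(i) for i in frame.index],
            col_ids=[str(c) for c in frame.columns],
        )


def _fingerprint_block(ds: Dataset, config: FingerprintConfig) -> np.ndarray:
    rows = []
    for rec in ds:
        if rec.smiles is None:
            raise FingerprintError(
                f"chemical {rec.chem_id!r} has no structure to fingerprint"
            )
        try:
            rows.append(fingerprint(rec.smiles, config).bits)
        except FingerprintError as exc:
            raise FingerprintError(f"chemical {rec.chem_id!r}: {exc}") from exc
    return np.vstack(rows) if rows else np.zeros((0, config.n_bits), dtype=np.uint8)


def similarity_matrix(
    query: Dataset, reference: Dataset, config: FingerprintConfig = FingerprintConfig()
) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity between two chemical sets.

    Computed in integer arithmetic (bit counts), so the self-set case is
    exactly symmetric with a unit diagonal.
    """
    fq = _fingerprint_block(query, config).astype(np.int64)
    fr = (
        fq
        if query is reference
        else _fingerprint_block(reference, config).astype(np.int64)
    )
    inter = fq @ fr.T
    pop_q = fq.sum(axis=1)
    pop_r = fr.sum(axis=1)
    union = pop_q[:, None] + pop_r[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return SimilarityMatrix(values=values, row_ids=query.ids, col_ids=reference.ids)


def similarity_distribution(
    sm: SimilarityMatrix, bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of pairwise similarities over [0, 1].

    For a self-similarity matrix only the n(n-1)/2 off-diagonal pairs
    enter (an analog of a radial distribution function); for a cross-set
    matrix all entries do. Returns ``(bin_edges, normalized_counts)`` with
    counts summing to 1.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if sm.is_self:
        n = len(sm.row_ids)
        if n < 2:
            raise ValueError("need at least 2 chemicals for a self-set distribution")
        vals = sm.values[np.triu_indices(n, k=1)]
    else:
        vals = sm.values.ravel()
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return edges, counts / counts.sum()


@dataclass
class Projection:
    """Coordinates of chemicals along the top eigen-directions of the
    centered self-similarity matrix, with out-of-sample support."""

    coordinates: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # all n, nonincreasing
    ids: list[str]
    _basis: np.ndarray = field(repr=False, default=None)  # (n, m) eigenvectors
    _scale: np.ndarray = field(repr=False, default=None)  # sqrt of top-m eigenvalues
    _col_means: np.ndarray = field(repr=False, default=None)
    _grand_mean: float = field(repr=False, default=0.0)

    def transform(self, sim_rows: np.ndarray) -> np.ndarray:
        """Project new chemicals given their similarity rows to the
        training set (shape (q, n))."""
        k = np.atleast_2d(np.asarray(sim_rows, dtype=float))
        kc = (
            k
            - self._col_means[None, :]
            - k.mean(axis=1, keepdims=True)
            + self._grand_mean
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            return kc @ self._basis / np.where(self._scale > 0, self._scale, np.inf)

    def to_csv(self, path: str | Path) -> None:
        cols = {f"pc{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        pd.DataFrame({"chem_id": self.ids, **cols}).to_csv(path, index=False)


def eigenprojection(sm: SimilarityMatrix, m: int = 3) -> Projection:
    """Kernel-PCA style embedding of a self-similarity matrix.

    The similarity matrix is double-centered and eigendecomposed; chemical
    i gets coordinates ``v_ij * sqrt(lambda_j)`` for the top-m eigenpairs.
    Negative tail eigenvalues (Tanimoto matrices need not be positive
    semidefinite) are clipped to zero for scaling but reported as-is.
    """
    if not sm.is_self:
        raise ValueError("eigenprojection requires a self-similarity matrix")
    n = len(sm.row_ids)
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= {n}, got m={m}")
    K = np.asarray(sm.values, dtype=float)
    K = 0.5 * (K + K.T)  # guard against float asymmetry
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand
    eigvals, eigvecs = np.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.sqrt(np.clip(eigvals[:m], 0.0, None))
    coords = eigvecs[:, :m] * scale[None, :]
    return Projection(
        coordinates=coords,
        eigenvalues=eigvals,
        ids=list(sm.row_ids),
        _basis=eigvecs[:, :m],
        _scale=scale,
        _col_means=col_means,
        _grand_mean=grand,
    )


def neighbor_order(sims: np.ndarray) -> np.ndarray:
    """Indices sorting similarities descending, ties by original position."""
    return np.argsort(-np.asarray(sims, dtype=float), kind="stable")


def neighbor_list(
    sm: SimilarityMatrix, chem: str, k: int
) -> list[tuple[str, float]]:
    """The k most similar reference chemicals, descending similarity.

    Self is excluded when the query set equals the reference set. Ties are
    broken by dataset order; if fewer than k neighbors exist the list is
    truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = sm.row(chem).copy()
    candidates = np.arange(len(sm.col_ids))
    if sm.is_self:
        self_idx = sm.col_ids.index(chem)
        mask = candidates != self_idx
        candidates, sims = candidates[mask], sims[mask]
    if k > len(candidates):
        logger.warning(
            "requested k=%d neighbors for %r but only %d available; truncating",
            k,
            chem,
            len(candidates),
        )
        k = len(candidates)
    order = neighbor_order(sims)[:k]
    return [(sm.col_ids[candidates[i]], float(sims[i])) for i in order]


def neighbor_overlap(
    list_a: list[tuple[str, float]], list_b: list[tuple[str, float]]
) -> float:
    """Fraction of shared neighbor identities between two neighbor lists."""
    if not list_a or not list_b:
        raise ValueError("neighbor lists must be non-empty")
    ids_a = {cid for cid, _ in list_a}
    ids_b = {cid for cid, _ in list_b}
    return len(ids_a & ids_b) / max(len(ids_a), len(ids_b))
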