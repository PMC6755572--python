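"""Chemical/activity data IO and training-set curation.

Activity scores live on the scale from 0.0 (inactive) to 1.0 (active); a
score combines estimated potency with the certainty that the chemical truly
interacts with the target. Curation removes the uncertain band just above
the activity cutoff, and evaluation subsets can be restricted to chemicals
whose independent activity sources agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_ENDPOINT = "activity"


@dataclass
class ChemicalRecord:
    """One chemical: identifier, structure, activities and source metadata.

    Parameters
    ----------
    chem_id:
        Opaque unique identifier within a dataset.
    smiles:
        SMILES string; may be ``None`` when the dataset carries a
        precomputed similarity matrix instead of structures.
    endpoint_scores:
        Mapping endpoint name -> activity score in ``[0, 1]``.
    n_sources:
        Number of independent activity records behind the score.
    source_calls:
        Optional per-source binary active/inactive calls (0/1).
    """

    chem_id: str
    smiles: str | None = None
    endpoint_scores: dict[str, float] = field(default_factory=dict)
    n_sources: int = 0
    source_calls: list[int] | None = None

    def __post_init__(self) -> None:
        for name, score in self.endpoint_scores.items():
            if not 0.0 <= float(score) <= 1.0:
                raise DataError(
                    f"activity score {score!r} for endpoint {name!r} of chemical "
                    f"{self.chem_id!r} is outside [0, 1]"
                )
        if self.n_sources < 0:
            raise DataError(f"negative n_sources for chemical {self.chem_id!r}")
        if self.source_calls is not None and self.n_sources < len(self.source_calls):
            raise DataError(
                f"chemical {self.chem_id!r}: n_sources={self.n_sources} < "
                f"{len(self.source_calls)} source calls"
            )

    def score(self, endpoint: str) -> float:
        try:
            return float(self.endpoint_scores[endpoint])
        except KeyError:
            raise DataError(
                f"chemical {self.chem_id!r} has no score for endpoint {endpoint!r}"
            ) from None


@dataclass
class Dataset:
    """An ordered, duplicate-free collection of chemicals for one endpoint."""

    records: list[ChemicalRecord]
    endpoint: str = DEFAULT_ENDPOINT

    def __post_init__(self) -> None:
        ids = [r.chem_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate chem_id(s) in dataset: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ChemicalRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ChemicalRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.chem_id for r in self.records]

    def get(self, chem_id: str) -> ChemicalRecord:
        for r in self.records:
            if r.chem_id == chem_id:
                return r
        raise KeyError(chem_id)

    def activities(self, endpoint: str | None = None) -> np.ndarray:
        """Activity scores for ``endpoint`` (default: the dataset endpoint)."""
        ep = endpoint or self.endpoint
        return np.array([r.score(ep) for r in self.records], dtype=float)

    def subset(self, keep: Iterable[str]) -> "Dataset":
        keep = set(keep)
        return Dataset(
            [r for r in self.records if r.chem_id in keep], endpoint=self.endpoint
        )


@dataclass(frozen=True)
class ColumnConfig:
    """Maps the canonical CSV schema onto arbitrary column headers."""

    chem_id: str = "chem_id"
    smiles: str = "smiles"
    activity: str = "activity"
    n_sources: str = "n_sources"
    source_calls: str = "source_calls"


def _parse_int(raw: object) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return 0
    return int(raw)


def _parse_calls(raw: object) -> list[int] | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    return [int(tok) for tok in text.split(";")]


def read_dataset(
    path: str | Path,
    format: str = "csv",
    config: ColumnConfig | None = None,
    endpoint: str = DEFAULT_ENDPOINT,
    validate_structures: bool = True,
) -> Dataset:
    """Read a chemical dataset from CSV/TSV or SDF.

    Rows whose structures cannot be parsed are logged and skipped, never
    silently dropped. Raises :class:`SchemaError` when a configured column
    is missing and ``FileNotFoundError`` for a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path, config or ColumnConfig(), endpoint, validate_structures)
    if format == "sdf":
        return _read_sdf(path, config or ColumnConfig(), endpoint)
    raise SchemaError(f"unknown dataset format {format!r}; expected 'csv' or 'sdf'")


def _read_csv(
    path: Path, cfg: ColumnConfig, endpoint: str, validate_structures: bool
) -> Dataset:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(
        path, sep=sep, dtype={cfg.chem_id: str}, float_precision="round_trip"
    )
    for col in (cfg.chem_id, cfg.activity):
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    has_smiles = cfg.smiles in frame.columns
    if not has_smiles:
        logger.info("no SMILES column %r in %s; structures omitted", cfg.smiles, path)

    records: list[ChemicalRecord] = []
    n_skipped = 0
    for row in frame.to_dict(orient="records"):
        smiles: str | None = None
        if has_smiles:
            raw = row[cfg.smiles]
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                smiles = str(raw) or None
        if smiles is not None and validate_structures and not _parsable(smiles):
            logger.warning(
                "skipping chemical %r: unparsable SMILES %r", row[cfg.chem_id], smiles
            )
            n_skipped += 1
            continue
        records.append(
            ChemicalRecord(
                chem_id=str(row[cfg.chem_id]),
                smiles=smiles,
                endpoint_scores={endpoint: float(row[cfg.activity])},
                n_sources=_parse_int(row.get(cfg.n_sources)),
                source_calls=_parse_calls(row.get(cfg.source_calls)),
            )
        )
    if n_skipped:
        logger.warning("%d of %d rows skipped in %s", n_skipped, len(frame), path)
    return Dataset(records, endpoint=endpoint)


def _parsable(smiles: str) -> bool:
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles) is not None


def _read_sdf(path: Path, cfg: ColumnConfig, endpoint: str) -> Dataset:
    from rdkit import Chem

    records: list[ChemicalRecord] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping SDF entry %d in %s: unparsable molecule", i, path)
            continue
        props = mol.GetPropsAsDict()
        if cfg.activity not in props:
            raise SchemaError(f"SD tag {cfg.activity!r} missing on molecule {i} in {path}")
        chem_id = str(props.get(cfg.chem_id, mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"))
        records.append(
            ChemicalRecord(
                chem_id=chem_id,
                smiles=Chem.MolToSmiles(mol),
                endpoint_scores={endpoint: float(props[cfg.activity])},
                n_sources=int(props.get(cfg.n_sources, 0)),
                source_calls=_parse_calls(props.get(cfg.source_calls)),
            )
        )
    return Dataset(records, endpoint=endpoint)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV schema (bit-exact round trip)."""
    rows = []
    for r in ds.records:
        rows.append(
            {
                "chem_id": r.chem_id,
                "smiles": "" if r.smiles is None else r.smiles,
                "activity": repr(r.score(ds.endpoint)),
                "n_sources": r.n_sources,
                "source_calls": ""
                if r.source_calls is None
                else ";".join(str(c) for c in r.source_calls),
            }
        )
    pd.DataFrame(
        rows, columns=["chem_id", "smiles", "activity", "n_sources", "source_calls"]
    ).to_csv(path, index=False)


def average_sources(scores: Sequence[float]) -> float:
    """Arithmetic mean of per-source activity scores for one chemical."""
    if len(scores) == 0:
        raise DataError("cannot average an empty list of source scores")
    arr = np.asarray(scores, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise DataError("source scores must lie in [0, 1]")
    return float(arr.mean())


def curate_training(ds: Dataset, low: float = 0.01, high: float = 0.1) -> Dataset:
    """Drop chemicals whose score falls strictly inside the uncertain band.

    Scores in the open interval ``(low, high)`` sit just above the activity
    cutoff where false positives concentrate; they are removed. Boundary
    values are retained.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"require 0 <= low < high <= 1, got ({low}, {high})")
    kept = [r for r in ds.records if not low < r.score(ds.endpoint) < high]
    removed = len(ds) - len(kept)
    if removed:
        logger.info(
            "curation removed %d chemical(s) with score in (%g, %g)", removed, low, high
        )
    return Dataset(kept, endpoint=ds.endpoint)


def consistency_subset(
    ds: Dataset, min_sources: int, majority_frac: float = 0.8
) -> Dataset:
    """Keep chemicals with many, mutually consistent activity sources.

    A chemical survives when ``n_sources > min_sources`` and its majority
    call (active or inactive) occurs in at least ``majority_frac`` of its
    per-source calls.
    """
    if min_sources < 0:
        raise ValueError("min_sources must be nonnegative")
    if not 0.5 < majority_frac <= 1.0:
        raise ValueError("majority_frac must lie in (0.5, 1]")
    kept = []
    for r in ds.records:
        if r.n_sources <= min_sources:
            continue
        if r.source_calls is None:
            raise DataError(
                f"chemical {r.chem_id!r} lacks source_calls; cannot assess consistency"
            )
        calls = np.asarray(r.source_calls)
        n_active = int((calls == 1).sum())
        majority = max(n_active, len(calls) - n_active) / len(calls)
        if majority >= majority_frac:
            kept.append(r)
    return Dataset(kept, endpoint=ds.endpoint)
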