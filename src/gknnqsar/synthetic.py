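"""Seeded synthetic chemical sets with controlled landscape structure.

Real activity data for a receptor endpoint are large external downloads;
every operation in this package is instead exercised on generated sets
whose structure-activity landscape is controlled by construction:

``smooth``
    Activity is a piecewise-linear (hence Lipschitz, constant ``lipschitz``)
    function of the Tanimoto similarity to a designated seed chemical.
    Because Jaccard distance 1 - S is a metric, the reverse triangle
    inequality gives |A_i - A_j| <= L * (1 - S_ij) for every pair, i.e.
    every finite SALI value is bounded by L — smoothness is a theorem of
    the construction, not an empirical observation.
``cliff``
    The smooth construction plus a designated pair with similarity >= 0.8
    whose activities are forced to 0.9 and 0.05, creating an activity
    cliff with SALI >= 4 by construction.
``random``
    Activities i.i.d. uniform on [0, 1] — a maximally rugged landscape.

Two modes: ``real_smiles`` enumerates a deterministic roster of valid
structures (scaffold x alkyl-chain x terminal-group decoration, folded
fingerprint duplicates removed) and computes true Morgan similarities;
``abstract_matrix`` embeds chemicals on a line segment and sets
S_ij = 1 - |u_i - u_j|, which is faster and lets expected outputs be
computed by hand. In noise-free smooth/cliff sets exactly ``n_actives``
chemicals exceed the activity threshold, so class imbalance (e.g. ~80
or ~9 actives out of ~1600, the agonist-like and antagonist-like
regimes) is steerable.

Per-chemical source counts and active/inactive source calls are also
synthesized (a mix of consistent and inconsistent chemicals) so the
consistency-filtering IO paths are testable end to end.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .chemio import ChemicalRecord, Dataset
from .chemspace import FingerprintConfig, SimilarityMatrix, fingerprint, similarity_matrix
from .errors import ConfigError

logger = logging.getLogger(__name__)

MODES = ("real_smiles", "abstract_matrix")
LANDSCAPES = ("smooth", "cliff", "random")

_SCAFFOLDS = (
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCOC1",
    "n1ccncc1",  # pyrazine, closed on carbon so decoration keeps valence
    "C1CCCC1",
)
_CHAINS = tuple("C" * n for n in range(0, 7))
_GROUPS = ("", "O", "N", "Cl", "C(=O)O", "C(=O)N", "OC", "S", "F", "C#N")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic set; identical spec + seed -> identical data."""

    n_chemicals: int = 100
    mode: str = "abstract_matrix"
    landscape: str = "smooth"
    n_actives: int = 20
    activity_noise: float = 0.0
    seed: int = 0
    threshold: float = 0.1
    lipschitz: float = 2.0
    endpoint: str = "activity"
    fp_config: FingerprintConfig = FingerprintConfig()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.landscape not in LANDSCAPES:
            raise ConfigError(
                f"unknown landscape {self.landscape!r}; expected one of {LANDSCAPES}"
            )
        if not 0 <= self.n_actives <= self.n_chemicals:
            raise ConfigError("need 0 <= n_actives <= n_chemicals")
        if self.activity_noise < 0:
            raise ConfigError("activity_noise must be nonnegative")


def smiles_roster(n: int, fp_config: FingerprintConfig = FingerprintConfig()) -> list[str]:
    """First n members of the deterministic scaffold-and-decoration
    enumeration, keeping only parseable structures with distinct
    fingerprints (folding collapses long homologs onto identical bits)."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        roster: list[str] = []
        seen: set[bytes] = set()
        for chain, group, scaffold in itertools.product(_CHAINS, _GROUPS, _SCAFFOLDS):
            smi = scaffold + chain + group
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            key = fingerprint(smi, fp_config).bits.tobytes()
            if key in seen:
                continue
            seen.add(key)
            roster.append(smi)
            if len(roster) == n:
                return roster
    finally:
        RDLogger.EnableLog("rdApp.error")
    raise ConfigError(
        f"roster enumeration exhausted at {len(roster)} structures; requested {n}"
    )


def _smooth_activities(
    sims_to_seed: np.ndarray,
    assignable: np.ndarray,
    n_actives: int,
    threshold: float,
    lipschitz: float,
) -> np.ndarray:
    """Activities = clip(threshold + L*(s - t), 0, 1) with the cut t placed
    so that exactly n_actives of the assignable chemicals are active.

    A deterministic ramp of 1e-9 per dataset position breaks exact
    similarity ties (discrete fingerprints produce them), so the active
    count is exact; it inflates the effective Lipschitz bound on finite
    SALI values by a negligible O(n * 1e-9 / (1 - S)) term.
    """
    s_eff = sims_to_seed + 1e-9 * np.arange(sims_to_seed.size)
    s = s_eff[assignable]
    if not 0 <= n_actives <= s.size:
        raise ConfigError("n_actives exceeds the number of assignable chemicals")
    s_sorted = np.sort(s)[::-1]
    if n_actives == 0:
        t = s_sorted[0] + 0.05
    elif n_actives == s.size:
        t = s_sorted[-1] - 0.05
    else:
        t = 0.5 * (s_sorted[n_actives] + s_sorted[n_actives - 1])
    act = np.zeros_like(sims_to_seed)
    act[assignable] = np.clip(threshold + lipschitz * (s - t), 0.0, 1.0)
    return act


def _source_calls(
    rng: np.random.Generator, active: bool, index: int
) -> tuple[int, list[int]]:
    n_sources = int(rng.integers(1, 13))
    p_agree = 0.6 if index % 5 == 4 else 0.9  # every 5th chemical is inconsistent
    majority = 1 if active else 0
    calls = [
        majority if rng.random() < p_agree else 1 - majority for _ in range(n_sources)
    ]
    return n_sources, calls


def generate(spec: SyntheticSpec) -> tuple[Dataset, SimilarityMatrix]:
    """Build a synthetic dataset and its self-similarity matrix."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chemicals
    if n < 2:
        raise ConfigError("need at least 2 chemicals")

    if spec.mode == "real_smiles":
        smiles: list[str | None] = list(smiles_roster(n, spec.fp_config))
        ids = [f"SYN{i:05d}" for i in range(n)]
        probe = Dataset(
            [ChemicalRecord(chem_id=ids[i], smiles=smiles[i], endpoint_scores={spec.endpoint: 0.0}) for i in range(n)],
            endpoint=spec.endpoint,
        )
        sm = similarity_matrix(probe, probe, spec.fp_config)
    else:
        u = rng.uniform(0.0, 0.45, size=n)
        if spec.landscape == "cliff":
            u[1] = min(u[0] + 0.05, 0.45)  # force a structurally close pair
        values = 1.0 - np.abs(u[:, None] - u[None, :])
        ids = [f"ABS{i:05d}" for i in range(n)]
        smiles = [None] * n
        sm = SimilarityMatrix(values=values, row_ids=ids, col_ids=ids)

    sims_to_seed = sm.values[0]

    if spec.landscape == "random":
        act = rng.uniform(0.0, 1.0, size=n)
    else:
        assignable = np.ones(n, dtype=bool)
        cliff_pair: tuple[int, int] | None = None
        n_act = spec.n_actives
        if spec.landscape == "cliff":
            cliff_pair = _pick_cliff_pair(sm.values)
            assignable[list(cliff_pair)] = False
            n_act = max(spec.n_actives - 1, 0)  # the cliff active counts too
        act = _smooth_activities(
            sims_to_seed, assignable, n_act, spec.threshold, spec.lipschitz
        )
        if cliff_pair is not None:
            act[cliff_pair[0]] = 0.9
            act[cliff_pair[1]] = 0.05
        if spec.activity_noise > 0:
            act = np.clip(act + rng.normal(0.0, spec.activity_noise, size=n), 0.0, 1.0)

    records = []
    for i in range(n):
        n_sources, calls = _source_calls(rng, act[i] > spec.threshold, i)
        records.append(
            ChemicalRecord(
                chem_id=ids[i],
                smiles=smiles[i],
                endpoint_scores={spec.endpoint: float(act[i])},
                n_sources=n_sources,
                source_calls=calls,
            )
        )
    return Dataset(records, endpoint=spec.endpoint), sm


def _pick_cliff_pair(values: np.ndarray) -> tuple[int, int]:
    """The most similar pair with S in [0.8, 1): close enough for a cliff,
    distinct enough for a finite SALI."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    s = values[iu, ju]
    eligible = (s >= 0.8) & (s < 1.0)
    if not eligible.any():
        raise ConfigError(
            "no chemical pair with similarity in [0.8, 1.0); cannot place a cliff"
        )
    best = np.flatnonzero(eligible)[np.argmax(s[eligible])]
    return int(iu[best]), int(ju[best])
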