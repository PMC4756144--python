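"""Labeled interaction datasets.

Positive aptamer-compound pairs come from an interaction list; negative
pairs are constructed by the random-pairing rule: sample uniformly,
without replacement, from the compound x aptamer product set excluding
the known positives.  The default negative:positive ratio is 2 (the
chance that a random pairing is a true interaction is assumed
negligible).  The assembled dataset is a pair x feature matrix plus the
class-label target vector c.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import AptamerRecord, CompoundRecord, FeatureSchema, assemble_vector

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "InteractionPair",
    "InteractionDataset",
    "generate_negatives",
    "assemble_dataset",
    "write_dataset",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class InteractionPair:
    compound_id: str
    aptamer_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class InteractionDataset:
    """Sample matrix (rows = pairs), binary labels y (1 = positive), schema."""

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema
    pairs: tuple[InteractionPair, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.pairs):
            raise ValueError("row count, label count and pair count must agree")
        if self.X.shape[1] != len(self.schema):
            raise ValueError("matrix width must equal schema length")
        keys = [(p.compound_id, p.aptamer_id) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (compound, aptamer) pair in dataset")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def generate_negatives(
    positives: Sequence[InteractionPair],
    compound_ids: Sequence[str],
    aptamer_ids: Sequence[str],
    *,
    ratio: float = 2.0,
    seed: int = 0,
) -> list[InteractionPair]:
    """Sample round(ratio * |positives|) negative pairs by random pairing.

    Pairs are drawn uniformly without replacement from the product set
    ``compound_ids x aptamer_ids`` minus the positive pairs.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    n_neg = int(round(ratio * len(positives)))
    if n_neg == 0:
        return []
    compound_ids = list(compound_ids)
    aptamer_ids = list(aptamer_ids)
    pos_keys = {(p.compound_id, p.aptamer_id) for p in positives}
    comp_set, apt_set = set(compound_ids), set(aptamer_ids)
    n_cells = len(compound_ids) * len(aptamer_ids)
    n_available = n_cells - sum(
        1 for c, a in pos_keys if c in comp_set and a in apt_set
    )
    if n_available < n_neg:
        raise ValueError(
            f"cannot draw {n_neg} negatives: only {n_available} non-positive "
            f"pairs exist (shortfall {n_neg - n_available})"
        )
    rng = np.random.default_rng(seed)
    n_apt = len(aptamer_ids)
    # Flatten the product set; mask out positives, then choose without replacement.
    mask = np.ones(n_cells, dtype=bool)
    apt_index = {a: j for j, a in enumerate(aptamer_ids)}
    comp_index = {c: i for i, c in enumerate(compound_ids)}
    for c, a in pos_keys:
        if c in comp_index and a in apt_index:
            mask[comp_index[c] * n_apt + apt_index[a]] = False
    candidates = np.flatnonzero(mask)
    chosen = rng.choice(candidates, size=n_neg, replace=False)
    return [
        InteractionPair(compound_ids[k // n_apt], aptamer_ids[k % n_apt], NEGATIVE)
        for k in chosen
    ]


def assemble_dataset(
    pairs: Sequence[InteractionPair],
    aptamers: Sequence[AptamerRecord] | Mapping[str, AptamerRecord],
    compounds: Sequence[CompoundRecord] | Mapping[str, CompoundRecord],
    schema: FeatureSchema,
) -> InteractionDataset:
    """Encode one feature-vector row per pair: positives first, then negatives,
    each block in input order."""
    if not pairs:
        raise ValueError("empty pair list")
    if not isinstance(aptamers, Mapping):
        aptamers = {a.id: a for a in aptamers}
    if not isinstance(compounds, Mapping):
        compounds = {c.id: c for c in compounds}
    ordered = [p for p in pairs if p.label == POSITIVE] + [
        p for p in pairs if p.label == NEGATIVE
    ]
    rows = np.empty((len(ordered), len(schema)), dtype=float)
    for i, pair in enumerate(ordered):
        if pair.aptamer_id not in aptamers:
            raise KeyError(f"unknown aptamer id {pair.aptamer_id!r}")
        if pair.compound_id not in compounds:
            raise KeyError(f"unknown compound id {pair.compound_id!r}")
        rows[i] = assemble_vector(
            aptamers[pair.aptamer_id], compounds[pair.compound_id], schema
        )
    y = np.array([1 if p.label == POSITIVE else 0 for p in ordered], dtype=np.int8)
    return InteractionDataset(X=rows, y=y, schema=schema, pairs=tuple(ordered))


def write_dataset(dataset: InteractionDataset, path: str | Path) -> None:
    """Write the assembled matrix as TSV: ids and label first, then features."""
    meta = pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in dataset.pairs],
            "aptamer_id": [p.aptamer_id for p in dataset.pairs],
            "label": [p.label for p in dataset.pairs],
        }
    )
    feats = pd.DataFrame(dataset.X, columns=list(dataset.schema.names))
    pd.concat([meta, feats], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
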