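"""Feature encoding for aptamer-compound interaction pairs.

An aptamer (a short single-stranded nucleic acid) is represented by its
nucleotide composition: the four mononucleotide frequencies over the
alphabet {a, c, g, u} (with ``t`` read as ``u``) followed by the sixteen
overlapping dinucleotide frequencies, giving a fixed 20-component block.
A compound is represented by a table of named numeric molecular
descriptors, each belonging to one of five classical descriptor families
(constitutional, electrostatic, geometrical, quantum-chemical,
topological).  An interaction pair is the concatenation of the two
blocks, aptamer first, in a fixed :class:`FeatureSchema` order.

Descriptor tables are cleaned before use: any descriptor with a missing
value for at least one compound, or with zero variance across compounds,
is dropped (columns are dropped, never compounds).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "APTAMER_FEATURE_NAMES",
    "AptamerRecord",
    "CompoundRecord",
    "FeatureSchema",
    "COMPOUND_CATEGORIES",
    "APTAMER_MONO",
    "APTAMER_DI",
    "encode_aptamer",
    "filter_descriptors",
    "assemble_vector",
    "read_fasta",
    "write_fasta",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_category_map",
    "write_category_map",
    "read_interactions",
    "write_interactions",
]

ALPHABET = ("a", "c", "g", "u")

#: Feature-type categories for the aptamer block.
APTAMER_MONO = "aptamer-mono"
APTAMER_DI = "aptamer-di"

#: The five compound descriptor families, in conventional order.
COMPOUND_CATEGORIES = (
    "constitutional",
    "electrostatic",
    "geometrical",
    "quantum-chemical",
    "topological",
)

_DINUCLEOTIDES = tuple(a + b for a, b in itertools.product(ALPHABET, ALPHABET))

#: Fixed order of the 20 aptamer composition features.
APTAMER_FEATURE_NAMES = tuple(f"freq_{m}" for m in ALPHABET) + tuple(
    f"freq_{d}" for d in _DINUCLEOTIDES
)


def _normalize_sequence(sequence: str) -> str:
    """Lowercase a nucleotide sequence and merge t into u."""
    return sequence.lower().replace("t", "u")


@dataclass(frozen=True)
class AptamerRecord:
    """An aptamer sequence over the alphabet a/c/g/u/t (case-insensitive)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"aptamer {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence.lower()):
            if ch not in ("a", "c", "g", "u", "t"):
                raise ValueError(
                    f"aptamer {self.id!r}: invalid character {ch!r} at position {pos}"
                )


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with named numeric descriptors (NaN marks a missing value)."""

    id: str
    descriptors: Mapping[str, float]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with a type category per feature.

    The aptamer block (4 mononucleotide + 16 dinucleotide frequencies) is
    always first; compound descriptors follow in table order.
    """

    names: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.categories):
            raise ValueError("names and categories must have equal length")
        if self.names[:20] != APTAMER_FEATURE_NAMES:
            raise ValueError("schema must start with the 20 aptamer features")
        expected = (APTAMER_MONO,) * 4 + (APTAMER_DI,) * 16
        if self.categories[:20] != expected:
            raise ValueError("aptamer block categories malformed")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in schema")

    @classmethod
    def build(
        cls,
        descriptor_names: Sequence[str],
        category_map: Mapping[str, str],
    ) -> "FeatureSchema":
        """Build a schema from retained descriptor names and their categories."""
        cats = []
        for name in descriptor_names:
            try:
                cat = category_map[name]
            except KeyError:
                raise KeyError(f"descriptor {name!r} missing from category map")
            if cat not in COMPOUND_CATEGORIES:
                raise ValueError(
                    f"descriptor {name!r}: unknown category {cat!r}; "
                    f"expected one of {COMPOUND_CATEGORIES}"
                )
            cats.append(cat)
        names = APTAMER_FEATURE_NAMES + tuple(descriptor_names)
        categories = (APTAMER_MONO,) * 4 + (APTAMER_DI,) * 16 + tuple(cats)
        return cls(names=names, categories=categories)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def compound_names(self) -> tuple[str, ...]:
        return self.names[20:]

    def category_counts(self) -> dict[str, int]:
        """Total feature count per category (the feature-distribution table)."""
        counts = {c: 0 for c in (APTAMER_MONO, APTAMER_DI) + COMPOUND_CATEGORIES}
        for cat in self.categories:
            counts[cat] += 1
        return counts

    def indices_by_category(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {
            c: [] for c in (APTAMER_MONO, APTAMER_DI) + COMPOUND_CATEGORIES
        }
        for i, cat in enumerate(self.categories):
            out[cat].append(i)
        return out


def encode_aptamer(record: AptamerRecord) -> np.ndarray:
    """Encode an aptamer as its 20 mono- and dinucleotide frequencies.

    Components 1-4 are single-nucleotide counts divided by the sequence
    length L; components 5-20 are overlapping dinucleotide counts divided
    by L - 1.  ``t`` and ``u`` are merged.  Each block sums to 1.
    """
    seq = _normalize_sequence(record.sequence)
    length = len(seq)
    if length < 2:
        raise ValueError(
            f"aptamer {record.id!r}: length {length} < 2, dinucleotide "
            "frequencies undefined"
        )
    vec = np.zeros(20, dtype=float)
    for ch in seq:
        vec[ALPHABET.index(ch)] += 1.0
    vec[:4] /= length
    di_index = {d: 4 + i for i, d in enumerate(_DINUCLEOTIDES)}
    for i in range(length - 1):
        vec[di_index[seq[i : i + 2]]] += 1.0
    vec[4:] /= length - 1
    return vec


def filter_descriptors(
    table: Sequence[CompoundRecord],
    *,
    variance_epsilon: float = 0.0,
) -> tuple[list[CompoundRecord], list[str]]:
    """Drop descriptors that are missing for any compound or have zero variance.

    Variance is "zero" when the population variance across compounds is
    <= ``variance_epsilon`` (default 0: exact constancy).  Retained column
    order is preserved.  Compounds are never dropped.
    """
    if not table:
        raise ValueError("empty descriptor table")
    names = list(table[0].descriptors.keys())
    for rec in table[1:]:
        if list(rec.descriptors.keys()) != names:
            raise ValueError(
                f"compound {rec.id!r}: descriptor names differ from first record"
            )
    retained: list[str] = []
    for name in names:
        values = [rec.descriptors[name] for rec in table]
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
            continue
        if np.var(np.asarray(values, dtype=float)) <= variance_epsilon:
            continue
        retained.append(name)
    if not retained:
        raise ValueError(
            "no descriptor survives filtering: every column is constant or has "
            "missing values (a single-compound table always fails, since any "
            "one value has zero variance)"
        )
    filtered = [
        CompoundRecord(rec.id, {n: float(rec.descriptors[n]) for n in retained})
        for rec in table
    ]
    return filtered, retained


def assemble_vector(
    aptamer: AptamerRecord,
    compound: CompoundRecord,
    schema: FeatureSchema,
) -> np.ndarray:
    """Concatenate the aptamer block and the compound block in schema order."""
    apt = encode_aptamer(aptamer)
    comp = np.empty(len(schema) - 20, dtype=float)
    for j, name in enumerate(schema.compound_names):
        if name not in compound.descriptors:
            raise KeyError(
                f"compound {compound.id!r}: descriptor {name!r} required by "
                "schema is absent"
            )
        comp[j] = compound.descriptors[name]
    vec = np.concatenate([apt, comp])
    if not np.all(np.isfinite(vec)):
        raise ValueError(
            f"pair ({compound.id!r}, {aptamer.id!r}): non-finite feature value"
        )
    return vec


# ---------------------------------------------------------------------------
# File I/O: FASTA sequences, descriptor tables, category maps, interactions
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[AptamerRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate aptamer id {rec.id!r}")
        seen.add(rec.id)
        records.append(AptamerRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[AptamerRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_descriptor_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound x descriptor table (TSV/CSV, first column = compound id).

    Non-numeric cells are treated as missing values.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus >= 1 descriptor column")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate compound id {dup!r}")
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    records = []
    for i, cid in enumerate(ids):
        records.append(
            CompoundRecord(id=cid, descriptors=dict(zip(values.columns, values.iloc[i])))
        )
    return records


def write_descriptor_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    names = list(records[0].descriptors.keys())
    rows = [[rec.id] + [rec.descriptors[n] for n in names] for rec in records]
    df = pd.DataFrame(rows, columns=["compound_id"] + names)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read the descriptor -> category sidecar (YAML or JSON)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: expected a mapping descriptor -> category")
    return {str(k): str(v) for k, v in mapping.items()}


def write_category_map(mapping: Mapping[str, str], path: str | Path) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(dict(mapping), indent=1, sort_keys=True))
    else:
        Path(path).write_text(yaml.safe_dump(dict(mapping), sort_keys=True))


def read_interactions(path: str | Path) -> list["InteractionPair"]:
    """Read an interaction list TSV with columns compound_id, aptamer_id, label."""
    from .dataset import InteractionPair  # local import avoids a cycle

    df = _read_table(path)
    required = {"compound_id", "aptamer_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(required)}")
    pairs = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.compound_id), str(row.aptamer_id))
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate pair {key}")
        seen.add(key)
        label = str(row.label).lower()
        if label not in ("positive", "negative"):
            raise ValueError(
                f"{path}:{lineno}: label must be positive/negative, got {row.label!r}"
            )
        pairs.append(InteractionPair(key[0], key[1], label))
    return pairs


def write_interactions(pairs: Sequence["InteractionPair"], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.compound_id, p.aptamer_id, p.label) for p in pairs],
        columns=["compound_id", "aptamer_id", "label"],
    )
    df.to_csv(path, sep="\t", index=False)
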