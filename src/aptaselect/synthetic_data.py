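"""Synthetic aptamer-compound interaction studies with planted signal.

The generator emits the three standard inputs (aptamer FASTA, compound
descriptor table, labeled interaction list) plus a ground-truth record
of the planted structure, so that feature ranking, redundancy handling
and incremental feature selection can all be validated against known
answers without any external data.

Structure of a study:

* aptamer sequences drawn uniformly over {a, c, g, u};
* a descriptor table whose columns are (i) *informative* standard-normal
  columns that enter the pair-labeling score, (ii) *redundant* noisy
  copies of informative columns, and (iii) *pure-noise* columns
  independent of everything;
* a latent score for every (compound, aptamer) cell,

      z = effect_size * (1/sqrt(k)) * sum_j x_j  +  beta_apt * v_a  +  eps,

  with x_j the compound's k informative columns, v_a the aptamer's
  standardized adenine frequency (zero by default), and eps pair-level
  Gaussian noise — the steep-logistic limit of a logistic response:
  a pair is positive exactly when z exceeds a threshold, chosen as the
  order statistic that makes the positive fraction hit its target;
* negative pairs drawn by the random-pairing rule from the sub-threshold
  cells.

Descriptor type categories are assigned round-robin over the five
compound descriptor families so that reporting code sees every category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import POSITIVE, InteractionPair, generate_negatives
from .encoding import (
    ALPHABET,
    COMPOUND_CATEGORIES,
    AptamerRecord,
    CompoundRecord,
    write_category_map,
    write_descriptor_table,
    write_fasta,
    write_interactions,
)

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticStudy", "generate_study", "write_study"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic interaction study.

    Defaults give a mid-sized recovery benchmark: 450 pairs at a 1:2
    positive:negative ratio over a 400 x 20 compound-aptamer grid,
    three informative descriptor columns carrying the pair-labeling
    signal at effect size 2, two noisy redundant copies, and 21
    pure-noise columns (26 descriptors, hence 46 features once the
    20-component aptamer block is prepended).  The wide compound grid
    keeps positives spread over many distinct compounds: because
    descriptor values repeat across all pairs of a compound, the
    effective sample size for column-label association is the number of
    distinct compounds involved, and a narrow grid would let chance
    compound-level correlations mask the planted signal.
    """

    n_compounds: int = 400
    n_aptamers: int = 20
    n_pairs: int = 450
    seq_length_range: tuple[int, int] = (25, 80)
    n_informative: int = 3
    n_redundant: int = 2
    n_noise: int = 21
    effect_size: float = 2.0
    redundancy_noise_sd: float = 0.3
    pair_noise_sd: float = 1.0
    aptamer_effect_size: float = 0.0
    positive_fraction_target: float = 1 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_aptamers", "n_pairs", "n_informative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_redundant", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")
        for name in (
            "effect_size",
            "redundancy_noise_sd",
            "pair_noise_sd",
            "aptamer_effect_size",
            "positive_fraction_target",
        ):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if name != "positive_fraction_target" and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.positive_fraction_target < 1):
            raise ValueError("positive_fraction_target must lie in (0, 1)")
        lo, hi = self.seq_length_range
        if lo < 2 or hi < lo:
            raise ValueError("seq_length_range must be (lo, hi) with 2 <= lo <= hi")
        if self.n_pairs > self.n_compounds * self.n_aptamers:
            raise ValueError(
                "n_pairs exceeds the number of compound x aptamer cells"
            )

    @property
    def n_descriptors(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic study.

    Indices refer to descriptor table columns (0-based); add 20 to get
    positions in the assembled interaction feature vector.
    """

    informative_indices: tuple[int, ...]
    redundant_parent_map: dict[int, int]
    noise_indices: tuple[int, ...]
    pair_scores: dict[tuple[str, str], float]
    threshold: float

    def __post_init__(self) -> None:
        info = set(self.informative_indices)
        for child, parent in self.redundant_parent_map.items():
            if parent not in info:
                raise ValueError(
                    f"redundant column {child} has non-informative parent {parent}"
                )


@dataclass(frozen=True)
class SyntheticStudy:
    aptamers: tuple[AptamerRecord, ...]
    compounds: tuple[CompoundRecord, ...]
    category_map: dict[str, str]
    pairs: tuple[InteractionPair, ...]
    ground_truth: GroundTruth
    spec: SyntheticSpec


def _random_sequences(rng: np.random.Generator, spec: SyntheticSpec) -> list[AptamerRecord]:
    lo, hi = spec.seq_length_range
    records = []
    letters = np.array(list(ALPHABET))
    for i in range(spec.n_aptamers):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length))
        records.append(AptamerRecord(id=f"apt_{i:04d}", sequence=seq))
    return records


def _descriptor_names(spec: SyntheticSpec) -> list[str]:
    names = [f"inf_{j:03d}" for j in range(spec.n_informative)]
    names += [f"red_{j:03d}" for j in range(spec.n_redundant)]
    names += [f"noise_{j:03d}" for j in range(spec.n_noise)]
    return names


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate a complete synthetic study from a seeded spec.

    Identical specs (including seed) produce bit-identical studies.
    """
    rng = np.random.default_rng(spec.seed)
    aptamers = _random_sequences(rng, spec)

    k = spec.n_informative
    informative = rng.normal(size=(spec.n_compounds, k))
    redundant = np.empty((spec.n_compounds, spec.n_redundant))
    parent_map: dict[int, int] = {}
    for j in range(spec.n_redundant):
        parent = j % k
        parent_map[k + j] = parent
        redundant[:, j] = informative[:, parent] + rng.normal(
            scale=spec.redundancy_noise_sd, size=spec.n_compounds
        )
    noise = rng.normal(size=(spec.n_compounds, spec.n_noise))
    table = np.hstack([informative, redundant, noise])

    names = _descriptor_names(spec)
    category_map = {
        name: COMPOUND_CATEGORIES[j % len(COMPOUND_CATEGORIES)]
        for j, name in enumerate(names)
    }
    compounds = tuple(
        CompoundRecord(
            id=f"cmp_{i:04d}",
            descriptors={n: float(table[i, j]) for j, n in enumerate(names)},
        )
        for i in range(spec.n_compounds)
    )

    # Latent pair score over the full compound x aptamer grid.
    compound_score = spec.effect_size * informative.sum(axis=1) / math.sqrt(k)
    if spec.aptamer_effect_size > 0:
        freq_a = np.array(
            [a.sequence.lower().count("a") / len(a.sequence) for a in aptamers]
        )
        sd = freq_a.std()
        apt_score = (freq_a - freq_a.mean()) / (sd if sd > 0 else 1.0)
    else:
        apt_score = np.zeros(spec.n_aptamers)
    eps = rng.normal(scale=spec.pair_noise_sd, size=(spec.n_compounds, spec.n_aptamers))
    z = (
        compound_score[:, None]
        + spec.aptamer_effect_size * apt_score[None, :]
        + eps
    )

    n_pos = int(round(spec.positive_fraction_target * spec.n_pairs))
    n_pos = max(1, min(n_pos, spec.n_pairs - 1))
    flat = z.ravel()
    # threshold = n_pos-th largest score: cells strictly above it are positive
    order = np.argsort(flat, kind="stable")
    pos_cells = order[-n_pos:]
    threshold = float(flat[order[-n_pos]])
    n_apt = spec.n_aptamers
    positives = [
        InteractionPair(
            compound_id=f"cmp_{cell // n_apt:04d}",
            aptamer_id=f"apt_{cell % n_apt:04d}",
            label=POSITIVE,
        )
        for cell in sorted(pos_cells.tolist())
    ]

    n_neg = spec.n_pairs - n_pos
    neg_seed = int(rng.integers(2**31))
    negatives = generate_negatives(
        positives,
        [c.id for c in compounds],
        [a.id for a in aptamers],
        ratio=n_neg / n_pos,
        seed=neg_seed,
    )
    pairs = tuple(positives) + tuple(negatives)

    pair_scores = {
        (p.compound_id, p.aptamer_id): float(
            z[int(p.compound_id[4:]), int(p.aptamer_id[4:])]
        )
        for p in pairs
    }
    truth = GroundTruth(
        informative_indices=tuple(range(k)),
        redundant_parent_map=parent_map,
        noise_indices=tuple(
            range(k + spec.n_redundant, k + spec.n_redundant + spec.n_noise)
        ),
        pair_scores=pair_scores,
        threshold=threshold,
    )
    return SyntheticStudy(
        aptamers=tuple(aptamers),
        compounds=compounds,
        category_map=category_map,
        pairs=pairs,
        ground_truth=truth,
        spec=spec,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study's standard input files plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "aptamers.fasta",
        "descriptors": outdir / "descriptors.tsv",
        "categories": outdir / "descriptor_categories.yaml",
        "interactions": outdir / "interactions.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(study.aptamers, paths["fasta"])
    write_descriptor_table(study.compounds, paths["descriptors"])
    write_category_map(study.category_map, paths["categories"])
    write_interactions(study.pairs, paths["interactions"])
    truth = study.ground_truth
    payload = {
        "informative_indices": list(truth.informative_indices),
        "noise_indices": list(truth.noise_indices),
        "redundant_parent_map": {str(kk): v for kk, v in truth.redundant_parent_map.items()},
        "threshold": truth.threshold,
        "pair_scores": {f"{c}\t{a}": s for (c, a), s in sorted(truth.pair_scores.items())},
        "spec": {
            f: getattr(study.spec, f)
            for f in (
                "n_compounds", "n_aptamers", "n_pairs", "seq_length_range",
                "n_informative", "n_redundant", "n_noise", "effect_size",
                "redundancy_noise_sd", "pair_noise_sd", "aptamer_effect_size",
                "positive_fraction_target", "seed",
            )
        },
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
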