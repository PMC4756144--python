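"""Incremental feature selection (IFS), optimal-model fitting and reporting.

IFS walks the mRMR feature list: for each prefix size i the dataset is
restricted to the first i ranked features and the prediction engine is
scored by stratified tenfold cross-validation.  Plotting MCC against i
gives the IFS curve; the optimal feature set is the prefix attaining the
maximum MCC (smallest prefix on ties), and the optimal model is the
engine refitted on all samples with that prefix.

Reporting covers the feature-type composition of a ranked-list head
(e.g. the top 10% of the MaxRel list) and of the optimal feature set:
for each type category, the count inside the set and the proportion of
that category's total feature budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import InteractionDataset, assemble_dataset, generate_negatives
from .encoding import (
    FeatureSchema,
    filter_descriptors,
    read_category_map,
    read_descriptor_table,
    read_fasta,
    read_interactions,
)
from .evaluation import MetricsReport, cross_validate, make_folds
from .models import Classifier, engine_factory
from .mrmr import DiscretizationSpec, RankedFeatureList, maxrel_list, mrmr_list

__all__ = [
    "IFSResult",
    "TypeDistribution",
    "run_ifs",
    "top_fraction_distribution",
    "selected_set_distribution",
    "optimal_model",
    "run_pipeline",
]


@dataclass(frozen=True)
class IFSResult:
    """Cross-validated metrics per prefix size of a ranked feature list."""

    sizes: tuple[int, ...]
    metrics: tuple[MetricsReport, ...]
    order: tuple[int, ...]  # the ranked list the prefixes are drawn from

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.metrics):
            raise ValueError("one metrics report per prefix size required")

    @property
    def optimal_index(self) -> int:
        """Prefix size attaining the maximum MCC; smallest size on ties."""
        mccs = [m.mcc for m in self.metrics]
        return self.sizes[int(np.argmax(mccs))]

    @property
    def optimal_metrics(self) -> MetricsReport:
        return self.metrics[self.sizes.index(self.optimal_index)]

    def optimal_features(self) -> tuple[int, ...]:
        return tuple(self.order[: self.optimal_index])

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": self.sizes,
                "sn": [m.sn for m in self.metrics],
                "sp": [m.sp for m in self.metrics],
                "acc": [m.acc for m in self.metrics],
                "mcc": [m.mcc for m in self.metrics],
            }
        )


def run_ifs(
    ranked: RankedFeatureList,
    dataset: InteractionDataset,
    engine: Callable[[], Classifier],
    folds: np.ndarray,
    i_max: int | None = None,
) -> IFSResult:
    """Evaluate every prefix IFS_i = {f_1, ..., f_i} of a ranked list."""
    n = len(ranked)
    if i_max is None:
        i_max = n
    if not (1 <= i_max <= n):
        raise ValueError(f"i_max must be in [1, {n}], got {i_max}")
    sizes = []
    metrics = []
    for i in range(1, i_max + 1):
        subset = ranked.order[:i]
        try:
            report, _ = cross_validate(engine, dataset.X, dataset.y, subset, folds)
        except Exception as exc:
            raise RuntimeError(f"IFS failed at prefix size {i}: {exc}") from exc
        sizes.append(i)
        metrics.append(report)
    return IFSResult(
        sizes=tuple(sizes), metrics=tuple(metrics), order=tuple(int(j) for j in ranked.order)
    )


@dataclass(frozen=True)
class TypeDistribution:
    """Per-category feature counts within a selected set, and the share of
    each category's total budget that the set captures."""

    counts: dict[str, int]
    totals: dict[str, int]
    head_size: int

    @property
    def proportions(self) -> dict[str, float]:
        return {
            cat: (self.counts[cat] / self.totals[cat] if self.totals[cat] else 0.0)
            for cat in self.counts
        }

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": [self.counts[c] for c in self.counts],
                "total": [self.totals[c] for c in self.counts],
                "proportion": [self.proportions[c] for c in self.counts],
            }
        )


def _distribution(indices: Sequence[int], schema: FeatureSchema, head_size: int) -> TypeDistribution:
    totals = schema.category_counts()
    counts = {cat: 0 for cat in totals}
    for idx in indices:
        counts[schema.categories[idx]] += 1
    return TypeDistribution(counts=counts, totals=totals, head_size=head_size)


def top_fraction_distribution(
    ranked: RankedFeatureList,
    schema: FeatureSchema,
    fraction: float = 0.10,
) -> TypeDistribution:
    """Type composition of the first round(fraction * n) ranked features."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(ranked)
    if n != len(schema):
        raise ValueError("ranked list and schema lengths differ")
    head = int(np.floor(fraction * n + 0.5))  # round half up
    head = max(head, 1)
    return _distribution([int(i) for i in ranked.order[:head]], schema, head)


def selected_set_distribution(
    feature_indices: Sequence[int], schema: FeatureSchema
) -> TypeDistribution:
    """Type composition of an arbitrary selected feature set."""
    return _distribution(feature_indices, schema, len(list(feature_indices)))


def optimal_model(
    dataset: InteractionDataset,
    ifs_result: IFSResult,
    engine: Callable[[], Classifier],
) -> tuple[Classifier, list[str]]:
    """Fit the engine on all samples restricted to the optimal prefix."""
    subset = list(ifs_result.optimal_features())
    model = engine()
    model.fit(dataset.X[:, subset], dataset.y)
    names = [dataset.schema.names[i] for i in subset]
    return model, names


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _metrics_dict(m: MetricsReport) -> dict:
    return {
        "sn": round(m.sn, 10),
        "sp": round(m.sp, 10),
        "acc": round(m.acc, 10),
        "mcc": round(m.mcc, 10),
        "mcc_undefined": m.mcc_undefined,
    }


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run the full analysis from standard input files and write the bundle.

    Config keys: paths (``fasta``, ``descriptors``, ``categories``,
    ``interactions``), ``seed``, ``engines`` (list of registered engine
    names), ``ratio`` (negatives per positive; negatives already present
    in the interaction list are used as-is when ``ratio`` is null),
    ``discretization`` ({mode, t}), ``i_max``, ``top_fraction``, ``k_folds``.
    Outputs: MaxRel/mRMR lists (TSV), per-engine IFS curves (TSV),
    metrics and manifest (JSON), per-pair predictions of the best model
    (TSV), type-distribution tables (TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    engines = list(config.get("engines", ["nna"]))
    disc_cfg = dict(config.get("discretization", {}))
    disc = DiscretizationSpec(
        mode=disc_cfg.get("mode", "three-state-sigma"), t=float(disc_cfg.get("t", 1.0))
    )
    top_fraction = float(config.get("top_fraction", 0.10))
    k_folds = int(config.get("k_folds", 10))

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    aptamers = stage("read_fasta", read_fasta, config["fasta"])
    compounds = stage("read_descriptors", read_descriptor_table, config["descriptors"])
    category_map = stage("read_categories", read_category_map, config["categories"])
    pairs = stage("read_interactions", read_interactions, config["interactions"])

    compounds, retained = stage("filter_descriptors", filter_descriptors, compounds)
    schema = stage("build_schema", FeatureSchema.build, retained, category_map)

    ratio = config.get("ratio", None)
    if ratio is not None:
        positives = [p for p in pairs if p.label == "positive"]
        negatives = stage(
            "generate_negatives",
            generate_negatives,
            positives,
            [c.id for c in compounds],
            [a.id for a in aptamers],
            ratio=float(ratio),
            seed=seed,
        )
        pairs = positives + negatives
    dataset = stage("assemble_dataset", assemble_dataset, pairs, aptamers, compounds, schema)

    maxrel = stage("maxrel", maxrel_list, dataset, disc)
    mrmr = stage("mrmr", mrmr_list, dataset, disc)
    for ranked, fname in ((maxrel, "maxrel_list.tsv"), (mrmr, "mrmr_list.tsv")):
        pd.DataFrame(
            {
                "rank": np.arange(1, len(ranked) + 1),
                "feature": [schema.names[i] for i in ranked.order],
                "type": [schema.categories[i] for i in ranked.order],
                "score": np.round(ranked.scores, 10),
            }
        ).to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")

    top_dist = top_fraction_distribution(maxrel, schema, top_fraction)
    top_dist.frame().to_csv(
        outdir / "maxrel_top_distribution.tsv", sep="\t", index=False, float_format="%.10g"
    )

    folds = stage("make_folds", make_folds, dataset.y, k_folds, seed)
    i_max = config.get("i_max", None)
    summary: dict = {"engines": {}}
    best = None
    for name in engines:
        factory = engine_factory(name, seed)
        result = stage(f"ifs[{name}]", run_ifs, mrmr, dataset, factory, folds, i_max)
        result.curve_frame().to_csv(
            outdir / f"ifs_curve_{name}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary["engines"][name] = {
            "optimal_n_features": result.optimal_index,
            "optimal_metrics": _metrics_dict(result.optimal_metrics),
        }
        if best is None or result.optimal_metrics.mcc > best[1].optimal_metrics.mcc:
            best = (name, result, factory)

    best_name, best_result, best_factory = best
    subset = list(best_result.optimal_features())
    sel_dist = selected_set_distribution(subset, schema)
    sel_dist.frame().to_csv(
        outdir / "optimal_set_distribution.tsv", sep="\t", index=False, float_format="%.10g"
    )
    _, y_pred = cross_validate(best_factory, dataset.X, dataset.y, subset, folds)
    pd.DataFrame(
        {
            "compound": [p.compound_id for p in dataset.pairs],
            "aptamer": [p.aptamer_id for p in dataset.pairs],
            "predicted_class": ["positive" if v == 1 else "negative" for v in y_pred],
            "true_class": [p.label for p in dataset.pairs],
        }
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    model, selected_names = optimal_model(dataset, best_result, best_factory)
    summary.update(
        {
            "best_engine": best_name,
            "n_samples": dataset.n_samples,
            "n_features": dataset.n_features,
            "selected_features": selected_names,
        }
    )
    (outdir / "metrics.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = {
        "seed": seed,
        "engines": engines,
        "ratio": ratio,
        "discretization": {"mode": disc.mode, "t": disc.t},
        "k_folds": k_folds,
        "i_max": i_max,
        "top_fraction": top_fraction,
        "inputs": {
            k: str(config[k]) for k in ("fasta", "descriptors", "categories", "interactions")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary
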