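"""End-to-end refinement pipeline.

Stage order (the framework's decision flow):

1. min-max normalization to [0, 1]
2. per-feature entropy profile + relevance filter (drop low-information)
3. entropy weighting of the survivors
4. fractal augmentation (when per-patient mask dimensions are available)
5. sigmoid adaptive weighting and composition of the refined set
6. redundancy filter (greedy, priority = adaptive weight)
7. stability filter (when replicate extractions are available)
8. optional cross-validated evaluation (when labels are available)

Identical inputs and seed produce byte-identical JSON reports; the run
manifest records stage-by-stage feature counts so the filtering funnel can be
audited and the run reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FeatureMatrix, PipelineConfig, ReplicateSet, min_max_normalize
from .entropy import estimate_entropy, entropy_weight_transform, relevance_filter
from .errors import SerfeError, ValidationError
from .evaluation import EvalReport, evaluate
from .filters import (
    FilterReport,
    assemble_filter_report,
    icc_estimate,
    redundancy_filter,
    stability_filter,
)
from .fractal import fractal_augment
from .weighting import RefinedFeatureSet, compose_refined, compute_adaptive_weights


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stage_counts: dict[str, int]
    fractal_augmented: bool
    stability_assessed: bool
    evaluated: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SerfeResult:
    refined: RefinedFeatureSet
    filter_report: FilterReport
    eval_report: EvalReport | None
    manifest: RunManifest
    entropy_profile_table: pd.DataFrame
    icc_table: pd.DataFrame | None


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except SerfeError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_serfe(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    replicates: ReplicateSet | None = None,
    fractal_dims: np.ndarray | dict[str, float] | None = None,
    config: PipelineConfig | None = None,
    run_evaluation: bool | None = None,
) -> SerfeResult:
    """Run the full refinement pipeline on a feature table.

    Parameters
    ----------
    features : FeatureMatrix
        Raw feature table (any scale; normalized internally).
    labels : array, optional
        Binary labels; defaults to the table's own labels when present.
    replicates : ReplicateSet, optional
        Repeated extractions for ICC-based stability filtering; when absent
        the stability stage is skipped and reported as not assessed.
    fractal_dims : array or mapping, optional
        Per-patient mask box-counting dimensions; when absent the fractal
        shift is a no-op (dimension 0 for every patient).
    run_evaluation : bool, optional
        Force evaluation on/off; defaults to "labels available".
    """
    config = config or PipelineConfig()
    if labels is None:
        labels = features.labels
    if run_evaluation is None:
        run_evaluation = labels is not None
    if run_evaluation and labels is None:
        raise ValidationError("evaluation requested but no labels available")

    initial_names = list(features.feature_names)
    counts = {"initial": features.n_features}

    normalized, _ = _stage("normalize", min_max_normalize, features)
    profile = _stage(
        "entropy", estimate_entropy, normalized,
        bins=config.entropy_bins, floor=config.entropy_floor, alpha=config.alpha,
    )
    filtered, dropped_low = _stage("relevance_filter", relevance_filter, normalized, profile)
    counts["post_entropy_filter"] = filtered.n_features
    kept_profile_idx = [profile.feature_names.index(f) for f in filtered.feature_names]
    sub_profile = dataclasses.replace(
        profile,
        feature_names=list(filtered.feature_names),
        entropy_bits=profile.entropy_bits[kept_profile_idx],
    )
    transformed = _stage("entropy_transform", entropy_weight_transform, filtered, sub_profile)

    if fractal_dims is None:
        dims = np.zeros(features.n_patients)
        augmented = transformed
        fractal_used = False
    else:
        augmented = _stage("fractal_augment", fractal_augment, transformed, fractal_dims, config.beta)
        fractal_used = config.beta > 0

    weights = _stage(
        "adaptive_weights", compute_adaptive_weights, augmented,
        gamma=config.gamma, score_statistic=config.score_statistic,
    )
    refined_all = _stage("compose", compose_refined, augmented, weights)

    priority = dict(zip(weights.feature_names, weights.weights))
    reduced, dropped_red, red_rate = _stage(
        "redundancy_filter", redundancy_filter, refined_all.matrix,
        threshold=config.redundancy_threshold, priority=priority,
    )
    counts["post_redundancy_filter"] = reduced.n_features

    icc_table = None
    dropped_unstable: list[str] = []
    stability_score = None
    icc_map = None
    if replicates is not None:
        candidate_reps = _stage(
            "stability_filter", replicates.select_features, reduced.feature_names
        )
        icc_table = _stage("stability_filter", icc_estimate, candidate_reps)
        stable_names, stability_score = _stage(
            "stability_filter", stability_filter, icc_table, config.icc_threshold
        )
        dropped_unstable = [f for f in reduced.feature_names if f not in set(stable_names)]
        reduced = reduced.select_features(stable_names)
        icc_map = dict(zip(icc_table["feature"], icc_table["icc"]))
    counts["post_stability_filter"] = reduced.n_features

    final_weights_idx = [weights.feature_names.index(f) for f in reduced.feature_names]
    final_weights = dataclasses.replace(
        weights,
        feature_names=list(reduced.feature_names),
        scores=weights.scores[final_weights_idx],
        weights=weights.weights[final_weights_idx],
    )
    scalar = refined_all.serfe_scalar
    provenance = _build_provenance(
        initial_names, profile, dropped_low, dropped_red, dropped_unstable, weights
    )
    refined = RefinedFeatureSet(
        matrix=reduced, weights=final_weights, serfe_scalar=scalar, provenance=provenance
    )

    report = assemble_filter_report(
        initial_features=initial_names,
        dropped_low_entropy=dropped_low,
        dropped_redundant=dropped_red,
        redundancy_rate=red_rate,
        dropped_unstable=dropped_unstable or None,
        stability_score=stability_score,
        icc=icc_map,
        thresholds={
            "entropy_floor_bits": config.entropy_floor,
            "redundancy_threshold": config.redundancy_threshold,
            "icc_threshold": config.icc_threshold,
        },
    )

    eval_report: EvalReport | None = None
    if run_evaluation:
        eval_report = _stage("evaluate", evaluate, refined, labels, config)

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        stage_counts=counts,
        fractal_augmented=fractal_used,
        stability_assessed=replicates is not None,
        evaluated=eval_report is not None,
    )
    return SerfeResult(
        refined=refined,
        filter_report=report,
        eval_report=eval_report,
        manifest=manifest,
        entropy_profile_table=profile.to_table(),
        icc_table=icc_table,
    )


def _build_provenance(
    initial_names, profile, dropped_low, dropped_red, dropped_unstable, weights
) -> pd.DataFrame:
    factor = dict(zip(profile.feature_names, profile.factors))
    weight = dict(zip(weights.feature_names, weights.weights))
    status = {}
    for f in dropped_low:
        status[f] = "dropped:low_entropy"
    for f in dropped_red:
        status[f] = "dropped:redundant"
    for f in dropped_unstable:
        status[f] = "dropped:unstable"
    rows = []
    for f in initial_names:
        rows.append(
            {
                "feature": f,
                "entropy_factor": factor.get(f, np.nan),
                "weight": weight.get(f, np.nan),
                "status": status.get(f, "retained"),
            }
        )
    return pd.DataFrame(rows)
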