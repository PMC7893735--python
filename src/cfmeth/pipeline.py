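"""End-to-end composition: simulated study -> DMRs -> ratios -> classifiers.

`run_study` wires the whole chain on synthetic data; `run_analysis` does the
analysis half on any :class:`~cfmeth.simulate.StudyData`-shaped inputs, so
the same code path serves loaded real-schema data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import DMR, call_dmrs, hypo_dmrs, segment_candidate_regions
from .models import (
    CfMethModel,
    CombinedModel,
    ModelResult,
    combine_features,
    evaluate,
    select_cutoff,
    select_markers,
    train_cfmeth,
    train_combined,
)
from .origin import MarkerProfileSet, RatioConfig, ReferencePanel, build_marker_profiles, \
    build_reference_panel
from .simulate import CohortRecord, StudyConfig, StudyData, simulate_study


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side knobs, from DMR calling through model evaluation."""

    min_cpgs: int = 4
    max_gap_bp: int = 500
    min_delta: float = 0.2
    alpha: float = 0.05
    panel_epsilon: float = 0.01
    ratio: RatioConfig = RatioConfig()
    n_markers: int = 10
    n_folds: int = 10
    n_trees: int = 500
    max_fnr: float = 0.02
    n_boot: int = 2000


@dataclass
class StudyResult:
    """Everything the pipeline produced, discovery and validation."""

    dmrs: list[DMR]
    panel: ReferencePanel
    markers: list[str]
    discovery_profiles: MarkerProfileSet
    validation_profiles: MarkerProfileSet | None
    cfmeth: CfMethModel
    combined: CombinedModel
    threshold: float
    discovery: ModelResult  # combined model on discovery (out-of-fold scores)
    validation: ModelResult | None
    cfmeth_discovery: ModelResult
    cfmeth_validation: ModelResult | None
    discovery_records: pd.DataFrame
    validation_records: pd.DataFrame | None

    @property
    def discovery_fnr_percent(self) -> float:
        """False-negative rate (%) of the combined model at the threshold."""
        r = self.discovery
        return 100.0 * r.fn / (r.fn + r.tp)


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records]).set_index("sample_id")
    return df


def run_analysis(
    data: StudyData,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> StudyResult:
    """DMR discovery, origin inference, and model building on study data.

    Validation samples are scored by models refit on discovery only and
    imputed with discovery benign medians; their labels enter only at
    evaluation time.
    """
    cfg = config or PipelineConfig()
    cpg_map = data.cpg_map

    regions = segment_candidate_regions(cpg_map, cfg.min_cpgs, cfg.max_gap_bp)
    dmrs = call_dmrs(regions, data.tissues, cpg_map, cfg.min_delta, cfg.alpha)
    markers_pool = hypo_dmrs(dmrs)
    panel = build_reference_panel(markers_pool, data.tissues, cpg_map, cfg.panel_epsilon)

    disc_profiles = build_marker_profiles(data.discovery_samples, panel, cfg.ratio)
    disc_records = records_to_frame(data.discovery_records).loc[disc_profiles.ratios.index]
    disc_labels = disc_records["label"].to_numpy()

    k = min(cfg.n_markers, disc_profiles.ratios.shape[1])
    markers = select_markers(disc_profiles.ratios, disc_labels, k=k)

    cfmeth = train_cfmeth(
        disc_profiles.ratios, disc_labels, markers,
        n_folds=cfg.n_folds, seed=seed, n_trees=cfg.n_trees,
    )
    disc_features = combine_features(cfmeth.oof_scores, disc_records)
    combined = train_combined(disc_features, disc_labels, seed=seed, n_folds=cfg.n_folds)

    threshold = select_cutoff(combined.oof_scores, disc_labels, cfg.max_fnr)
    disc_eval = evaluate(
        combined.oof_scores, disc_labels, threshold,
        stages=disc_records["stage"], n_boot=cfg.n_boot, seed=seed,
    )
    cfmeth_disc_eval = evaluate(
        cfmeth.oof_scores, disc_labels, select_cutoff(cfmeth.oof_scores, disc_labels, cfg.max_fnr),
        stages=disc_records["stage"], n_boot=cfg.n_boot, seed=seed,
    )

    val_profiles = val_eval = cfmeth_val_eval = None
    val_records = None
    if data.validation_samples:
        # keep every panel column (imputing from discovery) so the refit
        # models always find their marker columns
        val_profiles = build_marker_profiles(
            data.validation_samples, panel, cfg.ratio,
            max_missing_fraction=1.0,
            impute_values=disc_profiles.impute_values,
        )
        val_records = records_to_frame(data.validation_records).loc[val_profiles.ratios.index]
        val_cfmeth_scores = cfmeth.score(val_profiles.ratios)
        val_features = combine_features(val_cfmeth_scores, val_records)
        val_combined_scores = combined.score(val_features)
        val_labels = val_records["label"].to_numpy()
        val_eval = evaluate(
            val_combined_scores, val_labels, threshold,
            stages=val_records["stage"], n_boot=cfg.n_boot, seed=seed,
        )
        cfmeth_val_eval = evaluate(
            val_cfmeth_scores, val_labels, 0.5,
            stages=val_records["stage"], n_boot=cfg.n_boot, seed=seed,
        )

    return StudyResult(
        dmrs=dmrs, panel=panel, markers=markers,
        discovery_profiles=disc_profiles, validation_profiles=val_profiles,
        cfmeth=cfmeth, combined=combined, threshold=threshold,
        discovery=disc_eval, validation=val_eval,
        cfmeth_discovery=cfmeth_disc_eval, cfmeth_validation=cfmeth_val_eval,
        discovery_records=disc_records, validation_records=val_records,
    )


def run_study(
    study_config: StudyConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[StudyData, StudyResult]:
    """Simulate a full study and run the analysis pipeline on it."""
    data = simulate_study(study_config, seed=seed)
    result = run_analysis(data, pipeline_config, seed=seed)
    return data, result
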