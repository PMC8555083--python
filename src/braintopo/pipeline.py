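"""End-to-end orchestration: cohort -> features -> classifier -> attribution.

These helpers run the whole chain in memory for simulation studies and
tests; the CLI wraps the same functions around files.
"""

from __future__ import annotations

import numpy as np

from braintopo.classify import (
    CvResult,
    PermutationResult,
    cross_validate_pipeline,
    fit_interpretation_model,
    permutation_test,
)
from braintopo.attribution import ContributionReport, backward_propagate_contributions
from braintopo.cohort import CohortConfig, SubjectRecord, simulate_cohort
from braintopo.connectome import partial_correlation, sparsity_grid
from braintopo.features import FeatureTable, assemble_features, feature_table
from braintopo.io import RunConfig
from braintopo.sae import SaeConfig
from braintopo.timeseries import motion_exclusion, preprocess
from braintopo.topology import compute_metric_curves


def cohort_config_from_run(cfg: RunConfig) -> CohortConfig:
    return CohortConfig(
        n_group_a=cfg.n_group_a,
        n_group_b=cfg.n_group_b,
        n_regions=cfg.n_regions,
        n_timepoints=cfg.n_timepoints,
        tr_seconds=cfg.tr_seconds,
        effect_regions=tuple(cfg.effect_regions),
        effect_size=cfg.effect_size,
        noise_sd=cfg.noise_sd,
        motion_severity=cfg.motion_severity,
        signal_band=(cfg.low_hz, cfg.high_hz),
        seed=cfg.seed,
    )


def sae_config_from_run(cfg: RunConfig, seed_offset: int = 0) -> SaeConfig:
    return SaeConfig(
        hidden_sizes=tuple(cfg.sae_hidden_sizes),
        pretrain_epochs=cfg.pretrain_epochs,
        finetune_epochs=cfg.finetune_epochs,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed + seed_offset,
    )


def subjects_to_features(
    records: list[SubjectRecord], cfg: RunConfig
) -> tuple[FeatureTable, list[str]]:
    """Preprocess, estimate networks, and assemble features for a cohort.

    Motion-excluded subjects are flagged and left out of the table
    (their ids are returned separately).
    """
    grid = sparsity_grid(cfg.s_min, cfg.s_max, cfg.s_step)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(records)) % (2**31 - 1)
    vectors = []
    excluded: list[str] = []
    for i, rec in enumerate(records):
        if motion_exclusion(rec.motion, cfg.max_translation_mm, cfg.max_rotation_deg):
            excluded.append(rec.subject_id)
            continue
        clean = preprocess(
            rec.timeseries,
            rec.motion,
            n_discard=cfg.n_discard,
            low_hz=cfg.low_hz,
            high_hz=cfg.high_hz,
            regress_global_signal=cfg.regress_global_signal,
        )
        pc = partial_correlation(clean, shrinkage=cfg.shrinkage)
        curves = compute_metric_curves(
            pc, grid, null_ensemble_size=cfg.null_ensemble_size, seed=int(seeds[i])
        )
        vectors.append(assemble_features(curves, rec.subject_id, rec.group))
    return feature_table(vectors), excluded


def simulate_and_extract(cfg: RunConfig) -> tuple[FeatureTable, list[str]]:
    """Simulate the cohort defined by ``cfg`` and extract its feature table."""
    records = simulate_cohort(cohort_config_from_run(cfg))
    return subjects_to_features(records, cfg)


def classify_features(
    table: FeatureTable, cfg: RunConfig, positive_group: str = "A"
) -> CvResult:
    return cross_validate_pipeline(
        table.matrix,
        table.labels01(positive_group),
        k_outer=cfg.k_outer,
        seed=cfg.seed,
        sae_config=sae_config_from_run(cfg),
        c_grid=tuple(cfg.c_grid),
        k_inner=cfg.k_inner,
    )


def permutation_significance(
    table: FeatureTable,
    cfg: RunConfig,
    observed: float | None = None,
    positive_group: str = "A",
) -> PermutationResult:
    return permutation_test(
        table.matrix,
        table.labels01(positive_group),
        n_perm=cfg.n_permutations,
        seed=cfg.seed,
        k_outer=cfg.k_outer,
        sae_config=sae_config_from_run(cfg),
        c_grid=tuple(cfg.c_grid),
        k_inner=cfg.k_inner,
        observed=observed,
    )


def attribute_features(
    table: FeatureTable,
    cfg: RunConfig,
    top_k: int = 10,
    seed_offset: int = 0,
    positive_group: str = "A",
) -> ContributionReport:
    """Fit the interpretation SAE on the full cohort and run the backward pass."""
    model, _ = fit_interpretation_model(
        table.matrix,
        table.labels01(positive_group),
        sae_config_from_run(cfg, seed_offset=seed_offset),
    )
    return backward_propagate_contributions(model, table.names, top_k=top_k)
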