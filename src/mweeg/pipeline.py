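"""End-to-end study driver: synthetic cohort -> feature tables -> modeling
datasets -> predictor selection -> model family -> comparison report.

Mirrors the study protocol: per-subject feature extraction, exclusion of
subjects with a flat mind-wandering report (range < 2 Likert points),
within-subject normalization, subject-wise train/test split, |z| > 5 outlier
removal, scaling by training statistics, correlation-filter threshold sweep,
grid-searched ε-SVR fits under the electrode budget, and held-out evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dataset as ds
from . import evaluation, selection, svr
from .bands import BandScheme
from .features import build_feature_table, normalize_within_subject
from .simulate import Annotations, GeneratorConfig, generate_cohort

__all__ = ["StudyResult", "extract_cohort_features", "run_study"]


@dataclass
class StudyResult:
    report: evaluation.ModelReport
    family: svr.ModelFamily
    screen: pd.Series
    sets: list[selection.PredictorSet]
    single_set: selection.PredictorSet
    train: ds.ModelingDataset
    test: ds.ModelingDataset
    excluded_subjects: list
    behavioral: evaluation.BehavioralResult


def extract_cohort_features(cohort, scheme: BandScheme | None = None
                            ) -> tuple[pd.DataFrame, dict[int, Annotations]]:
    """Raw (pre-normalization) section-feature table for a generated cohort."""
    tables, annotations = [], {}
    for subject, (rec, ann, _truth) in enumerate(cohort):
        tables.append(build_feature_table(rec, ann, subject, scheme=scheme))
        annotations[subject] = ann
    return pd.concat(tables, ignore_index=True), annotations


def run_study(config: GeneratorConfig,
              test_fraction: float = 1.0 / 3.0,
              min_mw_range: float = 2.0,
              z_max: float = 5.0,
              threshold_step: float = 0.01,
              electrode_budget: int = 9,
              k_folds: int = 10,
              c_grid=svr.DEFAULT_C_GRID,
              epsilon_grid=svr.DEFAULT_EPSILON_GRID,
              scheme: BandScheme | None = None) -> StudyResult:
    """Run the whole pipeline on a synthetic cohort defined by *config*.

    All randomness (cohort, split, CV folds) derives from ``config.seed``.
    """
    cohort = generate_cohort(config)
    raw, annotations = extract_cohort_features(cohort, scheme)

    raw, excluded = ds.exclude_subjects(raw, min_mw_range)
    annotations = {s: a for s, a in annotations.items() if s not in excluded}

    normalized = normalize_within_subject(raw)
    split_seed = (config.seed * 2654435761 + 1) % (2**31 - 1)
    train_df, test_df = ds.split_by_subject(normalized, test_fraction,
                                            seed=split_seed)
    train_df = ds.remove_outlier_sections(train_df, z_max)
    test_df = ds.remove_outlier_sections(test_df, z_max)
    train, test = ds.scale_by_training(train_df, test_df)

    screen = selection.correlation_screen(train)
    sets = selection.build_threshold_sets(screen, threshold_step)
    single = selection.single_best_set(screen)

    cv_seed = (config.seed * 40503 + 7) % (2**31 - 1)
    family = svr.fit_model_family(train, sets, single,
                                  electrode_budget=electrode_budget,
                                  k_folds=k_folds, seed=cv_seed,
                                  c_grid=c_grid, epsilon_grid=epsilon_grid)

    behavioral = evaluation.behavioral_validation(annotations)
    report = evaluation.build_report(family.models, test, annotations)
    return StudyResult(report=report, family=family, screen=screen, sets=sets,
                       single_set=single, train=train, test=test,
                       excluded_subjects=excluded, behavioral=behavioral)
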