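"""Modeling-dataset assembly: subject exclusion, subject-wise split, outlier
removal, and scaling by training statistics.

The invariant guarded throughout: nothing computed on the training side may
depend on test rows.  Scaling statistics come from the training partition
only, and whole subjects belong to exactly one partition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import feature_columns

__all__ = [
    "ModelingDataset",
    "exclude_subjects",
    "split_by_subject",
    "remove_outlier_sections",
    "scale_by_training",
]


@dataclass
class ModelingDataset:
    """Predictor matrix + response, scaled by training statistics."""

    X: np.ndarray                    # (samples, features)
    y: np.ndarray                    # (samples,)
    subjects: np.ndarray             # (samples,)
    feature_names: tuple[str, ...]
    split: str                       # "train" | "test"
    scale_mean: np.ndarray           # training per-feature mean
    scale_sd: np.ndarray             # training per-feature SD (population)

    @property
    def n(self) -> int:
        return len(self.y)

    def inverse_transform(self) -> np.ndarray:
        """Undo the training-statistics scaling of X (round-trip check)."""
        return self.X * self.scale_sd + self.scale_mean


def exclude_subjects(df: pd.DataFrame, min_mw_range: float = 2.0
                     ) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose raw probe-answer range (max - min) is below threshold.

    Must run on the raw (pre-normalization) table; mirrors the study rule that
    subjects reporting an MW range under two Likert points are uninformative.
    Returns the filtered table and the list of excluded subject ids.
    """
    rng = df.groupby("subject")["response"].agg(lambda s: s.max() - s.min())
    excluded = sorted(rng.index[rng < min_mw_range].tolist())
    if excluded:
        warnings.warn(f"excluded {len(excluded)} subject(s) with MW range "
                      f"< {min_mw_range}: {excluded}")
    return df[~df["subject"].isin(excluded)].reset_index(drop=True), excluded


def split_by_subject(df: pd.DataFrame, test_fraction: float = 1.0 / 3.0,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign whole subjects to train/test partitions, uniformly at random.

    The number of test subjects is round-half-up of n_subjects * test_fraction
    (43 subjects at 1/3 -> 14 test).  Both partitions must be non-empty.
    """
    subjects = sorted(pd.unique(df["subject"]).tolist())
    if len(subjects) < 3:
        raise ConfigurationError("split_by_subject: need >= 3 subjects")
    n_test = int(np.floor(len(subjects) * test_fraction + 0.5))
    if n_test < 1 or n_test >= len(subjects):
        raise ConfigurationError(
            f"test_fraction: yields {n_test} test subjects of {len(subjects)}; "
            "both partitions must be non-empty")
    rng = np.random.default_rng(seed)
    test_subjects = set(rng.choice(len(subjects), size=n_test, replace=False))
    test_ids = {subjects[i] for i in test_subjects}
    is_test = df["subject"].isin(test_ids)
    return (df[~is_test].reset_index(drop=True),
            df[is_test].reset_index(drop=True))


def remove_outlier_sections(df: pd.DataFrame, z_max: float = 5.0) -> pd.DataFrame:
    """Drop rows in which any (already-normalized) feature exceeds |z| > z_max."""
    cols = feature_columns(df)
    vals = df[cols].to_numpy(dtype=float)
    keep = (np.abs(vals) <= z_max).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"removed {dropped} outlier section(s) with |z| > {z_max}")
    return df[keep].reset_index(drop=True)


def scale_by_training(train: pd.DataFrame, test: pd.DataFrame
                      ) -> tuple[ModelingDataset, ModelingDataset]:
    """Scale both partitions by the training partition's mean and SD.

    Training columns come out mean-0/SD-1; test columns are transformed with
    the same statistics (their post-scaling means need not be 0).  Columns
    with zero training variance are dropped from both partitions.
    """
    cols = feature_columns(train)
    if list(cols) != list(feature_columns(test)):
        raise ConfigurationError("train/test feature columns differ")
    xtr = train[cols].to_numpy(dtype=float)
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0)               # population convention
    zero = sd == 0
    if zero.any():
        bad = [cols[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"dropping zero-training-variance columns: {bad[:5]}"
                      + ("..." if len(bad) > 5 else ""))
    keep = ~zero
    kept_cols = tuple(c for c, k in zip(cols, keep) if k)
    mu, sd = mu[keep], sd[keep]

    def _make(df: pd.DataFrame, split: str) -> ModelingDataset:
        x = (df[list(kept_cols)].to_numpy(dtype=float) - mu) / sd
        return ModelingDataset(
            X=x, y=df["response"].to_numpy(dtype=float),
            subjects=df["subject"].to_numpy(), feature_names=kept_cols,
            split=split, scale_mean=mu, scale_sd=sd)

    return _make(train, "train"), _make(test, "test")
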