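"""Correlation-filter predictor screening and the threshold sweep.

Predictors are screened by the absolute Pearson correlation |r| between each
(training-partition) feature column and the response.  Candidate predictor
sets are built at thresholds 0.00, 0.01, ... up to the largest 0.01-multiple
not exceeding the maximum |r| (a maximum of 0.346 yields 35 sets); membership
is |r| >= threshold, so sets are nested and the top set always contains the
best predictor.  A separate single-best-predictor set supports the simple
single-regression baseline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ModelingDataset
from .exceptions import StructuralError

__all__ = [
    "PredictorSet",
    "correlation_screen",
    "build_threshold_sets",
    "single_best_set",
    "parse_feature_name",
    "electrodes_used",
]


@dataclass(frozen=True)
class PredictorSet:
    """A correlation threshold with its surviving features and electrodes."""

    threshold: float
    members: tuple[str, ...]
    electrodes: frozenset[str]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    @property
    def n_features(self) -> int:
        return len(self.members)


def parse_feature_name(name: str) -> tuple:
    """Parse ``power_<el>_<band>`` / ``coh_<el1>_<el2>_<band>`` feature names."""
    parts = name.split("_")
    if parts[0] == "power" and len(parts) == 3:
        return ("power", parts[1], parts[2])
    if parts[0] == "coh" and len(parts) == 4:
        return ("coh", parts[1], parts[2], parts[3])
    raise StructuralError(f"unparseable feature name: {name!r}")


def _electrodes_of(names) -> frozenset[str]:
    els: set[str] = set()
    for n in names:
        parsed = parse_feature_name(n)
        els.update(parsed[1:-1])
    return frozenset(els)


def electrodes_used(pset: PredictorSet) -> int:
    """Distinct electrodes appearing in any member (coherence features count 2)."""
    return len(_electrodes_of(pset.members))


def correlation_screen(train: ModelingDataset) -> pd.Series:
    """|Pearson r| of every training feature column against the response.

    Zero-variance columns get |r| = 0 with a warning.  Uses training rows
    only — the screen must never see test data.
    """
    x = train.X
    y = train.y
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    zero = (sx == 0) | (sy == 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s) assigned |r|=0")
    denom = np.where(zero, 1.0, sx * sy)
    r = np.abs(xc.T @ yc / denom)
    r[zero] = 0.0
    return pd.Series(r, index=list(train.feature_names), name="abs_r")


def build_threshold_sets(screen: pd.Series, step: float = 0.01
                         ) -> list[PredictorSet]:
    """One nested PredictorSet per threshold 0, step, ..., <= max |r|."""
    max_r = float(screen.max()) if len(screen) else 0.0
    n_thresholds = int(np.floor(max_r / step + 1e-9)) + 1 if max_r >= step else 1
    sets = []
    for i in range(n_thresholds):
        thr = round(i * step, 10)
        members = tuple(screen.index[(screen.to_numpy() >= thr - 1e-12)])
        sets.append(PredictorSet(threshold=thr, members=members,
                                 electrodes=_electrodes_of(members)))
    return sets


def single_best_set(screen: pd.Series) -> PredictorSet:
    """The one-predictor set holding the arg-max |r| feature.

    Ties are broken by lexicographic feature-name order (logged).
    """
    max_r = float(screen.max())
    winners = sorted(screen.index[screen.to_numpy() == max_r])
    if len(winners) > 1:
        warnings.warn(f"|r| tie at {max_r:.4f} among {winners}; "
                      f"keeping {winners[0]!r}")
    best = winners[0]
    return PredictorSet(threshold=max_r, members=(best,),
                        electrodes=_electrodes_of([best]))
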