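"""Held-out accuracy, correlation tests, r-difference tests, and the
behavioral (reaction-time) validation of the probe responses.

Model precision is the Pearson correlation r between predicted and measured
mind-wandering scores on the held-out subjects.  Pairs of models evaluated on
the same test responses are compared with a dependent-correlation test
(Steiger's Z, via Dunn & Clark, using the correlation between the two
prediction series); an independent Fisher-z difference test is also provided.
Reaction-time validation correlates per-section RT variance with the raw
probe answer within each subject, Fisher-transforms the r values, and applies
a one-sample Wilcoxon signed-rank test.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import ModelingDataset
from .exceptions import ConfigurationError
from .simulate import Annotations
from .svr import FittedModel

__all__ = [
    "COMPARISON_PAIRS",
    "ModelReport",
    "BehavioralResult",
    "heldout_correlation",
    "correlation_test",
    "r_difference_test",
    "behavioral_validation",
    "build_report",
]

#: the eight between-model contrasts reported by build_report
COMPARISON_PAIRS = (
    ("model1", "model2"), ("model3", "model4"),
    ("model1", "model3"), ("model2", "model4"),
    ("model1", "model5"), ("model2", "model5"),
    ("model3", "model5"), ("model4", "model5"),
)

_P_FLOOR = 1e-300


def _safe_corr(a: np.ndarray, b: np.ndarray, label: str = "series") -> float:
    """Pearson r, defined as 0 when either series is constant (with warning)."""
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(f"{label}: constant series; correlation reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def heldout_correlation(model: FittedModel, test: ModelingDataset
                        ) -> tuple[float, int]:
    """Pearson r between model predictions and measured responses on test rows."""
    if test.n < 3:
        raise ConfigurationError("test partition: need >= 3 rows")
    pred = model.predict(test.X, test.feature_names)
    return _safe_corr(pred, test.y, f"{model.name} predictions"), test.n


def correlation_test(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise ConfigurationError("n: need >= 3")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: p reported at underflow floor")
        return _P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return max(float(2.0 * stats.t.sf(abs(t), df=n - 2)), _P_FLOOR)


def r_difference_test(r1: float, r2: float, n: int,
                      method: str = "dependent", r12: float | None = None,
                      alternative: str = "greater") -> tuple[float, float]:
    """Test r1 vs r2 measured on the same n samples.

    method "independent": Fisher-z difference
        Z = (atanh r1 - atanh r2) / sqrt(2 / (n - 3)).
    method "dependent": Steiger's Z for two correlations sharing one variable
    (both models correlated against the same measured responses), which needs
    ``r12``, the correlation between the two prediction series.

    ``alternative``: "greater" (one-sided, r1 > r2; the default) or
    "two-sided".
    """
    if n <= 3:
        raise ConfigurationError("n: need > 3")
    for val, nm in ((r1, "r1"), (r2, "r2")):
        if not -1.0 < val < 1.0:
            raise ConfigurationError(f"{nm}: must lie strictly inside (-1, 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if method == "independent":
        z = float((z1 - z2) / np.sqrt(2.0 / (n - 3)))
    elif method == "dependent":
        if r12 is None:
            raise ConfigurationError("r12: required for the dependent method")
        if not -1.0 <= r12 <= 1.0:
            raise ConfigurationError("r12: must lie in [-1, 1]")
        # two effectively identical prediction series force r1 == r2; clamp so
        # the variance term stays finite in that degenerate limit
        r12 = float(np.clip(r12, -1.0 + 1e-8, 1.0 - 1e-8))
        if z1 == z2:
            z = 0.0
            return z, (0.5 if alternative == "greater" else 1.0)
        # Steiger (via Dunn & Clark): covariance of the two Fisher z's
        rm = (r1 + r2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rm * rm)), 1.0)
        h = (1.0 - f * rm * rm) / (1.0 - rm * rm)
        z = float((z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h)))
    else:
        raise ConfigurationError(f"method: unknown {method!r}")
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ConfigurationError(f"alternative: unknown {alternative!r}")
    return z, max(p, _P_FLOOR)


@dataclass
class BehavioralResult:
    """Per-subject RT-variance vs MW correlations and the signed-rank test."""

    subjects: list
    r_values: np.ndarray
    fisher_z: np.ndarray
    p_value: float
    skipped: list


def behavioral_validation(annotations: dict | list,
                          alternative: str = "greater") -> BehavioralResult:
    """Correlate per-section RT variance with the raw probe answer, per subject.

    ``annotations`` maps subject id -> Annotations (a list is treated as
    enumerate()).  Each subject's r is Fisher-transformed; the z values are
    tested against 0 with a one-sample Wilcoxon signed-rank test (exact for
    n <= 25, normal approximation above).
    """
    if isinstance(annotations, list):
        annotations = dict(enumerate(annotations))
    subjects, rs, skipped = [], [], []
    for subj, ann in annotations.items():
        rv = ann.rts.var(axis=1, ddof=1)
        answers = np.asarray(ann.probe_answers, dtype=float)
        if rv.std() == 0 or answers.std() == 0:
            warnings.warn(f"subject {subj!r}: constant RT variance or answers; "
                          "skipped")
            skipped.append(subj)
            continue
        rs.append(float(np.corrcoef(rv, answers)[0, 1]))
        subjects.append(subj)
    rs = np.asarray(rs)
    z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    if len(z) == 0:
        raise ConfigurationError("behavioral_validation: no usable subjects")
    method = "exact" if len(z) <= 25 else "approx"
    p = float(stats.wilcoxon(z, alternative=alternative, method=method).pvalue)
    return BehavioralResult(subjects=subjects, r_values=rs, fisher_z=z,
                            p_value=p, skipped=skipped)


@dataclass
class ModelReport:
    """The model-comparison output: per-model accuracy, contrasts, behavior."""

    n_test: int
    model_r: dict[str, float]
    model_p: dict[str, float]
    comparisons: list[dict]          # model_a, model_b, Z, p, method
    behavioral: dict | None = None

    def to_json(self) -> str:
        return json.dumps({
            "n_test": self.n_test,
            "model_r": self.model_r,
            "model_p": self.model_p,
            "comparisons": self.comparisons,
            "behavioral": self.behavioral,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelReport":
        d = json.loads(text)
        return cls(n_test=d["n_test"], model_r=d["model_r"],
                   model_p=d["model_p"], comparisons=d["comparisons"],
                   behavioral=d["behavioral"])

    def render(self) -> str:
        lines = [f"Held-out evaluation (n = {self.n_test} sections)",
                 f"{'model':<8} {'r':>7} {'p':>12}"]
        for m in sorted(self.model_r):
            lines.append(f"{m:<8} {self.model_r[m]:>7.3f} {self.model_p[m]:>12.3g}")
        lines.append("")
        lines.append(f"{'contrast':<20} {'Z':>7} {'p':>12}")
        for c in self.comparisons:
            lines.append(f"{c['model_a']} vs {c['model_b']:<11} "
                         f"{c['Z']:>7.2f} {c['p']:>12.3g}")
        if self.behavioral is not None:
            lines.append("")
            lines.append(
                f"RT-variance validation: median r = "
                f"{np.median(self.behavioral['r_values']):.3f}, signed-rank p = "
                f"{self.behavioral['p_value']:.2g}")
        return "\n".join(lines)


def build_report(models: dict[str, FittedModel], test: ModelingDataset,
                 annotations: dict | None = None,
                 method: str = "dependent",
                 alternative: str = "greater") -> ModelReport:
    """Assemble the full comparison report for the fitted five-model family."""
    preds = {name: m.predict(test.X, test.feature_names)
             for name, m in models.items()}
    model_r, model_p = {}, {}
    for name, pred in preds.items():
        r = _safe_corr(pred, test.y, f"{name} predictions")
        model_r[name] = r
        model_p[name] = correlation_test(r, test.n)

    comparisons = []
    for a, b in COMPARISON_PAIRS:
        if a not in preds or b not in preds:
            continue
        r12 = _safe_corr(preds[a], preds[b], f"{a}/{b} predictions") \
            if method == "dependent" else None
        zstat, p = r_difference_test(model_r[a], model_r[b], test.n,
                                     method=method, r12=r12,
                                     alternative=alternative)
        comparisons.append({"model_a": a, "model_b": b, "Z": zstat, "p": p,
                            "method": method, "r12": r12})

    behavioral = None
    if annotations is not None:
        b = behavioral_validation(annotations)
        behavioral = {"subjects": list(b.subjects),
                      "r_values": [float(v) for v in b.r_values],
                      "fisher_z": [float(v) for v in b.fisher_z],
                      "p_value": b.p_value,
                      "skipped": list(b.skipped)}
    return ModelReport(n_test=test.n, model_r=model_r, model_p=model_p,
                       comparisons=comparisons, behavioral=behavioral)
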