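"""Feature ranking and interpretation.

The univariate ANOVA F statistic (equivalently the squared two-sample
pooled-variance t for two groups) ranks features by class separation;
staged feature addition re-validates the classifier on the top-n features
for growing n; impurity importances score features from the trained
ensemble; class-conditional kernel density estimates visualize how a
feature's distribution shifts between the in- and out-of-corona classes.
The F statistic is computed from its definition here rather than delegated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import (
    ClassifierConfig,
    CoronaClassifier,
    SmoteConfig,
    ValidationResult,
    validate,
)

logger = logging.getLogger(__name__)

#: Number of top-ranked features used downstream by default; classifier
#: performance peaks near this count before declining slightly with the
#: full set.
DEFAULT_N_FEATURES = 38


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by descending F; ties broken by name."""

    table: pd.DataFrame  # columns: rank, feature, f_statistic

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def top(self, n: int) -> list[str]:
        return self.features[:n]


def anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way two-group ANOVA F = between-group MS / within-group MS.

    Defined as 0 when both between- and within-group variance vanish
    (logged); infinite when only the within-group variance vanishes.
    """
    if np.ptp(values) == 0:  # globally constant: both mean squares vanish
        logger.info("feature constant in both classes; F defined as 0")
        return 0.0
    groups = [values[labels], values[~labels]]
    n_total = len(values)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ms_between == 0.0:
            logger.info("feature constant in both classes; F defined as 0")
            return 0.0
        return float("inf")
    return float(ms_between / ms_within)


def anova_rank(
    features: pd.DataFrame, labels: Sequence[bool]
) -> FeatureRanking:
    """Rank every feature by its two-group ANOVA F statistic.

    ``features`` should be the scaled table; ``labels`` boolean with
    True = in-corona.  Both classes need ≥2 members.
    """
    y = np.asarray(labels, dtype=bool)
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("each class needs ≥2 members")
    stats = {
        name: anova_f(features[name].to_numpy(dtype=float), y)
        for name in features.columns
    }
    ordered = sorted(stats.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "feature": [name for name, _ in ordered],
            "f_statistic": [f for _, f in ordered],
        }
    )
    return FeatureRanking(table=table)


def staged_feature_curve(
    features: pd.DataFrame,
    labels: Sequence[bool],
    ranking: FeatureRanking,
    n_splits: int = 100,
    test_fraction: float = 0.1,
    cfg: ClassifierConfig = ClassifierConfig(),
    smote_cfg: SmoteConfig | None = SmoteConfig(),
    seed: int | None = None,
) -> list[tuple[int, ValidationResult]]:
    """Validation metrics as features are unmasked from the ranking,
    highest F first.

    Row n validates the classifier on the top-n features.  With a shared
    seed the n = m row reproduces a plain validation run on all features
    bit-for-bit.
    """
    missing = [c for c in features.columns if c not in ranking.features]
    if missing:
        raise ValueError(f"ranking does not cover features: {missing}")
    rows = []
    for n in range(1, len(ranking.features) + 1):
        subset = ranking.top(n)
        result = validate(
            features[subset],
            labels,
            n_splits=n_splits,
            test_fraction=test_fraction,
            cfg=cfg,
            smote_cfg=smote_cfg,
            seed=seed,
        )
        rows.append((n, result))
    return rows


def staged_curve_table(
    rows: list[tuple[int, ValidationResult]]
) -> pd.DataFrame:
    """Flatten a staged curve into one row per feature count."""
    records = []
    for n, result in rows:
        rec: dict = {"n_features": n}
        for name in ValidationResult.METRIC_NAMES:
            lo, hi = result.ci95(name)
            rec[f"{name}_mean"] = result.mean(name)
            rec[f"{name}_ci_low"] = lo
            rec[f"{name}_ci_high"] = hi
        records.append(rec)
    return pd.DataFrame(records)


def impurity_importances(model: CoronaClassifier) -> pd.DataFrame:
    """Mean impurity-decrease importance per feature, summing to 1,
    sorted descending."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError("model is untrained or lacks impurity importances")
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return (
        pd.DataFrame({"feature": model.feature_names, "importance": imp})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def class_kde(
    values: Sequence[float],
    labels: Sequence[bool],
    bandwidth: float | str | None = None,
    grid_size: int = 256,
) -> pd.DataFrame:
    """Class-conditional kernel density estimates of one scaled feature.

    Gaussian kernels with the variance-based (Scott) bandwidth rule unless
    overridden; densities are evaluated on a *grid_size*-point grid over
    [0, 1] and renormalized to unit trapezoid integral there, so boundary
    tail mass does not distort comparisons.  Each class needs ≥2 points.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {"x": grid}
    for cls, column in ((True, "density_in"), (False, "density_out")):
        pts = x[y == cls]
        if len(pts) < 2:
            raise ValueError(
                f"class {'in' if cls else 'out'} has fewer than 2 points"
            )
        if np.ptp(pts) == 0:  # degenerate: all mass at one point
            raise ValueError("cannot estimate a density from constant values")
        kde = gaussian_kde(pts, bw_method=bandwidth)
        dens = kde(grid)
        area = np.trapezoid(dens, grid)
        out[column] = dens / area
    return pd.DataFrame(out)
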