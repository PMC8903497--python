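"""Selection-stability profiles and group comparisons of top features.

Collates which features the embedded selection chose across the LOOCV
folds into per-channel / per-measure / per-band profiles (average count
per iteration and percentage of iterations with at least one selection),
and compares the most frequently selected features between outcome groups
with Bonferroni-corrected two-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import CvRun
from .features import CohortLabels, FeatureId, FeatureTable

__all__ = [
    "SelectionProfile",
    "GroupComparison",
    "collate_selections",
    "difference_profile",
    "top_features",
    "group_feature_tests",
    "write_group_comparison",
    "read_group_comparison",
]

AXES = ("channel", "measure", "band_or_scale")


@dataclass
class SelectionProfile:
    """Selection counts and rates collated over LOOCV iterations.

    ``feature_counts`` maps each FeatureId to its total selection count
    over the ``n_iterations`` folds.  ``axis_counts[axis]`` maps category
    (channel / measure / band label) to total count; average counts are
    counts / n_iterations and, per axis, sum exactly to the number of
    features selected per fold.  ``axis_hit_pct`` is the percentage of
    iterations in which the category was selected at least once.
    """

    n_iterations: int
    feature_counts: dict[FeatureId, int]
    axis_counts: dict[str, dict[str, int]]
    axis_hit_counts: dict[str, dict[str, int]]

    def feature_pct(self, fid: FeatureId) -> float:
        return 100.0 * self.feature_counts.get(fid, 0) / self.n_iterations

    def axis_average(self, axis: str) -> dict[str, float]:
        return {c: n / self.n_iterations
                for c, n in self.axis_counts[axis].items()}

    def axis_hit_pct(self, axis: str) -> dict[str, float]:
        return {c: 100.0 * n / self.n_iterations
                for c, n in self.axis_hit_counts[axis].items()}

    def axis_frame(self, axis: str) -> pd.DataFrame:
        avg = self.axis_average(axis)
        pct = self.axis_hit_pct(axis)
        return pd.DataFrame({"category": list(avg),
                             "avg_count_per_iteration": list(avg.values()),
                             "pct_iterations_selected": [pct[c] for c in avg]})


def collate_selections(cv_run: CvRun) -> SelectionProfile:
    """Sum selections over folds and divide by the iteration count."""
    if not cv_run.folds:
        raise ValueError("empty CV run")
    if any(not f.selected for f in cv_run.folds):
        raise ValueError("fold with empty selection")
    n_iter = len(cv_run.folds)
    feature_counts: dict[FeatureId, int] = {}
    axis_counts = {a: {} for a in AXES}
    axis_hit_counts = {a: {} for a in AXES}
    for fold in cv_run.folds:
        seen = {a: set() for a in AXES}
        for fid in fold.selected:
            feature_counts[fid] = feature_counts.get(fid, 0) + 1
            for axis in AXES:
                cat = getattr(fid, axis)
                axis_counts[axis][cat] = axis_counts[axis].get(cat, 0) + 1
                seen[axis].add(cat)
        for axis in AXES:
            for cat in seen[axis]:
                axis_hit_counts[axis][cat] = \
                    axis_hit_counts[axis].get(cat, 0) + 1
    return SelectionProfile(n_iterations=n_iter,
                            feature_counts=feature_counts,
                            axis_counts=axis_counts,
                            axis_hit_counts=axis_hit_counts)


def difference_profile(a: SelectionProfile, b: SelectionProfile,
                       axis: str) -> dict[str, float]:
    """Signed difference of average counts per category (a minus b)."""
    avg_a = a.axis_average(axis)
    avg_b = b.axis_average(axis)
    cats = list(dict.fromkeys(list(avg_a) + list(avg_b)))
    return {c: avg_a.get(c, 0.0) - avg_b.get(c, 0.0) for c in cats}


def top_features(profile: SelectionProfile, m: int = 20,
                 order: Optional[Sequence[FeatureId]] = None
                 ) -> list[FeatureId]:
    """The m most frequently selected features.

    Ties break by the deterministic feature-table column order when
    ``order`` is given, else by the profile's insertion order.
    """
    fids = list(order) if order is not None else list(profile.feature_counts)
    fids = [f for f in fids if profile.feature_counts.get(f, 0) > 0]
    ranked = sorted(fids,
                    key=lambda f: -profile.feature_counts.get(f, 0))
    return ranked[:m]  # sorted() is stable, so ties keep input order


@dataclass
class GroupComparison:
    """Per-feature group statistics in report (Table-3) layout."""

    table: pd.DataFrame  # one row per feature
    n_comparisons: int

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.n_comparisons


def group_feature_tests(table: FeatureTable, labels: CohortLabels,
                        features: Sequence[FeatureId],
                        n_comparisons: int = 20,
                        profile: Optional[SelectionProfile] = None,
                        welch: bool = False) -> GroupComparison:
    """Two-sample t test per feature with Bonferroni correction.

    Uses the independent pooled-variance Student's t by default (the
    groups are independent and of unequal size); ``welch=True`` drops the
    equal-variance assumption.  The significance flag is
    p < 0.05 / n_comparisons.  Features with zero variance in both groups
    get a missing p.
    """
    y = labels.y(table.subject_ids)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both groups must be non-empty")
    alpha = 0.05 / n_comparisons
    col_of = {fid: j for j, fid in enumerate(table.feature_ids)}
    rows = []
    for fid in features:
        x = table.values[:, col_of[fid]]
        pos, neg = x[y == 1], x[y == 0]
        if np.var(pos) == 0.0 and np.var(neg) == 0.0:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_ind(pos, neg, equal_var=not welch)
        rows.append({
            "feature": str(fid),
            "channel": fid.channel,
            "band_or_scale": fid.band_or_scale,
            "measure": fid.measure,
            "mean_positive": float(pos.mean()),
            "sd_positive": float(pos.std(ddof=1)) if pos.size > 1 else np.nan,
            "mean_negative": float(neg.mean()),
            "sd_negative": float(neg.std(ddof=1)) if neg.size > 1 else np.nan,
            "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
            "p": float(p) if np.isfinite(p) else np.nan,
            "significant": bool(np.isfinite(p) and p < alpha),
            "pct_iterations_selected": (profile.feature_pct(fid)
                                        if profile is not None else np.nan),
        })
    df = pd.DataFrame(rows)
    if profile is not None:
        df = df.sort_values("pct_iterations_selected", ascending=False,
                            kind="stable").reset_index(drop=True)
    return GroupComparison(table=df, n_comparisons=n_comparisons)


def write_group_comparison(comp: GroupComparison, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    comp.table.to_csv(path, index=False)
    return path


def read_group_comparison(path, n_comparisons: int = 20) -> GroupComparison:
    df = pd.read_csv(path)
    return GroupComparison(table=df, n_comparisons=n_comparisons)
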