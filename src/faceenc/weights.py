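"""Encoding-weight summaries and their relation to age.

A fitted model carries one weight per (feature, lag) per cross-validation
fold.  Absolute values are taken (the analysis does not discriminate
whether a feature maps to an increase or decrease of the response) and
reduced over lags and folds to one value per feature.  Features are grouped
into complex (self-conscious/social) and basic emotions, and per-feature
weights are correlated with age across the subjects whose fit reached
permutation significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig
from .model import EncodingFit
from .stats import PermutationResult


@dataclass
class WeightSummary:
    subject_id: str
    region: str
    condition: str
    per_feature: np.ndarray          # one non-negative value per feature
    feature_names: tuple[str, ...]
    complex_mean: float
    basic_mean: float
    included: bool = True


@dataclass
class AgeCorrelation:
    label: str                        # feature or group name
    r: float
    p_uncorrected: float
    n: int


def summarize_weights(fit: EncodingFit, config: PipelineConfig,
                      included: bool = True) -> WeightSummary:
    """Reduce |weights| over lags and folds to one value per feature.

    The reduction is the mean by default ("max" available via
    ``config.weight_reduction``); group means average the configured
    complex/basic member features.
    """
    names = config.feature_names
    n_lags = config.n_lags
    W = np.abs(np.asarray(fit.weights, dtype=float))
    if W.ndim != 2 or W.shape[1] != len(names) * n_lags:
        raise ValueError(
            f"expected folds x {len(names) * n_lags} weights, got {W.shape}")
    # columns are feature-major then lag
    per_fold_feature = W.reshape(W.shape[0], len(names), n_lags)
    if config.weight_reduction == "mean":
        per_feature = per_fold_feature.mean(axis=(0, 2))
    else:
        per_feature = per_fold_feature.max(axis=(0, 2))
    index = {name: i for i, name in enumerate(names)}
    complex_mean = float(np.mean(
        [per_feature[index[f]] for f in config.effective_complex_group]))
    basic_mean = float(np.mean(
        [per_feature[index[f]] for f in config.basic_group]))
    return WeightSummary(subject_id=fit.subject_id, region=fit.region,
                         condition=fit.condition, per_feature=per_feature,
                         feature_names=names, complex_mean=complex_mean,
                         basic_mean=basic_mean, included=included)


def filter_included(perm_results: dict[str, PermutationResult],
                    threshold: float = 0.05) -> list[str]:
    """Subject ids whose permutation p is below the threshold."""
    return sorted(sid for sid, res in perm_results.items()
                  if res.p_two_tailed < threshold)


def correlate_with_age(summaries: list[WeightSummary],
                       ages: dict[str, float]
                       ) -> tuple[pd.DataFrame, dict[str, AgeCorrelation]]:
    """Pearson correlation of each feature weight (and group mean) with age.

    Returns the per-feature table sorted by r descending (ties broken by
    feature name) with 1-based ranks, and the complex/basic group-level
    correlations.  Requires >= 3 subjects and non-constant weights/ages.
    """
    included = [s for s in summaries if s.included]
    if len(included) < 3:
        raise ValueError("need at least 3 included subjects")
    names = included[0].feature_names
    age_vec = np.array([ages[s.subject_id] for s in included], dtype=float)
    if age_vec.std() == 0:
        raise ValueError("zero variance in ages")
    weight_mat = np.stack([s.per_feature for s in included])  # subjects x F

    def _corr(values: np.ndarray, label: str) -> AgeCorrelation:
        if values.std() == 0:
            raise ValueError(f"zero variance in weights for {label!r}")
        r, p = scipy.stats.pearsonr(values, age_vec)
        return AgeCorrelation(label=label, r=float(r), p_uncorrected=float(p),
                              n=len(age_vec))

    rows = []
    for i, name in enumerate(names):
        c = _corr(weight_mat[:, i], name)
        rows.append({"feature": name, "r": c.r, "p": c.p_uncorrected,
                     "n": c.n})
    table = pd.DataFrame(rows).sort_values(
        ["r", "feature"], ascending=[False, True]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    groups = {
        "complex": _corr(np.array([s.complex_mean for s in included]),
                         "complex"),
        "basic": _corr(np.array([s.basic_mean for s in included]), "basic"),
    }
    return table, groups


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional extra column for users; the primary
    report stays uncorrected)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def weights_table(summaries: list[WeightSummary],
                  ages: dict[str, float]) -> pd.DataFrame:
    """Subjects x features TSV-ready table with group means, age, flag."""
    rows = []
    for s in summaries:
        row = {"subject": s.subject_id, "region": s.region,
               "condition": s.condition, "age": ages.get(s.subject_id),
               "included": s.included,
               "complex_mean": s.complex_mean, "basic_mean": s.basic_mean}
        row.update({name: v for name, v in zip(s.feature_names, s.per_feature)})
        rows.append(row)
    return pd.DataFrame(rows)
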