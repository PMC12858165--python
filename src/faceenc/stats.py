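"""Permutation and parametric inference on prediction accuracies.

The temporal-shuffle permutation test destroys the alignment between the
emotion features and the neural response while preserving everything else:
the rows (2 Hz time bins) of the condition's feature matrix are jointly
permuted (all 48 features move together, keeping their instantaneous
covariance), the lagging -> fitting -> accuracy pipeline is rerun, and the
resulting null distribution of mean_r yields a two-tailed Monte-Carlo
p-value with add-one correction.  Group-level comparisons use standard
one-sample, paired and pooled-variance unpaired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import PipelineConfig, logger
from .features import (DesignMatrix, FeatureTimecourse, ResponseMatrix,
                       assemble_condition, build_design_matrix)
from .model import (Dataset, EncodingFit, concatenate_contacts,
                    contiguous_folds, cv_mean_r_batch)
from .preproc import SubjectRecord


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_two_tailed: float
    n_perm: int
    seed: int

    def to_record(self) -> dict:
        return {"observed": self.observed, "p": self.p_two_tailed,
                "n_perm": self.n_perm, "seed": self.seed,
                "null_mean": float(np.mean(self.null_values)),
                "null_sd": float(np.std(self.null_values))}


@dataclass
class GroupStat:
    test: str            # one_sample_t | paired_t | unpaired_t
    statistic: float
    df: int
    p_two_tailed: float
    groups: tuple[str, ...] = ()
    n: tuple[int, ...] = ()

    def to_record(self) -> dict:
        return {"test": self.test, "t": self.statistic, "df": self.df,
                "p": self.p_two_tailed, "groups": list(self.groups),
                "n": list(self.n)}


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def mc_p_two_tailed(observed: float, null_values: np.ndarray) -> float:
    """Two-tailed Monte-Carlo p: absolute deviation from the null median,
    with add-one correction (p is never 0 and never below 1/(n+1))."""
    null_values = np.asarray(null_values, dtype=float)
    med = float(np.median(null_values))
    n_extreme = int(np.sum(np.abs(null_values - med)
                           >= abs(observed - med) - 1e-15))
    return (1 + n_extreme) / (len(null_values) + 1)


def _shuffled_feature_batch(values: np.ndarray, rng: np.random.Generator,
                            n: int, mode: str) -> np.ndarray:
    """n shuffled copies of a (blocks x bins x features) condition feature
    array; rows are jointly permuted (or circularly shifted) across the
    condition's pooled time bins."""
    B, T, F = values.shape
    flat = values.reshape(B * T, F)
    total = B * T
    if mode == "permute":
        idx = np.argsort(rng.random((n, total)), axis=1)
    elif mode == "circular":
        shifts = rng.integers(1, total, size=n)
        idx = (np.arange(total)[None, :] + shifts[:, None]) % total
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return flat[idx].reshape(n, B, T, F)


def permutation_test(features: FeatureTimecourse, response: ResponseMatrix,
                     region: str, condition: str, alpha: float,
                     config: PipelineConfig,
                     n_perm: int | None = None,
                     seed: int | None = None,
                     chunk: int = 50) -> PermutationResult:
    """Temporal-shuffle significance test of one region x condition fit.

    For each permutation the condition's 2 Hz feature rows are jointly
    shuffled, the lagged design rebuilt (block boundaries respected), the
    ridge model re-fitted at the already-selected shared ``alpha`` with the
    same contiguous folds, and the cross-validated mean_r recorded.
    """
    n_perm = int(config.n_perm if n_perm is None else n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = int(config.rng_seed if seed is None else seed)
    rng = np.random.default_rng(seed)

    channels = response.channels
    good = (channels["status"] == "good").to_numpy()
    idx = np.flatnonzero((channels["region"] == region).to_numpy() & good)
    if len(idx) == 0:
        raise ValueError(f"no good contacts in region {region!r}")

    cond_mask = (features.block_meta["condition"] == condition).to_numpy()
    cond_features = FeatureTimecourse(
        values=features.values[cond_mask], fs=features.fs,
        names=features.names,
        block_meta=features.block_meta.loc[cond_mask].reset_index(drop=True))

    design = build_design_matrix(features, config.lags)
    Xc, Yc, _ = assemble_condition(design, response, condition)
    Xs, ys, contact_ids = concatenate_contacts(Xc, Yc[:, idx],
                                               config.contact_aggregation)
    folds = contiguous_folds(contact_ids, config.n_folds)
    observed = float(cv_mean_r_batch(Xs[None], ys, folds, alpha)[0])

    n_contacts = len(idx) if config.contact_aggregation == "concatenate" else 1
    null_values = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        shuffled = _shuffled_feature_batch(cond_features.values, rng, m,
                                           config.shuffle_mode)
        X_batch = _lagged_batch(shuffled, features.fs, config.lags)
        if n_contacts > 1:
            X_batch = np.tile(X_batch, (1, n_contacts, 1))
        null_values[done:done + m] = cv_mean_r_batch(X_batch, ys, folds, alpha)
        done += m
    p = mc_p_two_tailed(observed, null_values)
    return PermutationResult(observed=observed, null_values=null_values,
                             p_two_tailed=p, n_perm=n_perm, seed=seed)


def _lagged_batch(values: np.ndarray, fs: float,
                  lags: tuple[float, ...]) -> np.ndarray:
    """Lag-expand a batch of (blocks x bins x features) arrays into
    (batch x rows x features*lags) designs, zero-padded at block starts."""
    P, B, T, F = values.shape
    L = len(lags)
    X = np.zeros((P, B, T, F * L))
    for j, lag in enumerate(lags):
        lb = int(round(lag * fs))
        if lb == 0:
            X[:, :, :, j::L] = values
        else:
            X[:, :, lb:, j::L] = values[:, :, :-lb, :]
    return X.reshape(P, B * T, F * L)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def one_sample_t(values, popmean: float = 0.0) -> GroupStat:
    """Two-sided one-sample t against ``popmean``; df = n - 1.

    A sample with zero variance exactly at the population mean yields
    t = 0, p = 1; zero variance elsewhere is an error.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    if values.std(ddof=1) == 0:
        if np.isclose(values.mean(), popmean):
            return GroupStat("one_sample_t", 0.0, n - 1, 1.0, n=(n,))
        raise ValueError("zero variance away from the population mean")
    res = scipy.stats.ttest_1samp(values, popmean)
    return GroupStat("one_sample_t", float(res.statistic), n - 1,
                     float(res.pvalue), n=(n,))


def paired_t(a, b) -> GroupStat:
    """Two-sided paired t (one-sample t on differences); df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    stat = one_sample_t(a - b, 0.0)
    return GroupStat("paired_t", stat.statistic, stat.df, stat.p_two_tailed,
                     n=(len(a),))


def unpaired_t(a, b, labels: tuple[str, str] = ("a", "b")) -> GroupStat:
    """Two-sided two-sample t, pooled (equal-variance) convention;
    df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return GroupStat("unpaired_t", 0.0, len(a) + len(b) - 2, 1.0,
                             groups=labels, n=(len(a), len(b)))
        raise ValueError("zero pooled variance with unequal means")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    return GroupStat("unpaired_t", float(res.statistic),
                     len(a) + len(b) - 2, float(res.pvalue),
                     groups=labels, n=(len(a), len(b)))


# ---------------------------------------------------------------------------
# Condition contrast
# ---------------------------------------------------------------------------

def voice_effect(fits: list[EncodingFit],
                 subjects: dict[str, SubjectRecord],
                 region: str) -> tuple[pd.DataFrame, GroupStat | None]:
    """Per-subject speech-minus-music accuracy difference and, when both
    developmental groups are present, their unpaired contrast.

    The difference quantifies the effect of the human voice on the
    representation: positive means speech blocks are predicted better.
    """
    by_subject: dict[str, dict[str, float]] = {}
    for fit in fits:
        if fit.region != region:
            continue
        by_subject.setdefault(fit.subject_id, {})[fit.condition] = fit.mean_r
    rows = []
    for sid, accs in sorted(by_subject.items()):
        if "speech" not in accs or "music" not in accs:
            raise ValueError(f"subject {sid} lacks a fitted condition")
        rows.append({"subject": sid, "group": subjects[sid].group,
                     "r_speech": accs["speech"], "r_music": accs["music"],
                     "delta_r": accs["speech"] - accs["music"]})
    df = pd.DataFrame(rows)
    contrast = None
    if not df.empty:
        child = df.loc[df["group"] == "childhood", "delta_r"].to_numpy()
        post = df.loc[df["group"] == "post_childhood", "delta_r"].to_numpy()
        if len(child) >= 2 and len(post) >= 2:
            contrast = unpaired_t(child, post,
                                  labels=("childhood", "post_childhood"))
    return df, contrast
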