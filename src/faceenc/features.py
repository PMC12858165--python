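"""Emotion-feature time courses and lagged design matrices.

Per-frame (optionally per-face) emotion scores are reduced to one score per
frame by taking the maximum over faces, bin-averaged to 2 Hz, and expanded
into a lagged design matrix (one column per feature x lag).  HFB epochs are
averaged into matching 500 ms bins so each design row and each response row
refer to the same stimulus time.  Lag tau means the stimulus at t - tau
predicts the response at t; rows whose lagged time precedes block start are
zero-padded and blocks never leak into each other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig, logger
from .preproc import HFBEpochs, resolve_excluded_blocks


@dataclass
class FeatureTimecourse:
    """Per-block emotion scores: blocks x time x features, in [0, 1]."""

    values: np.ndarray
    fs: float
    names: tuple[str, ...]
    block_meta: pd.DataFrame  # columns: block_index, condition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be blocks x time x features")
        if self.values.shape[2] != len(self.names):
            raise ValueError("feature-name count mismatch")
        if len(self.block_meta) != self.values.shape[0]:
            raise ValueError("block_meta length mismatch")
        if self.values.size and (self.values.min() < -1e-9
                                 or self.values.max() > 1 + 1e-9):
            raise ValueError("feature values outside [0, 1]")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignMatrix:
    """Lagged predictors: rows are (block, bin), columns are (feature, lag)."""

    X: np.ndarray
    column_labels: list[tuple[str, float]]  # feature-major, then lag
    row_meta: pd.DataFrame  # columns: block_index, condition, bin

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.row_meta), len(self.column_labels)):
            raise ValueError("design shape inconsistent with metadata")


@dataclass
class ResponseMatrix:
    """Binned HFB responses: rows aligned with a DesignMatrix, one column
    per contact (z-units)."""

    Y: np.ndarray  # rows x contacts
    row_meta: pd.DataFrame
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.Y.ndim != 2 or len(self.row_meta) != self.Y.shape[0]:
            raise ValueError("response shape inconsistent with metadata")
        if len(self.channels) != self.Y.shape[1]:
            raise ValueError("channel table does not match response columns")


# ---------------------------------------------------------------------------
# Frame-level operations
# ---------------------------------------------------------------------------

def aggregate_faces(per_face: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum score across faces, per frame and emotion.

    ``per_face`` is frames x faces x features; absent faces are NaN rows.
    Returns ``(scores, no_face)`` where ``no_face`` flags frames without any
    face (their scores are all zero).
    """
    per_face = np.asarray(per_face, dtype=float)
    if per_face.ndim != 3:
        raise ValueError("expected frames x faces x features")
    finite = np.isfinite(per_face)
    if np.any((per_face < -1e-9) & finite) or np.any((per_face > 1 + 1e-9) & finite):
        raise ValueError("scores outside [0, 1]")
    present = finite.all(axis=2)  # frames x faces
    no_face = ~present.any(axis=1)
    masked = np.where(present[:, :, None], per_face, -np.inf)
    scores = masked.max(axis=1)
    scores[no_face] = 0.0
    if no_face.any():
        logger.warning("%d frames contain no face; scored 0", int(no_face.sum()))
    return scores, no_face


def aggregate_faces_table(df: pd.DataFrame,
                          feature_names: tuple[str, ...]) -> pd.DataFrame:
    """Collapse a per-face feature table (time, face_id, scores...) to one
    row per timestamp by max over faces."""
    if "face_id" not in df.columns:
        return df
    agg = df.groupby("time", sort=True)[list(feature_names)].max().reset_index()
    return agg


def resample_features(frame_times: np.ndarray, frame_scores: np.ndarray,
                      events: pd.DataFrame,
                      names: tuple[str, ...],
                      target_fs: float = 2.0,
                      window: tuple[float, float] = (0.0, 30.0),
                      excluded_blocks: tuple[int, ...] | None = None
                      ) -> FeatureTimecourse:
    """Bin-average per-frame scores to the feature rate within each block.

    Each output sample is the mean of the frames falling in its half-open
    ``1/target_fs`` bin.  Bins without frames carry the previous bin's value
    (flagged in the log); a block without any frame raises.  Output is
    clipped to [0, 1].
    """
    frame_times = np.asarray(frame_times, dtype=float)
    frame_scores = np.asarray(frame_scores, dtype=float)
    excluded = resolve_excluded_blocks(events, excluded_blocks)
    span = window[1] - window[0]
    n_bins = int(round(span * target_fs))
    if abs(n_bins - span * target_fs) > 1e-9:
        raise ValueError("window is not a whole number of feature bins")
    blocks, meta = [], []
    for row in events.itertuples():
        if row.block_index in excluded:
            continue
        t0 = row.onset + window[0]
        rel = frame_times - t0
        in_block = (rel >= 0) & (rel < span)
        if not in_block.any():
            raise ValueError(f"block {row.block_index} has no feature frames")
        idx = np.floor(rel[in_block] * target_fs).astype(int)
        sums = np.zeros((n_bins, frame_scores.shape[1]))
        counts = np.zeros(n_bins)
        np.add.at(sums, idx, frame_scores[in_block])
        np.add.at(counts, idx, 1)
        empty = counts == 0
        counts[empty] = 1
        binned = sums / counts[:, None]
        if empty.any():
            logger.warning("block %d: %d empty feature bins carried forward",
                           row.block_index, int(empty.sum()))
            # forward-fill; leading empties take the first filled value
            filled = np.flatnonzero(~empty)
            prev = np.maximum.accumulate(
                np.where(~empty, np.arange(n_bins), -1))
            prev[prev < 0] = filled[0]
            binned = binned[prev]
        blocks.append(np.clip(binned, 0.0, 1.0))
        meta.append({"block_index": row.block_index, "condition": row.condition})
    return FeatureTimecourse(values=np.stack(blocks), fs=target_fs,
                             names=tuple(names),
                             block_meta=pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# Design / response construction
# ---------------------------------------------------------------------------

def lag_block(values: np.ndarray, lag_bins: int) -> np.ndarray:
    """Shift one block's time x features matrix down by lag_bins rows,
    zero-padding the start (scores are activations; zero means absent)."""
    if lag_bins == 0:
        return values
    out = np.zeros_like(values)
    out[lag_bins:] = values[:-lag_bins]
    return out


def build_design_matrix(features: FeatureTimecourse,
                        lags: tuple[float, ...] = (0.0, 0.5, 1.0)
                        ) -> DesignMatrix:
    """Expand features into lagged predictors, blocks stacked in order.

    Column (f, tau) at row t holds feature f at time t - tau within the same
    block.  Columns are feature-major then lag.
    """
    lag_bins = []
    for lag in lags:
        lb = lag * features.fs
        if abs(lb - round(lb)) > 1e-9 or lb < 0:
            raise ValueError(f"lag {lag} not a non-negative multiple of "
                             f"1/{features.fs}")
        lag_bins.append(int(round(lb)))
    B, T, F = features.values.shape
    L = len(lags)
    X = np.zeros((B, T, F * L))
    for j, lb in enumerate(lag_bins):
        shifted = np.zeros_like(features.values)
        if lb == 0:
            shifted[:] = features.values
        else:
            shifted[:, lb:, :] = features.values[:, :-lb, :]
        X[:, :, j::L] = shifted
    column_labels = [(name, lag) for name in features.names for lag in lags]
    row_meta = features.block_meta.loc[
        features.block_meta.index.repeat(T)].reset_index(drop=True)
    row_meta["bin"] = np.tile(np.arange(T), B)
    return DesignMatrix(X=X.reshape(B * T, F * L),
                        column_labels=column_labels, row_meta=row_meta)


def bin_response(epochs: HFBEpochs, bin_width: float = 0.5,
                 n_bins: int | None = None) -> ResponseMatrix:
    """Average normalized HFB samples into successive half-open bins.

    The pre-onset margin is excluded; each bin averages
    ``bin_width * fs`` samples (must be an integer count).  Rows follow the
    same (block, bin) order as :func:`build_design_matrix`.
    """
    spb = bin_width * epochs.fs
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError(f"bin width {bin_width} s is not a whole number of "
                         f"samples at {epochs.fs} Hz")
    spb = int(round(spb))
    stim = epochs.stimulus_data()  # blocks x channels x time
    max_bins = stim.shape[2] // spb
    if n_bins is None:
        n_bins = max_bins
    elif n_bins > max_bins:
        raise ValueError("epoch too short for requested bin count")
    trimmed = stim[:, :, :n_bins * spb]
    binned = trimmed.reshape(stim.shape[0], stim.shape[1], n_bins, spb).mean(axis=3)
    B, C, T = binned.shape
    Y = binned.transpose(0, 2, 1).reshape(B * T, C)
    row_meta = epochs.block_meta[["block_index", "condition"]].loc[
        epochs.block_meta.index.repeat(T)].reset_index(drop=True)
    row_meta["bin"] = np.tile(np.arange(T), B)
    return ResponseMatrix(Y=Y, row_meta=row_meta, channels=epochs.channels)


def assemble_condition(design: DesignMatrix, response: ResponseMatrix,
                       condition: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Restrict an aligned design/response pair to one condition.

    Rows are kept in stimulus order.  Raises when the pair is misaligned or
    the condition has no retained blocks.
    """
    key = ["block_index", "condition", "bin"]
    if len(design.row_meta) != len(response.row_meta) or not (
            design.row_meta[key].reset_index(drop=True)
            .equals(response.row_meta[key].reset_index(drop=True))):
        raise ValueError("design and response rows are not aligned")
    mask = (design.row_meta["condition"] == condition).to_numpy()
    if not mask.any():
        raise ValueError(f"no retained blocks for condition {condition!r}")
    meta = design.row_meta.loc[mask].reset_index(drop=True)
    return design.X[mask], response.Y[mask], meta
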