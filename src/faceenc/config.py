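"""Pipeline configuration.

All numeric constants of the analysis live in :class:`PipelineConfig` so that
every stage (preprocessing, feature pipeline, model fitting, inference) is
driven by one validated object.  Defaults reproduce the published analysis
settings: 50 Hz line noise, a 110-140 Hz high-frequency band, 0-30 s blocks
with a -0.2-0 s baseline, 400 Hz working rate, 2 Hz feature rate, 500 ms
response bins, lags of 0/0.5/1 s, a 20-point log-spaced ridge penalty grid
between 10 and 10000, fivefold cross-validation and 5000 permutations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

logger = logging.getLogger("faceenc")

#: The 48-dimensional facial-expression vocabulary used by default.  The
#: analysis is name-driven: design-matrix columns, weight summaries and the
#: complex/basic emotion groupings all refer to these labels, and an input
#: feature table must provide exactly the configured names.
DEFAULT_FEATURE_NAMES: tuple[str, ...] = (
    "admiration", "adoration", "aesthetic_appreciation", "amusement",
    "anger", "anxiety", "awe", "awkwardness", "boredom", "calmness",
    "concentration", "confusion", "contemplation", "contempt", "contentment",
    "craving", "desire", "determination", "disappointment", "disgust",
    "distress", "doubt", "ecstasy", "embarrassment", "empathic_pain",
    "entrancement", "envy", "excitement", "fear", "gratitude", "guilt",
    "horror", "interest", "joy", "love", "nostalgia", "pain", "pride",
    "realization", "relief", "romance", "sadness", "satisfaction", "shame",
    "surprise", "sympathy", "tiredness", "triumph",
)

#: Self-conscious/social emotions whose comprehension requires representing
#: another person's mental state.
DEFAULT_COMPLEX_GROUP: tuple[str, ...] = ("guilt", "embarrassment", "pride", "envy")

#: The six canonical basic emotions.
DEFAULT_BASIC_GROUP: tuple[str, ...] = (
    "joy", "sadness", "fear", "anger", "disgust", "surprise",
)


def default_alpha_grid() -> np.ndarray:
    """20 ridge penalties log-spaced between 10 and 10000 (inclusive)."""
    return np.logspace(np.log10(10.0), np.log10(10000.0), 20)


@dataclass
class PipelineConfig:
    """Validated bundle of every tunable constant in the pipeline.

    Attributes
    ----------
    line_freq
        Mains frequency removed by the notch filter, Hz.
    hfb_band
        High-frequency-band edges, Hz.  The analytic amplitude of this band
        is the response variable of the encoding model.
    filter_order
        Butterworth order of the band-pass (applied forward-backward, so the
        effective order doubles).
    epoch_window
        Post-onset window extracted per stimulus block, seconds.
    baseline_window
        Pre-onset window used for z-scoring, seconds (negative start).
    target_fs
        Working sampling rate of the amplitude traces after downsampling, Hz.
    feature_fs
        Sampling rate of the emotion-feature time courses, Hz.
    bin_width
        Width of the response bins, seconds; must equal ``1 / feature_fs``.
    lags
        Stimulus-to-response delays, seconds; each must be a non-negative
        multiple of ``1 / feature_fs``.
    alpha_grid
        Candidate ridge penalties for the shared-regularizer search.
    n_folds
        Cross-validation folds (contiguous temporal segments).
    n_perm
        Temporal-shuffle permutations for the significance test.
    min_contacts
        Minimum electrode contacts a region must have to be fitted.
    excluded_blocks
        Absolute block indices dropped from analysis, or ``None`` meaning
        "the fifth music block" (resolved against the event table).
    contact_aggregation
        "concatenate" stacks contact responses row-wise (one weight vector
        per region); "average" averages contacts before fitting.
    weight_reduction
        How per-feature weight summaries reduce over lags and folds
        ("mean" of absolute weights, or "max").
    shuffle_mode
        Temporal-shuffle null: "circular" (default) applies a random
        circular shift to the condition's feature rows, preserving their
        autocorrelation so the test stays calibrated under temporally
        autocorrelated responses; "permute" jointly permutes rows, which
        whitens the features and is measurably anticonservative.
    include_interest_in_complex
        Adds "interest" to the complex-emotion group (five-emotion reading).
    bad_channel_sd / bad_channel_frac
        Optional amplitude flagger: a channel is flagged bad when more than
        ``bad_channel_frac`` of samples exceed ``bad_channel_sd`` robust SDs.
        Disabled unless invoked explicitly.
    """

    line_freq: float = 50.0
    hfb_band: tuple[float, float] = (110.0, 140.0)
    filter_order: int = 4
    notch_q: float = 30.0
    epoch_window: tuple[float, float] = (0.0, 30.0)
    baseline_window: tuple[float, float] = (-0.2, 0.0)
    target_fs: float = 400.0
    feature_fs: float = 2.0
    bin_width: float = 0.5
    lags: tuple[float, ...] = (0.0, 0.5, 1.0)
    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    n_folds: int = 5
    n_perm: int = 5000
    min_contacts: int = 1
    rng_seed: int = 0
    excluded_blocks: tuple[int, ...] | None = None
    contact_aggregation: str = "concatenate"
    weight_reduction: str = "mean"
    shuffle_mode: str = "circular"
    include_interest_in_complex: bool = False
    bad_channel_sd: float = 8.0
    bad_channel_frac: float = 0.01
    feature_names: tuple[str, ...] = DEFAULT_FEATURE_NAMES
    complex_group: tuple[str, ...] = DEFAULT_COMPLEX_GROUP
    basic_group: tuple[str, ...] = DEFAULT_BASIC_GROUP

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.complex_group = tuple(self.complex_group)
        self.basic_group = tuple(self.basic_group)
        self.lags = tuple(float(l) for l in self.lags)
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.hfb_band
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.hfb_band}")
        if self.line_freq <= 0:
            raise ValueError("line_freq must be positive")
        if self.target_fs <= 0 or self.feature_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if abs(self.bin_width * self.feature_fs - 1.0) > 1e-9:
            raise ValueError(
                f"bin_width ({self.bin_width}) must equal 1/feature_fs "
                f"({1.0 / self.feature_fs})"
            )
        for lag in self.lags:
            if lag < 0:
                raise ValueError(f"negative lag {lag}")
            if abs(lag * self.feature_fs - round(lag * self.feature_fs)) > 1e-9:
                raise ValueError(
                    f"lag {lag} is not a multiple of 1/feature_fs"
                )
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("empty epoch window")
        if self.baseline_window[1] <= self.baseline_window[0]:
            raise ValueError("empty baseline window")
        if self.baseline_window[1] > self.epoch_window[0] + 1e-12:
            raise ValueError("baseline must end at or before epoch start")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        a = self.alpha_grid
        if a.ndim != 1 or a.size < 1 or np.any(a < 0) or np.any(np.diff(a) <= 0):
            raise ValueError("alpha_grid must be strictly increasing and >= 0")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        for group, label in ((self.complex_group, "complex"), (self.basic_group, "basic")):
            missing = [g for g in group if g not in self.feature_names]
            if missing:
                raise ValueError(f"{label} group names absent from feature list: {missing}")
        if self.contact_aggregation not in ("concatenate", "average"):
            raise ValueError("contact_aggregation must be 'concatenate' or 'average'")
        if self.weight_reduction not in ("mean", "max"):
            raise ValueError("weight_reduction must be 'mean' or 'max'")
        if self.shuffle_mode not in ("permute", "circular"):
            raise ValueError("shuffle_mode must be 'permute' or 'circular'")

    # -- derived quantities -------------------------------------------------
    @property
    def baseline_margin(self) -> float:
        """Seconds of pre-onset signal retained for baseline statistics."""
        return -float(self.baseline_window[0])

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def effective_complex_group(self) -> tuple[str, ...]:
        if self.include_interest_in_complex and "interest" not in self.complex_group:
            return self.complex_group + ("interest",)
        return self.complex_group

    def bins_per_block(self) -> int:
        span = self.epoch_window[1] - self.epoch_window[0]
        n = span / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch window is not a whole number of bins")
        return int(round(n))

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_grid"] = [float(x) for x in self.alpha_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("hfb_band", "epoch_window", "baseline_window", "lags",
                    "excluded_blocks", "feature_names", "complex_group",
                    "basic_group"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, logged for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
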