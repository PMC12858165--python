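"""Synthetic studies with known ground truth.

Emulates the stimulus/response structure the analysis assumes: a 6.5 min
film of 13 interleaved 30 s speech/music blocks (music first, so seven
music and six speech blocks; the fifth music block face-free), 48 bounded
smooth emotion-feature time courses at 2 Hz with sparse expression bursts,
and neural responses carrying a known linear lagged coupling to the
features plus AR(1) noise.  Raw-signal mode additionally synthesizes
multichannel recordings — pink background noise, a 50 Hz line component and
a 110-140 Hz band-noise carrier amplitude-modulated so that the full
preprocessing chain (band-pass, Hilbert, sqrt, baseline z-score) recovers a
trace linear in the ground-truth coupling.

Everything is driven by a single seed and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal
from scipy.special import expit

from .config import DEFAULT_FEATURE_NAMES, PipelineConfig
from .features import (FeatureTimecourse, ResponseMatrix,
                       build_design_matrix)
from .model import SubjectBundle
from .preproc import Recording, SubjectRecord, resolve_excluded_blocks

#: Relative contribution of the 0 / 0.5 / 1 s lags in ground-truth weights.
LAG_PROFILE = np.array([0.5, 0.3, 0.2])


@dataclass
class GroundTruth:
    """Known generative parameters for one synthetic subject."""

    weights: dict[str, np.ndarray]      # condition -> features x lags
    coupling_snr: float                 # feature-driven var / noise var
    ar_coef: float                      # AR(1) coefficient of response noise
    age_slope: float = 0.0              # d(coupling amp)/d(age), complex set

    def flat(self, condition: str, lags: tuple[float, ...]) -> np.ndarray:
        """Feature-major (feature, lag) flattening matching design columns."""
        return self.weights[condition].reshape(-1)


@dataclass
class SyntheticStudy:
    """A full multi-subject synthetic dataset plus its ground truth."""

    subjects: list[SubjectRecord]
    events: pd.DataFrame
    features: FeatureTimecourse               # retained blocks only
    features_full: FeatureTimecourse          # all 13 blocks
    truths: dict[str, GroundTruth]
    bundles: list[SubjectBundle] = field(default_factory=list)
    recordings: dict[str, Recording] = field(default_factory=dict)

    @property
    def ages(self) -> dict[str, float]:
        return {s.id: s.age for s in self.subjects}

    def subject_map(self) -> dict[str, SubjectRecord]:
        return {s.id: s for s in self.subjects}


# ---------------------------------------------------------------------------
# Stimulus structure
# ---------------------------------------------------------------------------

def standard_events(n_blocks: int = 13, block_duration: float = 30.0,
                    start: float = 2.0, gap: float = 0.0,
                    first_condition: str = "music") -> pd.DataFrame:
    """The standard stimulus: interleaved 30 s blocks, music first (seven
    music, six speech for 13 blocks)."""
    other = "speech" if first_condition == "music" else "music"
    rows = []
    for k in range(n_blocks):
        rows.append({
            "onset": start + k * (block_duration + gap),
            "duration": block_duration,
            "condition": first_condition if k % 2 == 0 else other,
            "block_index": k + 1,
        })
    return pd.DataFrame(rows)


def simulate_features(events: pd.DataFrame, seed: int = 0,
                      names: tuple[str, ...] = DEFAULT_FEATURE_NAMES,
                      feature_fs: float = 2.0,
                      block_duration: float = 30.0,
                      smooth_sigma: float = 3.0,
                      burst_rate: float = 0.04,
                      burst_width: int = 8,
                      face_free_blocks: tuple[int, ...] | None = None
                      ) -> FeatureTimecourse:
    """Smooth, bounded, burst-punctuated emotion scores for every block.

    Each feature is Gaussian noise smoothed over ~1.5 s (so the 2 Hz lag-1
    autocorrelation is high, as real expression scores are), plus sparse
    positive bursts mimicking expression episodes, pushed through a logistic
    squashing into (0, 1).  Face-free blocks (default: the fifth music
    block) are all zero, as no expression scores exist there.
    """
    rng = np.random.default_rng(seed)
    face_free = set(resolve_excluded_blocks(events, face_free_blocks))
    T = int(round(block_duration * feature_fs))
    F = len(names)
    kernel = np.hanning(burst_width + 2)[1:-1]
    blocks, meta = [], []
    for row in events.itertuples():
        if row.block_index in face_free:
            block = np.zeros((T, F))
        else:
            z = scipy.ndimage.gaussian_filter1d(
                rng.standard_normal((T, F)), smooth_sigma, axis=0,
                mode="nearest")
            z /= np.maximum(z.std(axis=0, keepdims=True), 1e-12)
            bursts = np.zeros((T, F))
            for f in range(F):
                n_ev = rng.poisson(burst_rate * T)
                for _ in range(n_ev):
                    t0 = rng.integers(0, T)
                    amp = rng.exponential(2.0)
                    hi = min(T, t0 + len(kernel))
                    bursts[t0:hi, f] += amp * kernel[:hi - t0]
            block = expit(1.2 * z + bursts - 1.5)
        blocks.append(block)
        meta.append({"block_index": row.block_index,
                     "condition": row.condition})
    return FeatureTimecourse(values=np.stack(blocks), fs=feature_fs,
                             names=tuple(names),
                             block_meta=pd.DataFrame(meta))


def drop_blocks(features: FeatureTimecourse,
                block_indices: tuple[int, ...]) -> FeatureTimecourse:
    keep = ~features.block_meta["block_index"].isin(block_indices).to_numpy()
    return FeatureTimecourse(
        values=features.values[keep], fs=features.fs, names=features.names,
        block_meta=features.block_meta.loc[keep].reset_index(drop=True))


def per_face_frames(features: FeatureTimecourse, events: pd.DataFrame,
                    fps: float = 25.0, n_faces: int = 2,
                    p_no_face: float = 0.0, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Expand 2 Hz block features to per-face frame scores.

    One face per frame carries exactly the bin's score; the other faces
    score strictly less, so the max-over-faces aggregation recovers the
    original values.  With probability ``p_no_face`` a frame has no face at
    all (all-NaN row).  Returns ``(frame_times, per_face)`` where
    ``per_face`` is frames x faces x features.
    """
    rng = np.random.default_rng(seed)
    onset = {row.block_index: row.onset for row in events.itertuples()}
    frames_per_block = int(round(30.0 * fps))
    times, scores = [], []
    for b, row in enumerate(features.block_meta.itertuples()):
        t0 = onset[row.block_index]
        for i in range(frames_per_block):
            t = i / fps
            k = min(int(t * features.fs), features.n_bins - 1)
            v = features.values[b, k]
            face_rows = np.full((n_faces, len(features.names)), np.nan)
            if rng.random() >= p_no_face:
                top = rng.integers(0, n_faces)
                for j in range(n_faces):
                    face_rows[j] = v if j == top else v * rng.uniform(0, 1)
            times.append(t0 + t)
            scores.append(face_rows)
    return np.array(times), np.stack(scores)


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float,
         var: float) -> np.ndarray:
    """Stationary AR(1) noise along the second-to-last axis (time),
    restarted independently per block and contact."""
    if not (0 <= phi < 1):
        raise ValueError("AR(1) coefficient must be in [0, 1)")
    sd_innov = np.sqrt(var * (1 - phi ** 2))
    eps = rng.normal(0.0, sd_innov, size=shape)
    out = np.empty(shape)
    out[..., 0, :] = rng.normal(0.0, np.sqrt(var), size=shape[:-2] + (shape[-1],))
    for t in range(1, shape[-2]):
        out[..., t, :] = phi * out[..., t - 1, :] + eps[..., t, :]
    return out


def simulate_response(features: FeatureTimecourse,
                      truth: GroundTruth,
                      lags: tuple[float, ...] = (0.0, 0.5, 1.0),
                      n_contacts: int = 1,
                      seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Binned responses: lagged linear coupling plus AR(1) noise.

    ``y_c(t) = sum_f sum_tau w(f, tau) x_f(t - tau) + eps_c(t)`` with noise
    independent per contact and its stationary variance set per condition so
    that feature-driven variance / noise variance equals
    ``truth.coupling_snr`` (conditions with zero coupling get unit-variance
    noise).  Returns ``(Y, row_meta)`` with Y rows x contacts, rows aligned
    with :func:`build_design_matrix`.
    """
    design = build_design_matrix(features, lags)
    F = len(features.names)
    L = len(lags)
    n_rows = design.X.shape[0]
    s = np.zeros(n_rows)
    for condition, W in truth.weights.items():
        W = np.asarray(W, dtype=float)
        if W.shape != (F, L):
            raise ValueError(f"weights for {condition!r} must be {F} x {L}")
        mask = (design.row_meta["condition"] == condition).to_numpy()
        s[mask] = design.X[mask] @ W.reshape(-1)
    rng = np.random.default_rng(seed)
    B = features.n_blocks
    T = features.n_bins
    noise = np.empty((B, T, n_contacts))
    cond_per_block = features.block_meta["condition"].to_numpy()
    s_blocks = s.reshape(B, T)
    for condition in np.unique(cond_per_block):
        bmask = cond_per_block == condition
        v_sig = float(s_blocks[bmask].var())
        var_noise = v_sig / truth.coupling_snr if v_sig > 0 else 1.0
        noise[bmask] = _ar1(rng, (int(bmask.sum()), T, n_contacts),
                            truth.ar_coef, var_noise)
    Y = s_blocks.reshape(-1)[:, None] + noise.reshape(B * T, n_contacts)
    return Y, design.row_meta


# ---------------------------------------------------------------------------
# Raw signals
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spectrum /= np.sqrt(f)
    out = np.fft.irfft(spectrum, n)
    return out / out.std()


def _band_carrier(rng: np.random.Generator, n: int, fs: float,
                  band: tuple[float, float], stability: float) -> np.ndarray:
    """Unit-mean-amplitude carrier inside the band.

    A mixture of a frequency-wandering constant-amplitude tone (fraction
    ``stability`` of the power) and Gaussian band-limited noise.  A purely
    Gaussian carrier has a Rayleigh envelope whose fluctuations are as large
    as the envelope itself; the tone component stabilizes the instantaneous
    amplitude so the modulation imposed on the carrier, not the carrier's
    own stochasticity, dominates the extracted envelope.
    """
    lo, hi = band
    center = 0.5 * (lo + hi)
    # keep the wander well inside the band so the extraction filter's
    # response is flat over it (edge droop would turn frequency wander into
    # slow amplitude fluctuations)
    dev = 0.08 * (hi - lo)
    sigma = 0.02 * fs
    wander = scipy.ndimage.gaussian_filter1d(rng.standard_normal(n), sigma,
                                             mode="nearest")
    wander /= max(wander.std(), 1e-12)
    f_inst = np.clip(center + dev * wander,
                     center - 0.25 * (hi - lo), center + 0.25 * (hi - lo))
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    tone = np.sqrt(2.0) * np.cos(phase)           # unit power
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    noise = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    noise /= max(noise.std(), 1e-12)
    carrier = np.sqrt(stability) * tone + np.sqrt(1 - stability) * noise
    return carrier / np.abs(scipy.signal.hilbert(carrier)).mean()


def simulate_raw(envelopes: np.ndarray, env_times: np.ndarray,
                 fs: float, duration: float,
                 channels: pd.DataFrame, seed: int = 0,
                 band: tuple[float, float] = (110.0, 140.0),
                 line_freq: float = 50.0,
                 background_rel: float = 0.3,
                 line_rel: float = 2.0,
                 carrier_stability: float = 0.95) -> Recording:
    """Raw multichannel signal whose band envelope follows a target.

    Per channel: an independent in-band carrier (see :func:`_band_carrier`),
    normalized to unit mean analytic amplitude, is multiplied by the target
    envelope (linearly interpolated to the raw rate), then pink background
    noise and a channel-common 50 Hz line component are added, both scaled
    relative to the mean envelope.
    """
    if fs < 2 * band[1]:
        raise ValueError(f"fs={fs} too low for band {band}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    n_ch = envelopes.shape[0]
    if len(channels) != n_ch:
        raise ValueError("channel table does not match envelope count")
    line = np.sin(2 * np.pi * line_freq * t + rng.uniform(0, 2 * np.pi))
    data = np.empty((n, n_ch))
    for c in range(n_ch):
        env = np.clip(np.interp(t, env_times, envelopes[c]), 0.0, None)
        carrier = _band_carrier(rng, n, fs, band, carrier_stability)
        scale = env.mean() if env.mean() > 0 else 1.0
        data[:, c] = (env * carrier
                      + background_rel * scale * _pink_noise(rng, n)
                      + line_rel * scale * line)
    return Recording(data=data, fs=fs, channels=channels)


def region_channels(region: str, n_contacts: int,
                    n_other: int = 2) -> pd.DataFrame:
    names = [f"{region}{i + 1}" for i in range(n_contacts)]
    names += [f"oth{i + 1}" for i in range(n_other)]
    return pd.DataFrame({
        "name": names,
        "region": [region] * n_contacts + ["other"] * n_other,
        "hemisphere": ["L"] * len(names),
        "status": ["good"] * len(names),
    })


def simulate_subject_raw(subject: SubjectRecord, events: pd.DataFrame,
                         features_full: FeatureTimecourse,
                         truth: GroundTruth,
                         lags: tuple[float, ...] = (0.0, 0.5, 1.0),
                         region: str = "pSTC", n_contacts: int = 4,
                         n_other: int = 2, fs: float = 2048.0,
                         mod_depth: float = 0.3,
                         seed: int = 0) -> Recording:
    """Raw recording for one subject with known feature coupling.

    The per-contact HFB target envelope is ``(1 + mod_depth * u)^2`` where
    ``u`` is the z-scored lagged linear predictor plus AR(1) noise at the
    configured coupling SNR; the square compensates the pipeline's
    square-root transform so the normalized output is (up to carrier
    estimation noise) linear in the ground-truth coupling.
    """
    rng = np.random.default_rng(seed)
    excluded = resolve_excluded_blocks(events, None)
    Y, row_meta = simulate_response(features_full, truth, lags,
                                    n_contacts=n_contacts,
                                    seed=int(rng.integers(2 ** 31)))
    retained = ~row_meta["block_index"].isin(excluded).to_numpy()
    mu = Y[retained].mean(axis=0)
    sd = Y[retained].std(axis=0)
    u = (Y - mu) / sd
    env_lin = np.clip(1.0 + mod_depth * u, 0.05, None)
    env = (env_lin ** 2).T                      # contacts x rows

    onsets = {row.block_index: row.onset for row in events.itertuples()}
    times = np.array([
        onsets[b] + (k + 0.5) / features_full.fs
        for b, k in zip(row_meta["block_index"], row_meta["bin"])])
    duration = float(events["onset"].max() + events["duration"].max() + 2.0)
    # outside the blocks the envelope rests at each contact's mean stimulus
    # level, so pre-onset baselines (when the stimulus has inter-block
    # pauses) share the blocks' DC level; rest anchors are only inserted
    # where they do not fall inside another block
    rest = env.mean(axis=1, keepdims=True)
    bounds = [(row.onset, row.onset + row.duration)
              for row in events.itertuples()]

    def _free(t: float) -> bool:
        return all(not (b0 - 1e-9 < t < b1 + 1e-9) for b0, b1 in bounds)

    anchor_t = [0.0, duration]
    for b0, b1 in bounds:
        for t in (b0 - 0.5, b0 - 0.02, b1 + 0.02, b1 + 0.5):
            if 0 < t < duration and _free(t):
                anchor_t.append(t)
    anchor_t = np.array(sorted(anchor_t))
    pad_t = np.concatenate((anchor_t, times))
    order = np.argsort(pad_t, kind="stable")
    env_pad = np.concatenate(
        [np.repeat(rest, len(anchor_t), axis=1), env], axis=1)[:, order]
    pad_t = pad_t[order]
    other = np.ones((n_other, env_pad.shape[1]))
    channels = region_channels(region, n_contacts, n_other)
    return simulate_raw(np.vstack([env_pad, other]), pad_t, fs, duration,
                        channels, seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _sparse_weights(rng: np.random.Generator,
                    names: tuple[str, ...],
                    amplitudes: dict[str, float],
                    lags: tuple[float, ...]) -> np.ndarray:
    """features x lags ground-truth weights: amplitude x lag profile with
    random sign per feature; features not listed stay zero."""
    W = np.zeros((len(names), len(lags)))
    profile = LAG_PROFILE[:len(lags)]
    profile = profile / profile.sum()
    for f, amp in amplitudes.items():
        i = names.index(f)
        W[i] = rng.choice([-1.0, 1.0]) * max(amp, 0.0) * profile
    return W


def simulate_cohort(n_subjects: int = 12,
                    age_range: tuple[float, float] = (6.0, 50.0),
                    age_slope: float = 0.02,
                    base_complex: float = 0.1,
                    basic_level: float = 0.2,
                    jitter_sd: float = 0.03,
                    region: str = "pSTC",
                    n_contacts: int = 4,
                    snr: float = 1.0,
                    ar_coef: float = 0.3,
                    raw: bool = False,
                    seed: int = 0,
                    config: PipelineConfig | None = None) -> SyntheticStudy:
    """Cohort whose complex-emotion coupling grows linearly with age.

    Every subject couples to the complex and basic emotion features; the
    complex amplitudes follow ``base_complex + age_slope * age`` plus
    Gaussian jitter while the basic amplitudes stay at ``basic_level`` plus
    jitter, mirroring a development-dependent dissociation with known
    ground truth.

    Response noise emulates recording noise, which does not know about
    coupling strength: its variance is the same for every subject, fixed so
    that the subject at the cohort-median coupling sees the requested
    ``snr``.  (Scaling noise per subject instead would make the weight
    estimation error grow with age and leak an artifactual age correlation
    into every feature's absolute weight.)
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if age_range[1] <= age_range[0]:
        raise ValueError("degenerate age range")
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    events = standard_events()
    features_full = simulate_features(events, seed=int(rng.integers(2 ** 31)),
                                      names=cfg.feature_names,
                                      feature_fs=cfg.feature_fs)
    excluded = resolve_excluded_blocks(events, cfg.excluded_blocks)
    features = drop_blocks(features_full, excluded)

    ages = np.round(np.sort(rng.uniform(*age_range, size=n_subjects)), 1)
    weight_list = []
    for age in ages:
        amplitudes = {}
        for f in cfg.effective_complex_group:
            amplitudes[f] = base_complex + age_slope * age + rng.normal(0, jitter_sd)
        for f in cfg.basic_group:
            amplitudes[f] = basic_level + rng.normal(0, jitter_sd)
        weight_list.append(_sparse_weights(rng, cfg.feature_names,
                                           amplitudes, cfg.lags))
    design_X = build_design_matrix(features, cfg.lags).X
    v_sig = np.array([design_X @ W.reshape(-1) for W in weight_list]).var(axis=1)
    v_noise = float(np.median(v_sig)) / snr

    subjects, truths, bundles, recordings = [], {}, [], {}
    for i, age in enumerate(ages):
        sid = f"sim{i + 1:02d}"
        group = "childhood" if age <= 12 else "post_childhood"
        subject = SubjectRecord(id=sid, age=float(age), group=group)
        W = weight_list[i]
        truth = GroundTruth(weights={"speech": W, "music": W},
                            coupling_snr=float(v_sig[i] / v_noise),
                            ar_coef=ar_coef, age_slope=age_slope)
        truths[sid] = truth
        subjects.append(subject)
        sub_seed = int(rng.integers(2 ** 31))
        if raw:
            recordings[sid] = simulate_subject_raw(
                subject, events, features_full, truth, cfg.lags,
                region=region, n_contacts=n_contacts, fs=2048.0,
                seed=sub_seed)
        else:
            Y, row_meta = simulate_response(features, truth, cfg.lags,
                                            n_contacts=n_contacts,
                                            seed=sub_seed)
            channels = region_channels(region, n_contacts, n_other=0)
            bundles.append(SubjectBundle(
                subject=subject,
                response=ResponseMatrix(Y=Y, row_meta=row_meta,
                                        channels=channels)))
    return SyntheticStudy(subjects=subjects, events=events,
                          features=features, features_full=features_full,
                          truths=truths, bundles=bundles,
                          recordings=recordings)


def simulate_group_contrast(n_childhood: int = 8, n_post: int = 13,
                            region: str = "DLPFC",
                            coupled_group: str = "post_childhood",
                            coupled_conditions: tuple[str, ...] = ("speech", "music"),
                            amp: float = 0.25,
                            snr: float = 0.5,
                            ar_coef: float = 0.3,
                            n_contacts: int = 4,
                            seed: int = 0,
                            config: PipelineConfig | None = None
                            ) -> SyntheticStudy:
    """Two developmental groups, feature coupling only in one of them.

    The structural analogue of a development-dependent region: subjects of
    ``coupled_group`` carry coupling (amplitude ``amp`` on the complex and
    basic emotion features, in ``coupled_conditions``); the other group's
    responses are pure AR(1) noise.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    events = standard_events()
    features_full = simulate_features(events, seed=int(rng.integers(2 ** 31)),
                                      names=cfg.feature_names,
                                      feature_fs=cfg.feature_fs)
    excluded = resolve_excluded_blocks(events, cfg.excluded_blocks)
    features = drop_blocks(features_full, excluded)

    plan = ([("childhood", rng.uniform(5, 10)) for _ in range(n_childhood)]
            + [("post_childhood", rng.uniform(13, 55)) for _ in range(n_post)])
    subjects, truths, bundles = [], {}, []
    F, L = len(cfg.feature_names), cfg.n_lags
    for i, (group, age) in enumerate(plan):
        sid = f"sim{i + 1:02d}"
        subject = SubjectRecord(id=sid, age=round(float(age), 1), group=group)
        weights = {}
        for condition in ("speech", "music"):
            if group == coupled_group and condition in coupled_conditions:
                amplitudes = {f: amp + rng.normal(0, 0.02)
                              for f in (cfg.effective_complex_group
                                        + cfg.basic_group)}
                weights[condition] = _sparse_weights(
                    rng, cfg.feature_names, amplitudes, cfg.lags)
            else:
                weights[condition] = np.zeros((F, L))
        truth = GroundTruth(weights=weights, coupling_snr=snr,
                            ar_coef=ar_coef)
        truths[sid] = truth
        subjects.append(subject)
        Y, row_meta = simulate_response(features, truth, cfg.lags,
                                        n_contacts=n_contacts,
                                        seed=int(rng.integers(2 ** 31)))
        channels = region_channels(region, n_contacts, n_other=0)
        bundles.append(SubjectBundle(
            subject=subject,
            response=ResponseMatrix(Y=Y, row_meta=row_meta,
                                    channels=channels)))
    return SyntheticStudy(subjects=subjects, events=events,
                          features=features, features_full=features_full,
                          truths=truths, bundles=bundles)
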