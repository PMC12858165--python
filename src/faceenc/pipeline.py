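"""End-to-end orchestration: study on disk -> fits -> inference -> tables.

Glue between the stage modules.  A "study" is one stimulus (events +
feature table) plus per-subject recordings or pre-binned responses; the
analysis builds the shared lagged design, fits every subject x region x
condition with the shared ridge penalty, runs temporal-shuffle permutation
tests, computes the group statistics and the weight-by-age summary.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import PipelineConfig, logger
from .features import (FeatureTimecourse, ResponseMatrix,
                       aggregate_faces_table, bin_response,
                       build_design_matrix, resample_features)
from .model import EncodingFit, SubjectBundle, fit_all
from .preproc import SubjectRecord, preprocess, resolve_excluded_blocks
from .stats import GroupStat, PermutationResult, one_sample_t, paired_t, \
    permutation_test, voice_effect
from .synthetic import SyntheticStudy
from .weights import correlate_with_age, summarize_weights, weights_table


@dataclass
class StudyResults:
    fits: list[EncodingFit]
    alpha: float
    perm: dict[tuple[str, str, str], PermutationResult]
    group_stats: dict
    weight_table: pd.DataFrame | None = None
    age_correlations: pd.DataFrame | None = None
    group_correlations: dict | None = None

    def fit_records(self) -> list[dict]:
        records = []
        for fit in self.fits:
            rec = fit.to_record()
            key = (fit.subject_id, fit.region, fit.condition)
            if key in self.perm:
                rec["perm_p"] = self.perm[key].p_two_tailed
            records.append(rec)
        return records


def bundles_from_recordings(recordings: dict[str, "object"],
                            subjects: list[SubjectRecord],
                            events: pd.DataFrame,
                            config: PipelineConfig) -> list[SubjectBundle]:
    """Preprocess raw recordings into binned-response bundles."""
    by_id = {s.id: s for s in subjects}
    bundles = []
    for sid in sorted(recordings):
        epochs = preprocess(recordings[sid], events, config)
        response = bin_response(epochs, config.bin_width,
                                n_bins=config.bins_per_block())
        bundles.append(SubjectBundle(subject=by_id[sid], response=response))
    return bundles


def analyze_study(study: SyntheticStudy, config: PipelineConfig,
                  n_perm: int | None = None,
                  weight_region: str = "pSTC",
                  weight_condition: str = "speech",
                  include_threshold: float = 0.05) -> StudyResults:
    """Run the full analysis on an in-memory study.

    ``n_perm=0`` skips permutation testing (all fits treated as included
    for the weight analysis); ``n_perm=None`` uses the configured count.
    """
    bundles = list(study.bundles)
    if study.recordings:
        bundles += bundles_from_recordings(
            study.recordings, study.subjects, study.events, config)
    design = build_design_matrix(study.features, config.lags)
    fits, alpha, _ = fit_all(design, bundles, config)

    n_perm = config.n_perm if n_perm is None else n_perm
    perm: dict[tuple[str, str, str], PermutationResult] = {}
    if n_perm:
        by_id = {b.subject.id: b for b in bundles}
        for fit in fits:
            res = permutation_test(
                study.features, by_id[fit.subject_id].response,
                fit.region, fit.condition, alpha, config, n_perm=n_perm,
                seed=(config.rng_seed + zlib.crc32(
                    f"{fit.subject_id}/{fit.region}/{fit.condition}"
                    .encode()) % 100003) % (2 ** 31))
            perm[(fit.subject_id, fit.region, fit.condition)] = res

    subject_map = study.subject_map()
    group_stats = _group_statistics(fits, subject_map)

    weight_table = age_corr = group_corr = None
    relevant = [f for f in fits if f.region == weight_region
                and f.condition == weight_condition]
    if relevant:
        summaries = []
        for fit in relevant:
            key = (fit.subject_id, fit.region, fit.condition)
            included = (perm[key].p_two_tailed < include_threshold
                        if key in perm else True)
            summaries.append(summarize_weights(fit, config, included=included))
        ages = study.ages
        weight_table = weights_table(summaries, ages)
        included = [s for s in summaries if s.included]
        if len(included) >= 3:
            try:
                age_corr, groups = correlate_with_age(summaries, ages)
                group_corr = {k: {"r": v.r, "p": v.p_uncorrected, "n": v.n}
                              for k, v in groups.items()}
            except ValueError as exc:
                logger.warning("weight-age correlation skipped: %s", exc)
    return StudyResults(fits=fits, alpha=alpha, perm=perm,
                        group_stats=group_stats, weight_table=weight_table,
                        age_correlations=age_corr,
                        group_correlations=group_corr)


def _group_statistics(fits: list[EncodingFit],
                      subjects: dict[str, SubjectRecord]) -> dict:
    """One-sample tests per region x condition x group, paired speech-music
    tests per region x group, and the between-group voice-effect contrast."""
    stats: dict = {}
    frame = pd.DataFrame([{
        "subject": f.subject_id, "region": f.region,
        "condition": f.condition, "mean_r": f.mean_r,
        "group": subjects[f.subject_id].group} for f in fits])
    for (region, condition, group), sub in frame.groupby(
            ["region", "condition", "group"]):
        if len(sub) >= 2:
            key = f"{region}.{condition}.{group}.one_sample"
            try:
                stats[key] = one_sample_t(sub["mean_r"].to_numpy()).to_record()
            except ValueError as exc:
                logger.warning("%s skipped: %s", key, exc)
    for (region, group), sub in frame.groupby(["region", "group"]):
        wide = sub.pivot(index="subject", columns="condition",
                         values="mean_r").dropna()
        if {"speech", "music"} <= set(wide.columns) and len(wide) >= 2:
            key = f"{region}.{group}.paired_speech_music"
            try:
                stats[key] = paired_t(wide["speech"].to_numpy(),
                                      wide["music"].to_numpy()).to_record()
            except ValueError as exc:
                logger.warning("%s skipped: %s", key, exc)
    for region in frame["region"].unique():
        region_fits = [f for f in fits if f.region == region]
        have_both = {f.subject_id for f in region_fits
                     if f.condition == "speech"} & {
                         f.subject_id for f in region_fits
                         if f.condition == "music"}
        usable = [f for f in region_fits if f.subject_id in have_both]
        if usable:
            df, contrast = voice_effect(usable, subjects, region)
            stats[f"{region}.voice_effect"] = {
                "per_subject": df.to_dict(orient="records"),
                "group_contrast": contrast.to_record() if contrast else None,
            }
    return stats


# ---------------------------------------------------------------------------
# On-disk studies
# ---------------------------------------------------------------------------

def study_to_disk(study: SyntheticStudy, out_dir: str | Path,
                  config: PipelineConfig) -> None:
    """Write a study as TSV tables plus per-subject signal/response files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"id": s.id, "age": s.age, "group": s.group,
                   "sex": s.sex or ""} for s in study.subjects]).to_csv(
        out / "subjects.tsv", sep="\t", index=False)
    events = study.events.rename(columns={"condition": "trial_type"})
    events.to_csv(out / "events.tsv", sep="\t", index=False)

    # feature frames at the native 2 Hz rate, one frame per bin center
    onsets = {r.block_index: r.onset for r in study.events.itertuples()}
    rows = []
    for b, meta in enumerate(study.features.block_meta.itertuples()):
        t0 = onsets[meta.block_index]
        for k in range(study.features.n_bins):
            row = {"time": t0 + (k + 0.5) / study.features.fs}
            row.update(dict(zip(study.features.names,
                                study.features.values[b, k])))
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "features.tsv", sep="\t", index=False,
                              float_format="%.8g")

    truth = {sid: {
        "coupling_snr": t.coupling_snr, "ar_coef": t.ar_coef,
        "age_slope": t.age_slope,
        "weights": {c: w.tolist() for c, w in t.weights.items()},
    } for sid, t in study.truths.items()}
    (out / "ground_truth.json").write_text(json.dumps(truth, sort_keys=True))

    for sid, rec in study.recordings.items():
        sub = out / f"sub-{sid}"
        sub.mkdir(exist_ok=True)
        fio.write_binary_recording(rec, sub / f"sub-{sid}_ieeg.bin")
        rec.channels.to_csv(sub / f"sub-{sid}_channels.tsv", sep="\t",
                            index=False)
    for bundle in study.bundles:
        sid = bundle.subject.id
        sub = out / f"sub-{sid}"
        sub.mkdir(exist_ok=True)
        resp = bundle.response
        path = sub / f"sub-{sid}_responses.bin"
        resp.Y.astype("<f8").tofile(path)
        meta = {"shape": list(resp.Y.shape),
                "row_meta": resp.row_meta.to_dict(orient="list"),
                "channels": resp.channels.to_dict(orient="list")}
        path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))


def study_from_disk(in_dir: str | Path,
                    config: PipelineConfig) -> SyntheticStudy:
    """Load a study directory (as written by :func:`study_to_disk`).

    Subjects with raw ``*_ieeg.bin``/``.edf`` files are preprocessed lazily
    by :func:`analyze_study`; subjects with pre-binned ``*_responses.bin``
    load directly.
    """
    in_dir = Path(in_dir)
    subjects = fio.read_subjects(in_dir / "subjects.tsv")
    events = fio.read_events(in_dir / "events.tsv")
    raw_features = fio.read_features(in_dir / "features.tsv",
                                     config.feature_names)
    raw_features = aggregate_faces_table(raw_features, config.feature_names)
    features = resample_features(
        raw_features["time"].to_numpy(),
        raw_features[list(config.feature_names)].to_numpy(),
        events, config.feature_names, config.feature_fs,
        config.epoch_window, config.excluded_blocks)

    bundles, recordings = [], {}
    for subject in subjects:
        sub = in_dir / f"sub-{subject.id}"
        resp_path = sub / f"sub-{subject.id}_responses.bin"
        sig_bin = sub / f"sub-{subject.id}_ieeg.bin"
        sig_edf = sub / f"sub-{subject.id}_ieeg.edf"
        chan_path = sub / f"sub-{subject.id}_channels.tsv"
        if resp_path.exists():
            meta = json.loads(resp_path.with_suffix(".json").read_text())
            Y = np.fromfile(resp_path, dtype="<f8").reshape(meta["shape"])
            bundles.append(SubjectBundle(
                subject=subject,
                response=ResponseMatrix(
                    Y=Y, row_meta=pd.DataFrame(meta["row_meta"]),
                    channels=pd.DataFrame(meta["channels"]))))
        elif sig_bin.exists() or sig_edf.exists():
            path = sig_bin if sig_bin.exists() else sig_edf
            recordings[subject.id] = fio.read_recording(path, chan_path,
                                                        subject=subject)
        else:
            logger.warning("subject %s has no signal/response file; skipped",
                           subject.id)
    truths = {}
    truth_path = in_dir / "ground_truth.json"
    if truth_path.exists():
        from .synthetic import GroundTruth
        raw = json.loads(truth_path.read_text())
        truths = {sid: GroundTruth(
            weights={c: np.array(w) for c, w in t["weights"].items()},
            coupling_snr=t["coupling_snr"], ar_coef=t["ar_coef"],
            age_slope=t.get("age_slope", 0.0)) for sid, t in raw.items()}
    excluded = resolve_excluded_blocks(events, config.excluded_blocks)
    from .synthetic import drop_blocks
    return SyntheticStudy(subjects=subjects, events=events,
                          features=features,
                          features_full=features, truths=truths,
                          bundles=bundles, recordings=recordings)


def results_to_disk(results: StudyResults, out_dir: str | Path,
                    config: PipelineConfig) -> dict[str, Path]:
    group_stats = dict(results.group_stats)
    group_stats["shared_alpha"] = results.alpha
    if results.group_correlations:
        group_stats["weight_age_correlations"] = results.group_correlations
    return fio.write_results(out_dir, results.fit_records(), group_stats,
                             config, weights=results.weight_table,
                             correlations=results.age_correlations)
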