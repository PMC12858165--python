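"""Reading and writing the pipeline's external formats.

Signals come in as EDF (read through MNE) or as a raw numeric binary with a
JSON sidecar ``{"fs": ..., "channel_names": [...], "dtype": ...}``; an
optional reader handles a minimal BIDS-iEEG directory (``*_ieeg.edf`` or
``.bin`` plus ``*_channels.tsv`` and ``*_events.tsv``).  Events, features and
subjects are plain TSV.  Results are serialized deterministically (sorted
keys, fixed float precision) together with the configuration snapshot and
seed, so identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, logger
from .preproc import (CONDITIONS, HFBEpochs, Recording, SubjectRecord,
                      validate_channel_table)


class FormatError(ValueError):
    """The file is not in a recognized/consistent format."""


class MetadataError(ValueError):
    """Metadata (channel table, sidecar) disagrees with the signal file."""


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

def read_channel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    return validate_channel_table(df)


def read_recording(path: str | Path,
                   channel_table_path: str | Path,
                   subject: SubjectRecord | None = None) -> Recording:
    """Load a signal file and attach contact metadata.

    The channel table must name exactly the channels present in the file
    (order taken from the file); mismatches raise :class:`MetadataError`
    listing the offending names.
    """
    path = Path(path)
    channels = read_channel_table(channel_table_path)
    if path.suffix.lower() == ".edf":
        data, fs, names = _read_edf(path)
    elif path.suffix.lower() == ".bin":
        data, fs, names = _read_binary(path)
    else:
        raise FormatError(f"unknown signal format: {path.suffix!r}")
    table_names = list(channels["name"])
    extra_in_table = sorted(set(table_names) - set(names))
    extra_in_file = sorted(set(names) - set(table_names))
    if extra_in_table or extra_in_file:
        raise MetadataError(
            f"channel mismatch: in table but not file {extra_in_table}, "
            f"in file but not table {extra_in_file}"
        )
    channels = channels.set_index("name").loc[names].reset_index()
    return Recording(data=data, fs=fs, channels=channels, subject=subject)


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T  # samples x channels
    # MNE rescales recognized physical units to SI; undo so the values match
    # the file (the pipeline is scale invariant, this only aids round-trips).
    orig_units = getattr(raw, "_orig_units", {}) or {}
    scale = {"V": 1.0, "mV": 1e3, "uV": 1e6, "µV": 1e6}
    factors = np.array([scale.get(orig_units.get(name, ""), 1.0)
                        for name in raw.ch_names])
    data = data * factors
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def _read_binary(path: Path) -> tuple[np.ndarray, float, list[str]]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channel_names", "dtype"):
        if key not in meta:
            raise FormatError(f"sidecar missing key {key!r}")
    if meta["fs"] <= 0:
        raise FormatError(f"invalid sampling rate {meta['fs']}")
    names = list(meta["channel_names"])
    flat = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    if len(names) == 0 or flat.size % len(names):
        raise FormatError("file size not a multiple of the channel count")
    data = flat.reshape(-1, len(names)).astype(float)
    return data, float(meta["fs"]), names


def write_binary_recording(rec: Recording, path: str | Path,
                           dtype: str = "<f4") -> None:
    """Write samples x channels binary plus JSON sidecar."""
    path = Path(path)
    rec.data.astype(np.dtype(dtype)).tofile(path)
    sidecar = {"fs": rec.fs, "channel_names": list(rec.channels["name"]),
               "dtype": dtype, "n_samples": rec.n_samples}
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a plain EDF file (16-bit, one 1 s data record per second).

    The sampling rate must be a whole number of samples per second.  Each
    channel is scaled to its own physical range; values are quantized to the
    EDF 16-bit grid, so round-trips are exact only to ~1/65000 of the range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = math.ceil(rec.n_samples / spr)
    n_ch = rec.n_channels
    padded = np.zeros((n_rec * spr, n_ch))
    padded[:rec.n_samples] = rec.data

    phys_min = padded.min(axis=0)
    phys_max = padded.max(axis=0)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * gain + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    names = [str(n) for n in rec.channels["name"]]
    header += b"".join(f(n, 16) for n in names)
    header += b"".join(f("", 80) for _ in names)          # transducer
    header += b"".join(f("uV", 8) for _ in names)          # physical dim
    header += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_min)
    header += b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_max)
    header += b"".join(f(str(dig_min), 8) for _ in names)
    header += b"".join(f(str(dig_max), 8) for _ in names)
    header += b"".join(f("", 80) for _ in names)           # prefiltering
    header += b"".join(f(str(spr), 8) for _ in names)
    header += b"".join(f("", 32) for _ in names)           # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[r * spr:(r + 1) * spr]  # spr x n_ch
            fh.write(chunk.T.tobytes())


def read_bids_recording(directory: str | Path,
                        subject: SubjectRecord | None = None
                        ) -> tuple[Recording, pd.DataFrame]:
    """Minimal BIDS-iEEG directory reader.

    Expects exactly one ``*_ieeg.edf`` or ``*_ieeg.bin`` signal file plus
    ``*_channels.tsv`` (name, type, status[, region, hemisphere]) and
    ``*_events.tsv`` in the same directory.  Returns the recording and the
    parsed event table.
    """
    directory = Path(directory)
    signals = sorted(directory.glob("*_ieeg.edf")) + sorted(directory.glob("*_ieeg.bin"))
    if len(signals) != 1:
        raise FormatError(f"expected one *_ieeg signal file, found {len(signals)}")
    chan_files = sorted(directory.glob("*_channels.tsv"))
    event_files = sorted(directory.glob("*_events.tsv"))
    if not chan_files or not event_files:
        raise FormatError("missing *_channels.tsv or *_events.tsv")
    chans = pd.read_csv(chan_files[0], sep="\t", dtype={"name": str})
    if "region" not in chans.columns:
        chans["region"] = "other"
    if "hemisphere" not in chans.columns:
        chans["hemisphere"] = "L"
    if "status" not in chans.columns:
        chans["status"] = "good"
    table = chans[["name", "region", "hemisphere", "status"]]
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
        table.to_csv(tmp.name, sep="\t", index=False)
        rec = read_recording(signals[0], tmp.name, subject=subject)
    Path(tmp.name).unlink(missing_ok=True)
    events = read_events(event_files[0])
    return rec, events


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> pd.DataFrame:
    """Parse and validate the block event table.

    TSV columns: ``onset``, ``duration``, ``trial_type`` (or ``condition``),
    ``block_index``.  Blocks must be non-overlapping; conditions must be
    speech or music.  Returned sorted by onset with a ``condition`` column.
    """
    df = pd.read_csv(path, sep="\t")
    if "condition" not in df.columns and "trial_type" in df.columns:
        df = df.rename(columns={"trial_type": "condition"})
    missing = {"onset", "duration", "condition", "block_index"} - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return validate_events(df)


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values("onset").reset_index(drop=True)
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    if (df["duration"] <= 0).any():
        raise ValueError("non-positive block duration")
    if df["block_index"].duplicated().any():
        raise ValueError("duplicate block_index")
    ends = df["onset"] + df["duration"]
    if (df["onset"].to_numpy()[1:] < ends.to_numpy()[:-1] - 1e-9).any():
        raise ValueError("blocks overlap")
    df["block_index"] = df["block_index"].astype(int)
    return df


def read_features(path: str | Path,
                  feature_names: tuple[str, ...]) -> pd.DataFrame:
    """Read a per-frame feature table: ``time`` + one column per emotion.

    An optional ``face_id`` column marks per-face rows (several rows may
    share a timestamp); aggregation over faces happens downstream.  Scores
    must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError("feature table missing 'time' column")
    missing = [n for n in feature_names if n not in df.columns]
    if missing:
        raise ValueError(f"feature table missing emotion columns: {missing}")
    scores = df[list(feature_names)].to_numpy(dtype=float)
    if np.nanmin(scores) < -1e-9 or np.nanmax(scores) > 1 + 1e-9:
        raise ValueError("feature scores outside [0, 1]")
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read the subject table (id, age, group[, sex])."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "age", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    subjects = []
    for row in df.itertuples():
        sex = getattr(row, "sex", None)
        subjects.append(SubjectRecord(id=row.id, age=float(row.age),
                                      group=row.group,
                                      sex=None if pd.isna(sex) else sex))
    return subjects


# ---------------------------------------------------------------------------
# Epoch / array persistence
# ---------------------------------------------------------------------------

def save_epochs(epochs: HFBEpochs, path: str | Path) -> None:
    """HFB epochs as float32 binary + JSON sidecar (shape, fs, metadata)."""
    path = Path(path)
    epochs.data.astype("<f4").tofile(path)
    meta = {
        "shape": list(epochs.data.shape),
        "fs": epochs.fs,
        "n_margin": epochs.n_margin,
        "normalized": epochs.normalized,
        "block_meta": epochs.block_meta.to_dict(orient="list"),
        "channels": epochs.channels.to_dict(orient="list"),
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))


def load_epochs(path: str | Path) -> HFBEpochs:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return HFBEpochs(data=data.astype(float), fs=meta["fs"],
                     block_meta=pd.DataFrame(meta["block_meta"]),
                     channels=pd.DataFrame(meta["channels"]),
                     n_margin=meta["n_margin"],
                     normalized=meta["normalized"])


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _clean(obj, _warned=None):
    """Round floats, map NaN/inf to null (with one warning), sort keys."""
    if isinstance(obj, dict):
        return {k: _clean(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not math.isfinite(v):
            logger.warning("non-finite value serialized as null")
            return None
        return round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    return obj


def write_results(out_dir: str | Path,
                  fits: list[dict],
                  group_stats: dict,
                  config: PipelineConfig,
                  weights: pd.DataFrame | None = None,
                  correlations: pd.DataFrame | None = None) -> dict[str, Path]:
    """Serialize fit summaries, group statistics and weight tables.

    Produces ``results.json`` (per subject/region/condition fit records plus
    a config snapshot), ``group_stats.json`` and, when given,
    ``weights.tsv`` / ``age_correlations.tsv``.  Output is deterministic:
    keys sorted, floats fixed to 10 decimals, NaN serialized as null.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    results = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.rng_seed,
        "fits": fits,
    }
    paths["results"] = out_dir / "results.json"
    paths["results"].write_text(json.dumps(_clean(results), indent=1,
                                           sort_keys=True) + "\n")

    paths["group_stats"] = out_dir / "group_stats.json"
    paths["group_stats"].write_text(json.dumps(_clean(group_stats), indent=1,
                                               sort_keys=True) + "\n")

    if weights is not None:
        paths["weights"] = out_dir / "weights.tsv"
        weights.to_csv(paths["weights"], sep="\t", index=False,
                       float_format="%.10g")
    if correlations is not None:
        paths["age_correlations"] = out_dir / "age_correlations.tsv"
        correlations.to_csv(paths["age_correlations"], sep="\t", index=False,
                            float_format="%.10g")
    return paths
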