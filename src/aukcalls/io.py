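"""File interfaces: WAV audio, Raven-style selection tables, feature CSV.

Selection tables follow the Raven Pro tab-separated dialect: a header row,
required columns "Begin Time (s)" and "End Time (s)" (begin-inclusive,
end-exclusive, seconds from file start) and the annotation columns
"Individual" and "Context". Extra Raven columns are carried through and
ignored.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .schema import CallRecording, DataError, FEATURE_COLUMNS

logger = logging.getLogger(__name__)

REQUIRED_SELECTION_COLUMNS = ("Begin Time (s)", "End Time (s)")
ANNOTATION_COLUMNS = ("Individual", "Context")


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write mono PCM 16-bit WAV; float input clipped to [-1, 1]."""
    x = np.clip(np.asarray(samples, float), -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (x * 32767).astype(np.int16))


def read_wav(path: str | Path, channel: int = 0) -> Tuple[np.ndarray, int]:
    """Read a WAV file to float samples in [-1, 1]; stereo input is collapsed
    by channel selection."""
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, int(rate)


def read_selection_table(path: str | Path) -> pd.DataFrame:
    """Parse a Raven-style selection table.

    Rows with end <= begin are rejected with a log entry. Raises DataError
    naming any missing required column.
    """
    df = pd.read_csv(path, sep="\t")
    for col in REQUIRED_SELECTION_COLUMNS + ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise DataError(f"selection table {path}: missing column {col!r}")
    bad = df["End Time (s)"] <= df["Begin Time (s)"]
    if bad.any():
        logger.warning("selection table %s: rejecting %d rows with end <= begin",
                       path, int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def write_selection_table(
    path: str | Path, recordings: Sequence[CallRecording], gap_s: float = 0.1
) -> pd.DataFrame:
    """Write a Raven-style selection table laying the calls end to end with a
    fixed silent gap, as if they sat in one continuous recording."""
    rows = []
    t = 0.0
    for i, rec in enumerate(recordings, start=1):
        rows.append({
            "Selection": i, "View": "Spectrogram 1", "Channel": 1,
            "Begin Time (s)": round(t, 6),
            "End Time (s)": round(t + rec.duration_s, 6),
            "Low Freq (Hz)": 0.0, "High Freq (Hz)": rec.sample_rate / 2,
            "Individual": rec.individual_id, "Context": rec.context,
        })
        t += rec.duration_s + gap_s
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def load_annotated_calls(
    wav_path: str | Path, table_path: str | Path, channel: int = 0
) -> List[CallRecording]:
    """Cut annotated calls out of one WAV file using its selection table."""
    samples, rate = read_wav(wav_path, channel=channel)
    table = read_selection_table(table_path)
    calls = []
    for i, row in table.iterrows():
        b = int(round(row["Begin Time (s)"] * rate))
        e = int(round(row["End Time (s)"] * rate))
        seg = samples[b:e]
        if seg.size == 0:
            logger.warning("selection %s: empty segment, skipped", i)
            continue
        calls.append(CallRecording(
            samples=seg, sample_rate=rate,
            call_id=str(row.get("Selection", i + 1)),
            individual_id=str(row["Individual"]),
            context=str(row["Context"]),
        ))
    return calls


def write_feature_csv(path: str | Path, features: pd.DataFrame) -> None:
    """Write the feature table in the stable column order."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise DataError(f"feature table missing columns {missing}")
    features[FEATURE_COLUMNS].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"feature CSV {path}: missing columns {missing}")
    return df
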