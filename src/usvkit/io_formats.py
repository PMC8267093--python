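"""On-disk artifacts: mono WAV audio and the per-call table.

The call table is the pipeline's central exchange format: one row per call with
identity columns, onset/offset in seconds (half-open ``[onset, offset)``), the
12 acoustic feature columns in a fixed order, and an optional integer call
type.  Times are stored in seconds; only the duration *feature* is in
milliseconds, matching the conventional reporting unit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

GROUPS = ("control_female", "control_male", "tp_female", "tp_male")

#: Feature columns in canonical (reporting) order.
FEATURE_COLUMNS = (
    "duration_ms",
    "freq_dynamic_hz",
    "delta_freq_hz",
    "mean_freq_hz",
    "freq_tv_hz",
    "mean_freq_tv_hz",
    "linearity_index",
    "nb_modulation",
    "nb_jumps",
    "min_freq_hz",
    "max_freq_hz",
    "peak_freq_hz",
)

CALL_TABLE_COLUMNS = ("call_id", "animal_id", "group", "onset_s", "offset_s",
                      *FEATURE_COLUMNS, "call_type")


class FormatError(ValueError):
    """Raised for malformed on-disk artifacts."""


@dataclass
class Recording:
    """A mono ultrasonic recording with animal/group metadata."""

    samples: np.ndarray
    sample_rate: float
    animal_id: str = ""
    group: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.group and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class CallRecord:
    """One detected (or synthesized) call."""

    call_id: str
    animal_id: str
    group: str
    onset_s: float
    offset_s: float
    features: dict[str, float] | None = None
    call_type: int | None = None
    is_truth: bool = False

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"call {self.call_id!r}: offset_s ({self.offset_s}) must exceed "
                f"onset_s ({self.onset_s})")
        # empty group means "not yet assigned" (e.g. anonymous detection runs);
        # writing a call table requires a valid group
        if self.group and self.group not in GROUPS:
            raise ValueError(f"call {self.call_id!r}: unknown group {self.group!r}")


def read_wav(path: str | Path, *, band_ceiling_hz: float | None = None,
             animal_id: str = "", group: str = "", session_id: str = "") -> Recording:
    """Read a mono PCM16 or float32 RIFF/WAVE file.

    ``band_ceiling_hz`` enforces the Nyquist requirement of the analysis band:
    the sample rate must be at least twice the ceiling.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises plain ValueError on bad RIFF
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: {data.shape[1]}-channel audio unsupported (mono only)")
    if data.dtype not in (np.int16, np.float32):
        raise FormatError(f"{path}: unsupported sample format {data.dtype} "
                          "(PCM 16-bit or float-32 only)")
    if band_ceiling_hz is not None and rate < 2 * band_ceiling_hz:
        raise FormatError(
            f"{path}: sample rate {rate} Hz is below twice the analysis band "
            f"ceiling ({band_ceiling_hz} Hz requires >= {2 * band_ceiling_hz} Hz)")
    return Recording(samples=data, sample_rate=float(rate), animal_id=animal_id,
                     group=group, session_id=session_id)


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a Recording; int16 is written as PCM16, floats as float32."""
    data = rec.samples
    if data.dtype == np.int16:
        out = data
    else:
        out = np.asarray(data, dtype=np.float32)
    wavfile.write(str(Path(path)), int(round(rec.sample_rate)), out)


def _records_to_frame(calls: list[CallRecord]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "call_id": c.call_id, "animal_id": c.animal_id, "group": c.group,
            "onset_s": c.onset_s, "offset_s": c.offset_s,
        }
        feats = c.features or {}
        for name in FEATURE_COLUMNS:
            row[name] = feats.get(name, math.nan)
        row["call_type"] = c.call_type if c.call_type is not None else pd.NA
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CALL_TABLE_COLUMNS))
    return df.sort_values(["animal_id", "onset_s"], kind="mergesort").reset_index(drop=True)


def write_call_table(calls: list[CallRecord], path: str | Path) -> None:
    """Write calls as CSV sorted by (animal_id, onset_s), '.' decimal, UTF-8."""
    for c in calls:
        if c.group not in GROUPS:
            raise ValueError(f"call {c.call_id!r}: group {c.group!r} must be one "
                             f"of {GROUPS} to be written")
    df = _records_to_frame(calls)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_call_table(path: str | Path) -> list[CallRecord]:
    """Read a call table written by :func:`write_call_table`.

    The ``call_type`` column may be absent (pre-typing tables); feature columns
    that are entirely NaN yield records without features.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"call_id": str, "animal_id": str, "group": str})
    required = {"call_id", "animal_id", "group", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise FormatError(f"{path}: unknown group value(s) "
                          f"{sorted(df.loc[bad_group, 'group'].unique())}")
    bad_time = ~(df["offset_s"] > df["onset_s"])
    if bad_time.any():
        rows = df.index[bad_time].tolist()
        raise FormatError(f"{path}: offset_s <= onset_s at row(s) {rows}")
    seen: set[str] = set()
    records: list[CallRecord] = []
    for _, r in df.iterrows():
        if r["call_id"] in seen:
            raise FormatError(f"{path}: duplicate call_id {r['call_id']!r}")
        seen.add(r["call_id"])
        feats = {name: float(r[name]) for name in FEATURE_COLUMNS
                 if name in df.columns and pd.notna(r[name])}
        ct = None
        if "call_type" in df.columns and pd.notna(r["call_type"]):
            ct = int(r["call_type"])
        records.append(CallRecord(
            call_id=str(r["call_id"]), animal_id=str(r["animal_id"]),
            group=str(r["group"]), onset_s=float(r["onset_s"]),
            offset_s=float(r["offset_s"]), features=feats or None, call_type=ct))
    return records


def call_table_frame(calls: list[CallRecord]) -> pd.DataFrame:
    """Calls as a DataFrame in the canonical column order/sort."""
    return _records_to_frame(calls)
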