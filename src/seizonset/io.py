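"""Readers and writers: columnar CSV signals, annotation/event CSVs, EDF.

CSV signal layout: a ``time_s`` column followed by one column per channel,
headed ``<label>:<role>`` (role ``focal`` or ``remote``).  Annotations are
``onset_s,offset_s`` with 3 decimals; events add ``peak_sz``.

EDF support: a minimal standard 16-bit EDF writer (one 1 s data record per
second, physical dimension uV) and reading through ``mne.io.read_raw_edf``.
Channel roles ride in the EDF labels as ``-EPT`` (epileptogenic/focal) and
``-RMT`` (remote) suffixes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import SeizureEvent
from .recording import FOCAL, REMOTE, Annotation, Recording

_EDF_ROLE_SUFFIX = {FOCAL: "-EPT", REMOTE: "-RMT"}


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def write_recording_csv(recording: Recording, path) -> None:
    t = np.arange(recording.n_samples) / recording.fs
    data = {"time_s": t}
    for i, (label, role) in enumerate(zip(recording.labels, recording.roles)):
        data[f"{label}:{role}"] = recording.samples[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path, patient_id: str | None = None) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("signal CSV must contain a time_s column")
    t = df.pop("time_s").to_numpy()
    if len(t) < 2:
        raise ValueError("signal CSV must contain at least two samples")
    # whole-span estimate averages out the per-row rounding of time_s
    fs = round((len(t) - 1) / float(t[-1] - t[0]), 3)
    labels, roles, rows = [], [], []
    bad = []
    for col in df.columns:
        label, sep, role = col.rpartition(":")
        if not sep or role not in (FOCAL, REMOTE):
            bad.append(col)
            continue
        labels.append(label)
        roles.append(role)
        rows.append(df[col].to_numpy())
    if bad:
        raise ValueError(
            f"channels without a ':focal'/':remote' role suffix: {bad}"
        )
    return Recording(samples=np.asarray(rows), fs=round(fs, 6), labels=labels,
                     roles=roles, patient_id=patient_id or Path(path).stem)


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    pd.DataFrame(
        [(a.onset, a.offset) for a in annotations], columns=["onset_s", "offset_s"]
    ).to_csv(path, index=False, float_format="%.3f")


def read_annotations_csv(path) -> list[Annotation]:
    df = pd.read_csv(path)
    return [Annotation(onset=row.onset_s, offset=row.offset_s) for row in df.itertuples()]


def write_events_csv(events: list[SeizureEvent], path) -> None:
    pd.DataFrame(
        [(e.onset_s, e.offset_s, e.peak_sz) for e in events],
        columns=["onset_s", "offset_s", "peak_sz"],
    ).to_csv(path, index=False, float_format="%.3f")


def read_events_csv(path) -> list[SeizureEvent]:
    df = pd.read_csv(path)
    return [
        SeizureEvent(onset_s=row.onset_s, offset_s=row.offset_s,
                     peak_sz=row.peak_sz, n_segments=0)
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path) -> None:
    """Minimal 16-bit EDF export: 1 s data records, uV physical dimension.

    The record is padded with its last sample value up to a whole number of
    seconds.  Channel roles are encoded as ``-EPT``/``-RMT`` label suffixes.
    """
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr))
    x = recording.samples
    pad = n_rec * spr - recording.n_samples
    if pad:
        x = np.concatenate([x, np.repeat(x[:, -1:], pad, axis=1)], axis=1)
    # physical extremes rounded outward to the 2-decimal precision actually
    # stored in the header, so writer and reader use identical scaling
    pmin = np.floor(x.min(axis=1) * 100) / 100
    pmax = np.ceil(x.max(axis=1) * 100) / 100
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((x - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field(recording.patient_id or "X", 80),
        _edf_field("Startdate X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_ch + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    labels = [
        f"{lbl[:12]}{_EDF_ROLE_SUFFIX[role]}"
        for lbl, role in zip(recording.labels, recording.roles)
    ]
    sig = b"".join(
        b"".join(_edf_field(v, w) for v in values)
        for values, w in (
            (labels, 16),
            (["synthetic iEEG"] * n_ch, 80),
            (["uV"] * n_ch, 8),
            ([f"{v:.2f}" for v in pmin], 8),
            ([f"{v:.2f}" for v in pmax], 8),
            ([dmin] * n_ch, 8),
            ([dmax] * n_ch, 8),
            ([""] * n_ch, 80),
            ([spr] * n_ch, 8),
            ([""] * n_ch, 32),
        )
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_recording_edf(path, patient_id: str | None = None) -> Recording:
    """Read an EDF file via mne; roles parsed from -EPT/-RMT label suffixes."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels, roles = [], []
    bad = []
    for name in raw.ch_names:
        if name.endswith("-EPT"):
            labels.append(name[:-4])
            roles.append(FOCAL)
        elif name.endswith("-RMT"):
            labels.append(name[:-4])
            roles.append(REMOTE)
        else:
            bad.append(name)
    if bad:
        raise ValueError(f"EDF channels without -EPT/-RMT role suffix: {bad}")
    samples = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned EEG
    return Recording(samples=samples, fs=float(raw.info["sfreq"]), labels=labels,
                     roles=roles, patient_id=patient_id or Path(path).stem)


def read_recording(path, fmt: str | None = None, patient_id: str | None = None) -> Recording:
    """Dispatch on format (``csv`` or ``edf``), inferred from the suffix."""
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_recording_csv(path, patient_id=patient_id)
    if fmt == "edf":
        return read_recording_edf(path, patient_id=patient_id)
    raise ValueError(f"unsupported recording format {fmt!r}; expected csv or edf")
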