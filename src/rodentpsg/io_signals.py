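"""Read/write continuous signals, event tables, and hypnograms.

EDF/EDF+ files are read through MNE; writing uses a minimal EDF writer
(16-bit, one-second data records) sufficient for round-tripping synthetic
records. Tabular outputs are comma-separated UTF-8 text with "." decimals.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ChannelRole,
    ConfigurationError,
    EventInterval,
    FormatError,
    Hypnogram,
    InputError,
    ParameterError,
    SignalRecord,
)

__all__ = [
    "read_edf",
    "write_edf",
    "read_delimited",
    "write_delimited",
    "write_events",
    "read_events",
    "write_hypnogram",
    "read_hypnogram",
]

#: default physical range (mV) used when writing synthetic records
DEFAULT_PHYS_RANGE_MV = 10.0

_SI_PER_UNIT = {"V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6}


def _roles_dict(role_map: Iterable[ChannelRole] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(role_map, Mapping):
        pairs = [ChannelRole(n, r) for n, r in role_map.items()]
    else:
        pairs = list(role_map)
    roles = {cr.name: cr.role for cr in pairs}
    have = set(roles.values())
    missing = {"eeg_left", "eeg_right", "emg"} - have
    if missing:
        raise ConfigurationError(f"role map missing roles: {sorted(missing)}")
    return roles


def read_edf(path: str | os.PathLike, role_map) -> SignalRecord:
    """Read an EDF/EDF+ file into a :class:`SignalRecord`.

    Channels with differing native rates come back on a single grid at the
    maximum rate (the reader upsamples the slower channels). Values are
    returned in each channel's original physical unit.
    """
    import mne

    roles = _roles_dict(role_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt header, truncated records, ...
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    missing = [n for n in roles if n not in raw.ch_names]
    if missing:
        raise ConfigurationError(
            f"role map names channels absent from file: {missing}; "
            f"file has {raw.ch_names}"
        )
    data = raw.get_data()  # SI units for recognized channel types
    orig_units = dict(getattr(raw, "_orig_units", {}) or {})
    channels: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for i, name in enumerate(raw.ch_names):
        if name not in roles:
            continue
        unit = orig_units.get(name, "mV")
        scale = 1.0 / _SI_PER_UNIT.get(unit, 1.0)
        channels[name] = np.asarray(data[i], dtype=float) * scale
        units[name] = unit if unit in _SI_PER_UNIT else "mV"
    return SignalRecord(
        channels=channels, rate=float(raw.info["sfreq"]), roles=roles, units=units
    )


def _edf_field(value, width: int) -> bytes:
    text = str(value)
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    record: SignalRecord,
    path: str | os.PathLike,
    phys_range_mv: float = DEFAULT_PHYS_RANGE_MV,
) -> None:
    """Write a record as 16-bit EDF with one-second data records.

    The physical range is symmetric (``±phys_range_mv``); samples beyond it
    clip. A trailing partial second is zero-padded to a whole data record.
    """
    rate = record.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ParameterError(f"EDF writer requires an integer sampling rate, got {rate}")
    spr = int(round(rate))  # samples per 1-s data record
    names = list(record.channels)
    ns = len(names)
    n_rec = int(np.ceil(record.n_samples / spr)) if record.n_samples else 0
    pmin, pmax = -float(phys_range_mv), float(phys_range_mv)
    dmin, dmax = -32768, 32767
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.01", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(ns, 4)
    header += b"".join(_edf_field(n, 16) for n in names)
    header += b"".join(_edf_field("", 80) for _ in names)
    header += b"".join(_edf_field(record.units.get(n, "mV"), 8) for n in names)
    header += b"".join(_edf_field(pmin, 8) for _ in names)
    header += b"".join(_edf_field(pmax, 8) for _ in names)
    header += b"".join(_edf_field(dmin, 8) for _ in names)
    header += b"".join(_edf_field(dmax, 8) for _ in names)
    header += b"".join(_edf_field("", 80) for _ in names)
    header += b"".join(_edf_field(spr, 8) for _ in names)
    header += b"".join(_edf_field("", 32) for _ in names)
    gain = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for name in names:
                seg = record.channels[name][r * spr : (r + 1) * spr]
                if len(seg) < spr:
                    seg = np.pad(seg, (0, spr - len(seg)))
                dig = np.round((seg - pmin) * gain) + dmin
                fh.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())


def edf_quantization_step_mv(phys_range_mv: float = DEFAULT_PHYS_RANGE_MV) -> float:
    """Physical value of one 16-bit digital step for a symmetric range."""
    return 2 * phys_range_mv / 65535


def read_delimited(
    path: str | os.PathLike,
    rate: float,
    role_map,
    units: str = "mV",
) -> SignalRecord:
    """Read a CSV of one column per channel sampled at a constant rate."""
    roles = _roles_dict(role_map)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed delimited file {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"missing values in {path}")
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    return SignalRecord(
        channels=channels,
        rate=float(rate),
        roles=roles,
        units={c: units for c in channels},
    )


def write_delimited(record: SignalRecord, path: str | os.PathLike) -> None:
    """Write channels as CSV, one column per channel, full float precision."""
    df = pd.DataFrame({n: record.channels[n] for n in record.channels})
    df.to_csv(path, index=False)


def _fmt_time(x: float) -> str:
    """Exact decimal repr with at least 3 decimals (round-trips as float)."""
    s = np.format_float_positional(float(x), unique=True, trim="0")
    if "." not in s:
        s += "."
    whole, frac = s.split(".")
    return f"{whole}.{frac.ljust(3, '0')}"


EVENT_COLUMNS = [
    "onset_s",
    "offset_s",
    "duration_s",
    "kind",
    "band_lo_hz",
    "band_hi_hz",
    "peak_freq_hz",
    "laterality",
    "state",
]


def write_events(events: Sequence[EventInterval], path: str | os.PathLike) -> None:
    """Write an event table (CSV, schema fixed, times with >=3 decimals)."""
    onsets = [e.onset_s for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise InputError("events must be sorted by onset before writing")
    rows = [
        {
            "onset_s": _fmt_time(e.onset_s),
            "offset_s": _fmt_time(e.offset_s),
            "duration_s": _fmt_time(e.duration_s),
            "kind": e.kind,
            "band_lo_hz": e.band_lo_hz,
            "band_hi_hz": e.band_hi_hz,
            "peak_freq_hz": _fmt_time(e.peak_freq_hz),
            "laterality": e.laterality,
            "state": e.state,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | os.PathLike) -> list[EventInterval]:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    return [
        EventInterval(
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            kind=str(r.kind),
            band_lo_hz=float(r.band_lo_hz),
            band_hi_hz=float(r.band_hi_hz),
            peak_freq_hz=float(r.peak_freq_hz),
            laterality=str(r.laterality),
            state=str(r.state),
        )
        for r in df.itertuples()
    ]


HYPNOGRAM_COLUMNS = ["epoch_index", "start_s", "end_s", "state", "artifact_flag"]


def write_hypnogram(hyp: Hypnogram, path: str | os.PathLike) -> None:
    rows = [
        {
            "epoch_index": i,
            "start_s": _fmt_time(i * hyp.epoch_len_s),
            "end_s": _fmt_time((i + 1) * hyp.epoch_len_s),
            "state": lab,
            "artifact_flag": int(lab == "artifact"),
        }
        for i, lab in enumerate(hyp.labels)
    ]
    pd.DataFrame(rows, columns=HYPNOGRAM_COLUMNS).to_csv(path, index=False)


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read an epoch table back; sub-labels are expanded from epoch labels."""
    df = pd.read_csv(path)
    missing = [c for c in HYPNOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"hypnogram table missing columns {missing}")
    labels = [str(s) for s in df["state"]]
    epoch_len = float(df["end_s"].iloc[0] - df["start_s"].iloc[0]) if len(df) else 10.0
    sub = np.repeat(np.asarray(labels, dtype="U8"), int(round(epoch_len)))
    return Hypnogram(labels=labels, sub_labels=sub, epoch_len_s=epoch_len)
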