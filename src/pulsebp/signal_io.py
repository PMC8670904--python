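"""Reading and writing synchronized multichannel physiological records.

A :class:`Record` bundles the three channels used throughout the package —
ECG, PPG (finger volume pulse) and invasive ABP — sampled uniformly at a
single rate.  Two on-disk representations are supported:

* a diff-friendly delimited-text format: one ``# fs=<Hz>`` header line,
  a comma-separated column-name line, then one row per sample;
* a minimal single-segment WFDB-style pair (``.hea`` header plus 16-bit
  little-endian ``.dat``), restricted to one sampling rate shared by all
  channels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Record", "RecordFormatError", "read_record", "write_record"]

#: default physical units per channel; ecg/ppg are in arbitrary (a.u.) units
DEFAULT_UNITS = {"ecg": "au", "ppg": "au", "abp": "mmHg"}


class RecordFormatError(ValueError):
    """Raised when a record file or Record object violates the format contract."""


@dataclass
class Record:
    """Synchronized multichannel time series.

    Parameters
    ----------
    channels
        Mapping from lower-case channel name to 1-D float array.  All
        channels must have identical length.
    sampling_rate
        Sampling frequency in Hz, shared by every channel.
    units
        Physical units per channel (``abp`` is mmHg, ``ecg``/``ppg`` are
        arbitrary units by convention).
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise RecordFormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.channels:
            raise RecordFormatError("Record must contain at least one channel")
        normalized = {}
        length = None
        for name, data in self.channels.items():
            arr = np.asarray(data, dtype=float)
            if arr.ndim != 1:
                raise RecordFormatError(f"channel {name!r} is not 1-D")
            if arr.size == 0:
                raise RecordFormatError(f"channel {name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise RecordFormatError(f"channel {name!r} contains non-finite values")
            if length is None:
                length = arr.size
            elif arr.size != length:
                raise RecordFormatError(
                    f"ragged channel lengths: {name!r} has {arr.size} samples, "
                    f"expected {length}"
                )
            normalized[name.lower()] = arr
        self.channels = normalized
        self.units = {k.lower(): v for k, v in self.units.items()}
        for name in self.channels:
            self.units.setdefault(name, DEFAULT_UNITS.get(name, "au"))

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name.lower()]


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def _write_csv(record: Record, path: str) -> None:
    names = list(record.channels)
    data = np.column_stack([record.channels[n] for n in names])
    with open(path, "w") as fh:
        fh.write(f"# fs={record.sampling_rate!r}\n")
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, data, fmt="%.10g", delimiter=",")


def _read_csv(path: str) -> Record:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "fs=" not in header:
            raise RecordFormatError(f"{path}: missing '# fs=<Hz>' header line")
        try:
            fs = float(header.split("fs=", 1)[1].split()[0])
        except (ValueError, IndexError) as exc:
            raise RecordFormatError(f"{path}: unparseable sampling rate") from exc
        names = [c.strip().lower() for c in fh.readline().strip().split(",")]
        if not names or names == [""]:
            raise RecordFormatError(f"{path}: missing channel-name line")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise RecordFormatError(f"{path}: non-numeric content ({exc})") from exc
    if data.shape[1] != len(names):
        raise RecordFormatError(
            f"{path}: {len(names)} channel names but {data.shape[1]} columns"
        )
    return Record({n: data[:, i] for i, n in enumerate(names)}, sampling_rate=fs)


# ---------------------------------------------------------------------------
# WFDB-style header + 16-bit signal pair
# ---------------------------------------------------------------------------

def _wfdb_paths(path: str) -> tuple[str, str, str]:
    base = path[:-4] if path.endswith((".hea", ".dat")) else path
    return base, base + ".hea", base + ".dat"


def _write_wfdb(record: Record, path: str) -> None:
    base, hea, dat = _wfdb_paths(path)
    name = os.path.basename(base)
    names = list(record.channels)
    gains, ints = [], []
    for n in names:
        x = record.channels[n]
        # per-channel gain so the int16 range is used without clipping
        gain = 32000.0 / max(np.max(np.abs(x)), 1e-12)
        gains.append(gain)
        ints.append(np.round(x * gain).astype(np.int16))
    sig = np.column_stack(ints)  # interleaved, sample-major
    with open(hea, "w") as fh:
        fh.write(f"{name} {len(names)} {float(record.sampling_rate):.10g} {record.n_samples}\n")
        for n, gain, col in zip(names, gains, sig.T):
            first = int(col[0])
            checksum = int(np.sum(col, dtype=np.int64) % 65536)
            unit = record.units.get(n, "au")
            fh.write(f"{name}.dat 16 {float(gain):.10g}(0)/{unit} 16 0 {first} {checksum} 0 {n}\n")
    sig.astype("<i2").tofile(dat)


def _read_wfdb(path: str) -> Record:
    base, hea, dat = _wfdb_paths(path)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise RecordFormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"{hea}: header line needs name, n_sig, fs, n_samples")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if len(lines) - 1 < n_sig:
        raise RecordFormatError(f"{hea}: expected {n_sig} signal lines")
    names, gains, units = [], [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if tok[1] != "16":
            raise RecordFormatError(f"{hea}: only format 16 is supported, got {tok[1]}")
        gain_spec = tok[2]
        unit = "au"
        if "/" in gain_spec:
            gain_spec, unit = gain_spec.split("/", 1)
        gain = float(gain_spec.split("(")[0])
        names.append(tok[-1].lower())
        gains.append(gain)
        units.append(unit)
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_samples * n_sig:
        raise RecordFormatError(
            f"{dat}: expected {n_samples * n_sig} samples, found {raw.size}"
        )
    sig = raw.reshape(n_samples, n_sig)
    channels = {n: sig[:, i] / gains[i] for i, n in enumerate(names)}
    return Record(channels, sampling_rate=fs, units=dict(zip(names, units)))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_record(path: str, format: str = "csv") -> Record:
    """Read a multichannel record.

    Parameters
    ----------
    path
        File path; for ``wfdb`` the ``.hea``/``.dat`` suffix is optional.
    format
        ``"csv"`` (delimited text) or ``"wfdb"``.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'wfdb')")


def write_record(record: Record, path: str, format: str = "csv") -> None:
    """Write a record so that :func:`read_record` round-trips it.

    Round-trip precision is the text precision for ``csv`` and the
    per-channel 16-bit quantization step for ``wfdb``.
    """
    if not isinstance(record, Record):
        record = Record(**record) if isinstance(record, dict) else Record(
            record.channels, record.sampling_rate, getattr(record, "units", {})
        )
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'wfdb')")
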