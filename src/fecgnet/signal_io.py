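"""Canonical ECG record container and file I/O.

Every module in the package consumes :class:`Record`: a multichannel sampled
signal with a single sampling rate, per-channel roles (abdominal mixture,
fetal/maternal ground truth, fetal scalp reference), and R-peak annotations
for the fetal and maternal components.

Two on-disk layouts are supported:

* a minimal WFDB-compatible pair (text ``.hea`` header + 16-bit little-endian
  ``.dat`` signal, format 16, single segment) so PhysioNet-style records can
  be read and written, plus a plain-text annotation sidecar for R peaks;
* a CSV layout (one header row of channel labels, one column per channel)
  with the same annotation sidecar, convenient for synthetic fixtures.

Sample indexing is 0-based; time windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Record", "read_wfdb_record", "read_record", "write_record", "slice_record"]

ROLES = ("abdominal_mixture", "fetal_truth", "maternal_truth",
         "fetal_scalp_reference", "noise")


@dataclass
class Record:
    """A multichannel sampled ECG signal with ground truth and annotations.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in millivolts or
        normalized units.
    fs
        Sampling rate in Hz, strictly positive.
    channel_roles
        One role label per channel (e.g. ``"abdominal_mixture"``).
    rpeaks_fetal, rpeaks_maternal
        Strictly increasing R-peak sample indices in ``[0, n_samples)``.
    meta
        Free-form provenance (scenario, noise level, seed, ...).
    """

    signals: np.ndarray
    fs: float
    channel_roles: list[str]
    rpeaks_fetal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    rpeaks_maternal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.rpeaks_fetal = np.asarray(self.rpeaks_fetal, dtype=int)
        self.rpeaks_maternal = np.asarray(self.rpeaks_maternal, dtype=int)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_roles) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.signals.shape[0]} channels"
            )
        n = self.signals.shape[1]
        for name in ("rpeaks_fetal", "rpeaks_maternal"):
            idx = getattr(self, name)
            if idx.size:
                if np.any(np.diff(idx) <= 0):
                    raise ValueError(f"{name} must be strictly increasing")
                if idx[0] < 0 or idx[-1] >= n:
                    raise ValueError(f"{name} indices out of [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        """Return the first channel with the given role."""
        try:
            i = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"record has no channel with role {role!r}") from None
        return self.signals[i]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles


# ---------------------------------------------------------------------------
# annotation sidecar (plain text, shared by both formats)

def _with_ext(stem: Path, ext: str) -> Path:
    """Append an extension to a record stem (dots in names left intact)."""
    return stem.parent / (stem.name + ext)


def _write_annotations(record: Record, stem: Path) -> None:
    ann = {
        "rpeaks_fetal": record.rpeaks_fetal.tolist(),
        "rpeaks_maternal": record.rpeaks_maternal.tolist(),
        "meta": record.meta,
    }
    _with_ext(stem, ".ann.json").write_text(json.dumps(ann))


def _read_annotations(stem: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = _with_ext(stem, ".ann.json")
    if not path.exists():
        return np.empty(0, dtype=int), np.empty(0, dtype=int), {}
    ann = json.loads(path.read_text())
    return (
        np.asarray(ann.get("rpeaks_fetal", []), dtype=int),
        np.asarray(ann.get("rpeaks_maternal", []), dtype=int),
        ann.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# WFDB (minimal: format 16, single .dat, text header)

_WFDB_FMT = 16
_ADC_GAIN = 1000.0  # ADC units per mV -> 1 uV resolution over +-32 mV


def _write_wfdb(record: Record, stem: Path) -> None:
    n_ch, n = record.n_channels, record.n_samples
    dat_name = stem.name + ".dat"
    scaled = np.clip(np.round(record.signals * _ADC_GAIN), -32768, 32767)
    interleaved = scaled.T.astype("<i2")  # sample-major, channel-interleaved
    (stem.parent / dat_name).write_bytes(interleaved.tobytes())
    lines = [f"{stem.name} {n_ch} {record.fs:g} {n}"]
    for i, role in enumerate(record.channel_roles):
        lines.append(
            f"{dat_name} {_WFDB_FMT} {_ADC_GAIN:g}(0)/mV 16 0 0 0 0 {role}"
        )
    _with_ext(stem, ".hea").write_text("\n".join(lines) + "\n")


def _read_wfdb(stem: Path) -> Record:
    hea = _with_ext(stem, ".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    try:
        n_ch, fs, n = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"corrupt WFDB header {hea}: {lines[0]!r}") from exc
    roles, gains, dat_names = [], [], []
    for spec in lines[1 : 1 + n_ch]:
        parts = spec.split()
        if int(parts[1]) != _WFDB_FMT:
            raise ValueError(f"unsupported WFDB format {parts[1]} (only 16)")
        dat_names.append(parts[0])
        gain_field = parts[2].split("/")[0].split("(")[0]
        gains.append(float(gain_field) if float(gain_field) != 0 else 200.0)
        roles.append(parts[-1] if parts[-1] in ROLES else "abdominal_mixture")
    if len(set(dat_names)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    dat = stem.parent / dat_names[0]
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size != n_ch * n:
        raise ValueError(
            f"signal file {dat} holds {raw.size} samples, header declares {n_ch * n}"
        )
    signals = raw.reshape(n, n_ch).T.astype(float) / np.asarray(gains)[:, None]
    rf, rm, meta = _read_annotations(stem)
    return Record(signals, fs, roles, rf, rm, meta)


# ---------------------------------------------------------------------------
# CSV

def _write_csv(record: Record, stem: Path) -> None:
    path = _with_ext(stem, ".csv")
    header = ",".join(record.channel_roles)
    np.savetxt(path, record.signals.T, delimiter=",", header=header, comments="",
               fmt="%.9g")
    meta = dict(record.meta)
    meta["fs"] = record.fs
    rec = replace(record, meta=meta)
    _write_annotations(rec, stem)


def _read_csv(stem: Path) -> Record:
    path = _with_ext(stem, ".csv")
    if not path.exists():
        raise FileNotFoundError(f"missing CSV file {path}")
    with open(path) as fh:
        roles = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    rf, rm, meta = _read_annotations(stem)
    fs = meta.pop("fs", None)
    if fs is None:
        raise ValueError(f"no sampling rate recorded for {path}")
    return Record(data.T, fs, roles, rf, rm, meta)


# ---------------------------------------------------------------------------
# public API

def read_wfdb_record(path, annotation_suffix: str | None = None) -> Record:
    """Read a WFDB header/signal pair (and annotation sidecar if present).

    ``path`` may point at the ``.hea`` file or the record stem.
    ``annotation_suffix`` selects an alternative ``<stem>.<suffix>.ann.json``
    sidecar holding the R-peak annotations.
    """
    stem = Path(path)
    if stem.suffix == ".hea":
        stem = stem.with_suffix("")
    rec = _read_wfdb(stem)
    if annotation_suffix:
        rf, rm, meta = _read_annotations(
            stem.parent / f"{stem.name}.{annotation_suffix}")
        rec = replace(rec, rpeaks_fetal=rf, rpeaks_maternal=rm,
                      meta={**rec.meta, **meta})
    return rec


def read_record(path) -> Record:
    """Read a record in either supported format, dispatched on extension."""
    p = Path(path)
    if p.suffix == ".csv" or p.with_suffix(".csv").exists() and p.suffix == "":
        return _read_csv(p.with_suffix(""))
    return read_wfdb_record(p)


def write_record(record: Record, path, format: str = "csv") -> Path:
    """Write a record to ``path`` (extension ignored) in ``wfdb`` or ``csv``.

    Returns the primary file written. Annotations are persisted alongside in
    a ``.ann.json`` sidecar.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".hea", ".dat"):
        stem = stem.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    if format == "wfdb":
        _write_wfdb(record, stem)
        _write_annotations(record, stem)
        return _with_ext(stem, ".hea")
    if format == "csv":
        _write_csv(record, stem)
        return _with_ext(stem, ".csv")
    raise ValueError(f"unknown format {format!r}: use 'wfdb' or 'csv'")


def slice_record(record: Record, start_s: float, end_s: float) -> Record:
    """Return the sub-record covering ``[start_s, end_s)`` seconds.

    Annotation indices are re-based to the slice origin; annotations outside
    the window are dropped.
    """
    if not (0 <= start_s < end_s <= record.duration_s + 1e-12):
        raise ValueError(
            f"invalid slice [{start_s}, {end_s}) for a "
            f"{record.duration_s:.3f}-s record"
        )
    i0 = int(round(start_s * record.fs))
    i1 = int(round(end_s * record.fs))
    i1 = min(i1, record.n_samples)

    def rebase(idx: np.ndarray) -> np.ndarray:
        kept = idx[(idx >= i0) & (idx < i1)]
        return kept - i0

    return replace(
        record,
        signals=record.signals[:, i0:i1].copy(),
        rpeaks_fetal=rebase(record.rpeaks_fetal),
        rpeaks_maternal=rebase(record.rpeaks_maternal),
        meta=dict(record.meta),
    )
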