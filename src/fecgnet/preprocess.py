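"""Signal conditioning chain and its exact inverse.

The chain applied before the network sees a signal:

1. zero-phase 3–100 Hz Butterworth band-pass (removes baseline drift and
   high-frequency noise; powerline at 50 Hz is inside the band and left to
   the network);
2. polyphase resampling to 250 Hz;
3. segmentation into 1024-sample windows overlapping by 24 samples at each
   end (hop 1024 − 2·24 = 976), the last window anchored at the signal tail;
4. per-segment Z-score normalization, with the (mean, sd) pair retained.

The inverse — :func:`stitch` — denormalizes each transformed window and
reassembles by overlap-discard: each window owns its central 976 samples,
the first and last additionally own their leading/trailing 24-sample edges.
This makes ``stitch(segment(x))`` lossless for any length ≥ 1024.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, resample_poly

from .signal_io import Record

__all__ = ["SegmentSet", "bandpass_3_100", "resample_to_250", "segment",
           "zscore", "stitch", "SEGMENT_LEN", "EDGE_OVERLAP", "HOP"]

SEGMENT_LEN = 1024
EDGE_OVERLAP = 24
HOP = SEGMENT_LEN - 2 * EDGE_OVERLAP  # 976
TARGET_FS = 250.0
_SD_EPS = 1e-8


@dataclass
class SegmentSet:
    """Fixed-length windows of one channel plus stitching metadata.

    ``segments`` has shape ``(n_segments, 1024)``; ``offsets[i]`` is the
    start index of window ``i`` in the source signal; ``norm_state`` holds
    the per-segment ``(mean, sd)`` used by :func:`zscore` (``None`` before
    normalization).
    """

    segments: np.ndarray
    offsets: np.ndarray
    fs: float
    source_length: int
    norm_state: np.ndarray | None = None  # (n_segments, 2): mean, sd

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def bandpass_3_100(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 3–100 Hz.

    Requires ``fs > 200`` so the 100 Hz corner is representable; filter
    before downsampling.
    """
    if fs <= 200:
        raise ValueError(
            f"fs={fs} too low for the 3-100 Hz band; filter before downsampling"
        )
    signal = np.asarray(signal, dtype=float)
    # forward-backward filtering squares the magnitude response, so the
    # design corner is pre-warped (117 Hz) to keep 5-90 Hz within +-1 dB
    # while the effective -3 dB point stays near 100 Hz
    high = min(117.0, 0.99 * fs / 2) / (fs / 2)
    b, a = butter(4, [3.0 / (fs / 2), high], btype="band")
    return filtfilt(b, a, signal)


def resample_to_250(record: Record) -> Record:
    """Polyphase-resample all channels to 250 Hz, rescaling annotations."""
    if record.fs == TARGET_FS:
        return record
    from fractions import Fraction

    frac = Fraction(250, int(round(record.fs))).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    signals = np.stack([resample_poly(ch, up, down) for ch in record.signals])
    n_new = signals.shape[1]

    def scale(idx: np.ndarray) -> np.ndarray:
        out = np.round(idx * TARGET_FS / record.fs).astype(int)
        out = np.clip(out, 0, n_new - 1)
        return np.unique(out)

    return replace(
        record, signals=signals, fs=TARGET_FS,
        rpeaks_fetal=scale(record.rpeaks_fetal),
        rpeaks_maternal=scale(record.rpeaks_maternal),
    )


def segment(signal: np.ndarray, fs: float = TARGET_FS) -> SegmentSet:
    """Window one channel into 1024-sample segments with hop 976.

    The final window is anchored at ``len(signal) - 1024`` so the tail is
    always covered (possibly with a larger overlap into the previous window).
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n < SEGMENT_LEN:
        raise ValueError(
            f"signal of length {n} is shorter than one {SEGMENT_LEN}-sample "
            "window; zero-pad the record first"
        )
    offsets = list(range(0, n - SEGMENT_LEN + 1, HOP))
    if offsets[-1] + SEGMENT_LEN < n:
        # anchor the final window at the tail (larger overlap with its
        # predecessor); replace the last hop-aligned window when the
        # predecessor still covers the vacated range, else append
        tail = n - SEGMENT_LEN
        if len(offsets) > 1 and tail <= offsets[-2] + SEGMENT_LEN:
            offsets[-1] = tail
        else:
            offsets.append(tail)
    offsets = np.asarray(offsets, dtype=int)
    segs = np.stack([signal[o:o + SEGMENT_LEN] for o in offsets])
    return SegmentSet(segs, offsets, fs, n)


def zscore(sset: SegmentSet) -> SegmentSet:
    """Standardize each segment independently to mean 0, sd 1.

    The sd is floored at a small epsilon so flat segments map to zeros; the
    (mean, sd) actually used is stored for the inverse transform.
    """
    mean = sset.segments.mean(axis=1)
    sd = np.maximum(sset.segments.std(axis=1), _SD_EPS)
    segs = (sset.segments - mean[:, None]) / sd[:, None]
    return replace(sset, segments=segs,
                   norm_state=np.stack([mean, sd], axis=1))


def stitch(sset: SegmentSet, transformed_segments: np.ndarray,
           restore_mean: bool = True) -> np.ndarray:
    """Denormalize transformed windows and reassemble the full channel.

    ``transformed_segments`` must be congruent with ``sset`` (same count and
    window length).  Each window is mapped back through its stored
    ``(mean, sd)`` — the mean is re-added only when ``restore_mean`` is true,
    which is right for signals normalized with their own statistics; for a
    component extracted *from* a normalized mixture only the scale applies.
    Overlapping sample ranges are owned by the later window's central
    region (overlap-discard, no crossfading).
    """
    segs = np.asarray(transformed_segments, dtype=float)
    if segs.shape != sset.segments.shape:
        raise ValueError(
            f"transformed segments shape {segs.shape} does not match "
            f"segment set shape {sset.segments.shape}"
        )
    if sset.norm_state is not None:
        mean, sd = sset.norm_state[:, 0], sset.norm_state[:, 1]
        segs = segs * sd[:, None]
        if restore_mean:
            segs = segs + mean[:, None]
    out = np.zeros(sset.source_length)
    offs = sset.offsets
    n_seg = sset.n_segments
    # ownership boundaries: window i owns [bounds[i], bounds[i+1]); the
    # boundary prefers the later window's trusted (central) start but never
    # leaves a gap when the tail window overlaps its predecessor unevenly
    bounds = [0]
    for i in range(1, n_seg):
        b = min(offs[i] + EDGE_OVERLAP, offs[i - 1] + SEGMENT_LEN - EDGE_OVERLAP)
        b = max(b, offs[i], bounds[-1])
        bounds.append(int(b))
    bounds.append(sset.source_length)
    for i, off in enumerate(offs):
        lo, hi = bounds[i], bounds[i + 1]
        out[lo:hi] = segs[i, lo - off:hi - off]
    return out
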