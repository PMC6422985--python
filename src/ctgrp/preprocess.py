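"""Rule-based FHR denoising and fixed-length segment selection.

The cleaning pipeline has three stages, applied in order:

1. **Gap handling** — runs of exactly-zero samples (signal loss) longer
   than 15 s are spliced out; shorter runs are bridged by linear
   interpolation between the flanking valid samples.
2. **Stabilization** — wherever two adjacent samples differ by more than
   25 bpm the stretch up to the next *stable part* (by default at least 8
   consecutive samples, i.e. 2 s at 4 Hz, with all adjacent differences
   within 25 bpm) is replaced by linear interpolation between the last
   stable sample and the first sample of the next stable part.
3. **Extreme removal** — samples outside the physiological 50-200 bpm
   window are refilled with monotone piecewise-cubic Hermite (PCHIP)
   interpolation through the surrounding in-range samples.

Runs of invalid samples touching either end of the record have no anchor
to interpolate from and are trimmed instead. Classification uses the
final minutes of the cleaned trace (closest to delivery, when the pH
outcome is measured); :func:`select_segment` extracts that window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.interpolate import PchipInterpolator

from .records import FHRRecord

__all__ = [
    "PreprocessConfig",
    "SegmentSpan",
    "find_missing_segments",
    "remove_long_gaps",
    "stabilize",
    "remove_extremes",
    "preprocess",
    "select_segment",
]


@dataclass
class PreprocessConfig:
    long_gap_s: float = 15.0
    jump_bpm: float = 25.0
    min_bpm: float = 50.0
    max_bpm: float = 200.0
    segment_length_min: float = 13.0
    stable_run_samples: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.min_bpm < self.max_bpm):
            raise ValueError("need 0 < min_bpm < max_bpm")
        if self.long_gap_s <= 0:
            raise ValueError("long_gap_s must be positive")
        if self.jump_bpm <= 0:
            raise ValueError("jump_bpm must be positive")
        if self.stable_run_samples < 2:
            raise ValueError("stable_run_samples must be >= 2")


@dataclass(frozen=True)
class SegmentSpan:
    """Half-open sample interval [start, end)."""
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _runs(mask: np.ndarray) -> List[SegmentSpan]:
    """Maximal runs of True in a boolean mask, ordered."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [SegmentSpan(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def find_missing_segments(record: FHRRecord) -> List[SegmentSpan]:
    """Maximal runs of exactly-zero samples, ordered and non-overlapping."""
    return _runs(record.samples == 0.0)


def remove_long_gaps(record: FHRRecord, config: PreprocessConfig = PreprocessConfig()) -> FHRRecord:
    """Splice out zero-runs longer than ``long_gap_s``; interpolate shorter ones.

    "Longer than" is strict: a run of exactly ``long_gap_s`` seconds is
    interpolated, not removed. Zero-runs touching the record boundary are
    trimmed (no flanking anchor exists).
    """
    x = record.samples.copy()
    nonzero = np.flatnonzero(x != 0.0)
    if nonzero.size == 0:
        raise ValueError(f"no valid signal in record {record.record_id}")
    x = x[nonzero[0]:nonzero[-1] + 1]

    limit = config.long_gap_s * record.fs  # samples; strict comparison below
    keep = np.ones(x.size, dtype=bool)
    for span in _runs(x == 0.0):
        if len(span) > limit:
            keep[span.start:span.end] = False
        else:
            left, right = x[span.start - 1], x[span.end]
            x[span.start:span.end] = np.linspace(left, right, len(span) + 2)[1:-1]
    return record.with_samples(x[keep])


def stabilize(record: FHRRecord, config: PreprocessConfig = PreprocessConfig()) -> FHRRecord:
    """Repair unstable stretches (adjacent jumps above ``jump_bpm``).

    A stable part is a run of at least ``stable_run_samples`` consecutive
    samples whose adjacent differences are all within ``jump_bpm``.
    Samples between two stable parts are replaced by linear interpolation
    from the last sample of one to the first sample of the next; unstable
    margins before the first / after the last stable part are trimmed.
    """
    x = record.samples.copy()
    if x.size < config.stable_run_samples:
        raise ValueError(f"unstable record {record.record_id}: "
                         f"shorter than one stable run")
    ok = np.abs(np.diff(x)) <= config.jump_bpm
    # sample i belongs to a stable adjacency chain; runs of True in `ok`
    # of length >= stable_run_samples-1 adjacencies give stable parts
    stable_parts = [SegmentSpan(s.start, s.end + 1) for s in _runs(ok)
                    if (s.end + 1 - s.start) >= config.stable_run_samples]
    if not stable_parts:
        raise ValueError(f"unstable record {record.record_id}: no stable part found")
    for prev, nxt in zip(stable_parts[:-1], stable_parts[1:]):
        a, b = prev.end - 1, nxt.start
        x[a:b + 1] = np.linspace(x[a], x[b], b - a + 1)
    lo, hi = stable_parts[0].start, stable_parts[-1].end
    return record.with_samples(x[lo:hi])


def remove_extremes(record: FHRRecord, config: PreprocessConfig = PreprocessConfig()) -> FHRRecord:
    """Replace samples outside [min_bpm, max_bpm] by PCHIP interpolation.

    Monotone Hermite interpolation through the surrounding in-range
    samples cannot overshoot its anchors, so every output sample stays in
    range. Out-of-range runs at the record boundary are trimmed.
    """
    x = record.samples.copy()
    in_range = (x >= config.min_bpm) & (x <= config.max_bpm)
    if in_range.all():
        return record.with_samples(x)
    good = np.flatnonzero(in_range)
    if good.size < 4:
        raise ValueError(f"record {record.record_id}: fewer than 4 in-range "
                         f"samples, cannot interpolate extremes")
    x = x[good[0]:good[-1] + 1]
    in_range = in_range[good[0]:good[-1] + 1]
    idx = np.flatnonzero(in_range)
    bad = np.flatnonzero(~in_range)
    if bad.size:
        x[bad] = PchipInterpolator(idx, x[idx])(bad)
        x = np.clip(x, config.min_bpm, config.max_bpm)
    return record.with_samples(x)


def preprocess(record: FHRRecord, config: PreprocessConfig = PreprocessConfig()) -> FHRRecord:
    """Full cleaning chain: gaps -> stabilization -> extremes.

    The output contains no zeros and every sample lies in
    [min_bpm, max_bpm]; artifact-free records pass through unchanged.
    """
    rec = remove_long_gaps(record, config)
    rec = stabilize(rec, config)
    return remove_extremes(rec, config)


def select_segment(record: FHRRecord, segment_length_min: float = 13.0) -> FHRRecord:
    """Return the final ``segment_length_min`` minutes of the record.

    The window closest to delivery is kept because the pH outcome is
    measured at delivery.
    """
    n_req = int(round(segment_length_min * 60.0 * record.fs))
    if len(record) < n_req:
        raise ValueError(
            f"record {record.record_id} has {len(record)} samples "
            f"({len(record) / record.fs / 60:.2f} min), shorter than the "
            f"requested {segment_length_min} min ({n_req} samples)")
    return record.with_samples(record.samples[-n_req:])
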