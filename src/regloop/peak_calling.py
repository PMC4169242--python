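"""Threshold-and-merge peak calling on smoothed tiling-array signal.

A probe qualifies when its (smoothed, mock-subtracted) value reaches the y0
threshold; qualifying probes on one chromosome are clustered while the
center-to-center distance between successive qualifying probes stays below
the distance cut-off; clusters supported by at least ``min_probes`` probes
are reported as peaks spanning ``[first probe center, last probe center + 1)``
with the cluster's maximum probe value as score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip_signal import SignalTrack
from .genomics_core import GenomicInterval, PeakSet, ValidationError

__all__ = ["PeakCallParams", "call_peaks", "peak_summary"]


@dataclass(frozen=True)
class PeakCallParams:
    """Parameters of the threshold-and-merge caller.

    threshold_y0 is an absolute cutoff on the smoothed log2 ratio by default
    (0.97, with a 600 bp distance cut-off); ``threshold_mode='quantile'``
    instead interprets it as a genome-wide signal quantile in (0, 1).
    """

    threshold_y0: float = 0.97
    max_gap: int = 600
    min_probes: int = 3
    threshold_mode: str = "absolute"

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValidationError("max_gap must be > 0")
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "quantile" and not (0.0 < self.threshold_y0 < 1.0):
            raise ValidationError("quantile threshold must lie in (0,1)")


def _resolve_threshold(track: SignalTrack, params: PeakCallParams) -> float:
    if params.threshold_mode == "absolute":
        return params.threshold_y0
    flat = track.concat()
    if len(flat) == 0:
        return np.inf
    return float(np.quantile(flat, params.threshold_y0))


def call_peaks(track: SignalTrack, params: PeakCallParams | None = None) -> PeakSet:
    """Call enriched regions from a processed signal track.

    Successive qualifying probes are clustered while their center-to-center
    distance is strictly less than ``max_gap`` (a gap of exactly ``max_gap``
    breaks the run); a non-qualifying probe only breaks a run when it pushes
    the distance between flanking qualifying probes to the cut-off or beyond.
    """
    if params is None:
        params = PeakCallParams()
    thr = _resolve_threshold(track, params)
    intervals: list[GenomicInterval] = []
    counts: list[int] = []
    for chrom in track.probe_map.chroms:
        pos = track.probe_map.positions[chrom]
        vals = track.values[chrom]
        qual = np.flatnonzero(vals >= thr)
        if len(qual) == 0:
            continue
        qpos = pos[qual]
        qval = vals[qual]
        breaks = np.flatnonzero(np.diff(qpos) >= params.max_gap)
        starts_idx = np.concatenate([[0], breaks + 1])
        ends_idx = np.concatenate([breaks, [len(qual) - 1]])
        for a, b in zip(starts_idx, ends_idx):
            n = b - a + 1
            if n < params.min_probes:
                continue
            intervals.append(
                GenomicInterval(
                    chrom,
                    int(qpos[a]),
                    int(qpos[b]) + 1,
                    score=float(qval[a : b + 1].max()),
                )
            )
            counts.append(int(n))
    return PeakSet(intervals, source_label=track.label or "peaks", probe_counts=counts)


def peak_summary(peaks: PeakSet) -> pd.Series:
    """Deterministic summary of a peak set: count, length stats, probe support."""
    lengths = np.array([iv.length for iv in peaks], dtype=float)
    summary = {
        "n_peaks": len(peaks),
        "total_bp": peaks.total_bp,
        "length_mean": float(lengths.mean()) if len(lengths) else float("nan"),
        "length_median": float(np.median(lengths)) if len(lengths) else float("nan"),
        "length_min": float(lengths.min()) if len(lengths) else float("nan"),
        "length_max": float(lengths.max()) if len(lengths) else float("nan"),
    }
    if peaks.probe_counts is not None and len(peaks.probe_counts):
        summary["mean_probe_count"] = float(np.mean(peaks.probe_counts))
    else:
        summary["mean_probe_count"] = float("nan")
    return pd.Series(summary)
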