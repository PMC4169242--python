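"""Probe-level ChIP-chip signal processing.

The tiling-array signal is a per-probe log2 IP/input ratio.  The processing
chain is: quantile normalization between replicate arrays, replicate pooling
by the per-probe median, running-median smoothing along each chromosome
(window of three probes by default, five for the FLAG-AOP arrays), and
direct subtraction of the pooled mock-control track.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomics_core import GenomeLayout, ValidationError

__all__ = [
    "ProbeMap",
    "SignalTrack",
    "quantile_normalize",
    "median_center",
    "pool_replicates",
    "smooth_running_median",
    "subtract_mock",
    "read_bedgraph",
    "write_bedgraph",
]


class ProbeMap:
    """Ordered probe center coordinates, per chromosome.

    Positions must be strictly increasing within each chromosome.
    """

    def __init__(self, positions: Mapping[str, np.ndarray]):
        self.positions: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValidationError(f"{chrom}: positions must be 1-D")
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{chrom}: probe centers not strictly increasing")
            self.positions[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        if list(self.positions) != list(other.positions):
            return False
        return all(np.array_equal(self.positions[c], other.positions[c]) for c in self.positions)

    def same_as(self, other: "ProbeMap") -> bool:
        return self is other or self == other


@dataclass
class SignalTrack:
    """One value per probe of a :class:`ProbeMap` (log2 IP/input ratio)."""

    probe_map: ProbeMap
    values: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self):
        if list(self.values) != list(self.probe_map.positions):
            raise ValidationError("track chromosomes do not match the probe map")
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.probe_map.positions[chrom].shape:
                raise ValidationError(f"{chrom}: one value per probe required")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{chrom}: non-finite signal values")
            self.values[chrom] = v

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.probe_map.chroms])

    def with_values(self, flat: np.ndarray, label: str | None = None) -> "SignalTrack":
        """Rebuild a track from a flat vector in probe-map order."""
        out: dict[str, np.ndarray] = {}
        i = 0
        for chrom in self.probe_map.chroms:
            n = len(self.probe_map.positions[chrom])
            out[chrom] = np.asarray(flat[i : i + n], dtype=float).copy()
            i += n
        return SignalTrack(self.probe_map, out, label if label is not None else self.label)


def _require_shared_map(tracks: Sequence[SignalTrack]) -> ProbeMap:
    if not tracks:
        raise ValidationError("at least one track required")
    pm = tracks[0].probe_map
    for t in tracks[1:]:
        if not t.probe_map.same_as(pm):
            raise ValidationError("tracks do not share one probe map")
    return pm


def quantile_normalize(tracks: Sequence[SignalTrack]) -> list[SignalTrack]:
    """Quantile normalization between arrays.

    Forces every track onto the common distribution given by the per-rank
    mean of the input order statistics; ties take the value interpolated at
    their average rank, so within-track rank order is preserved exactly.
    """
    pm = _require_shared_map(tracks)
    mat = np.column_stack([t.concat() for t in tracks])  # probes x tracks
    n = mat.shape[0]
    sorted_mat = np.sort(mat, axis=0)
    target = sorted_mat.mean(axis=1)  # mean of order statistics, length n
    out = []
    for j, t in enumerate(tracks):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n, dtype=float)
        # average ranks over tied values
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=ranks)
        counts = np.bincount(inv)
        ranks = (sums / counts)[inv]
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        new = target[lo] * (1 - frac) + target[hi] * frac
        out.append(t.with_values(new, label=t.label))
    return out


def median_center(track: SignalTrack) -> SignalTrack:
    """Shift a track by a constant so its genome-wide median is zero.

    A location-only stand-in for within-array intensity normalization on
    log-ratio tracks.
    """
    flat = track.concat()
    if len(flat) == 0:
        raise ValidationError("empty track")
    return track.with_values(flat - np.median(flat))


def pool_replicates(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Pool replicates by taking the median probe value.

    An even replicate count yields the mean of the two central values.
    """
    pm = _require_shared_map(tracks)
    mat = np.column_stack([t.concat() for t in tracks])
    pooled = np.median(mat, axis=1)
    return tracks[0].with_values(pooled, label="pooled")


def smooth_running_median(track: SignalTrack, window: int = 3) -> SignalTrack:
    """Running median along each chromosome; the window shrinks at edges.

    ``window`` must be odd.  Smoothing never crosses a chromosome boundary;
    at chromosome edges the window is truncated to the available probes and
    the median of an even count is the mean of the central pair.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if window == 1:
        return SignalTrack(track.probe_map, {c: v.copy() for c, v in track.values.items()}, track.label)
    half = window // 2
    out: dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        n = len(v)
        if n == 0:
            out[chrom] = v.copy()
            continue
        res = np.empty(n)
        if n >= window:
            win = np.lib.stride_tricks.sliding_window_view(v, window)
            res[half : n - half] = np.median(win, axis=1)
        for i in range(min(half, n)):
            res[i] = np.median(v[: i + half + 1][: n])
        for i in range(max(n - half, 0), n):
            res[i] = np.median(v[i - half :])
        if n < window:
            for i in range(n):
                res[i] = np.median(v[max(0, i - half) : i + half + 1])
        out[chrom] = res
    return SignalTrack(track.probe_map, out, track.label)


def subtract_mock(track: SignalTrack, mock: SignalTrack) -> SignalTrack:
    """Adjust by the mock control via direct per-probe subtraction."""
    _require_shared_map([track, mock])
    out = {c: track.values[c] - mock.values[c] for c in track.values}
    return SignalTrack(track.probe_map, out, track.label)


# ---------------------------------------------------------------------------
# bedGraph-style track I/O (chrom, start, end, value); probe center = start.


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.probe_map.chroms:
            pos = track.probe_map.positions[chrom]
            vals = track.values[chrom]
            for p, v in zip(pos, vals):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, probe_map: ProbeMap | None = None) -> SignalTrack:
    """Read a 4-column track; probe centers are the start coordinates.

    If ``probe_map`` is given the file must match it exactly; otherwise a new
    map is built from the file.
    """
    path = Path(path)
    pos: dict[str, list[int]] = {}
    vals: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            pos.setdefault(chrom, []).append(int(fields[1]))
            vals.setdefault(chrom, []).append(float(fields[3]))
    pm = ProbeMap({c: np.array(p, dtype=np.int64) for c, p in pos.items()})
    if probe_map is not None:
        if pm != probe_map:
            raise ValidationError(f"{path}: probes do not match the expected probe map")
        pm = probe_map
    return SignalTrack(pm, {c: np.array(v) for c, v in vals.items()}, label=path.stem)
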