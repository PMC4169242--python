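"""Seeded generators for synthetic genomes, ChIP-chip tracks, and expression.

The generators emulate the statistical structure the downstream analyses
assume — a multi-chromosome genome with non-overlapping gene models, tiling
probes spaced approximately every 300 bp, three-replicate ChIP and mock
log2-ratio tracks with planted enriched regions and Gaussian probe noise,
and two-condition expression matrices with batch structure and planted
fold-changes — so that every pipeline stage is testable without any array
download.  Planted truth is always returned alongside the data.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chip_signal import ProbeMap, SignalTrack
from .genomics_core import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    ValidationError,
)

__all__ = [
    "GenerationError",
    "ChipSimTruth",
    "ExprSimTruth",
    "generate_genome",
    "generate_probe_map",
    "plant_peaks",
    "generate_chip_tracks",
    "generate_expression",
]


class GenerationError(RuntimeError):
    """Rejection sampling could not place the requested features."""


@dataclass
class ChipSimTruth:
    """Ground truth for a planted-peak ChIP-chip simulation.

    amplitude is the log2-ratio enrichment added to every probe falling in a
    planted peak; noise_sd is the per-probe Gaussian noise; artifact peaks
    (regions enriched in both ChIP and mock, e.g. nonspecific sticky
    chromatin) are shared between the ChIP tracks and the mock so that mock
    subtraction can be shown to remove them.
    """

    planted_peaks: PeakSet
    amplitude: float = 2.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    seed: int = 0
    scale_factors: Sequence[float] | None = None
    artifact_peaks: PeakSet | None = None
    artifact_amplitude: float = 1.5

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.scale_factors is not None and len(self.scale_factors) != self.n_replicates:
            raise ValidationError("one scale factor per replicate required")


@dataclass
class ExprSimTruth:
    """Ground truth for a two-condition expression simulation with batches."""

    de_gene_ids: frozenset
    effect_log2: float = 1.0
    noise_sd: float = 0.25
    batch_sd: float = 0.0
    n_per_group: int = 4
    n_batches: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")


def generate_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 100,
    gene_length_range: tuple[int, int] = (1_000, 10_000),
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[GenomeLayout, list[GeneModel]]:
    """A multi-chromosome genome with non-overlapping, uniformly placed genes.

    Genes get random strand and a single exon spanning the gene.  Placement
    uses bounded rejection sampling; an infeasible packing raises
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    layout = GenomeLayout([(f"chr{i + 1}", chrom_length) for i in range(n_chrom)])
    genes: list[GeneModel] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    lo, hi = gene_length_range
    for k in range(n_genes):
        for attempt in range(max_tries):
            chrom = layout.names[rng.integers(0, n_chrom)]
            length = int(rng.integers(lo, hi + 1))
            if length >= chrom_length:
                continue
            start = int(rng.integers(0, chrom_length - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                span = GenomicInterval(chrom, start, end)
                genes.append(GeneModel(f"gene_{k + 1:04d}", span, strand, (span,)))
                break
        else:
            raise GenerationError(
                f"could not place gene {k + 1}/{n_genes} after {max_tries} tries"
            )
    genes.sort(key=lambda g: (g.chrom, g.span.start))
    return layout, genes


def generate_probe_map(
    genome: GenomeLayout,
    spacing: int = 300,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> ProbeMap:
    """Tiling probes spaced approximately every ``spacing`` bp.

    Placement is a deterministic grid at ``spacing/2 + k*spacing`` with
    optional Gaussian jitter; jittered centers are clipped so the order stays
    strictly increasing and every center stays on the chromosome.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        grid = np.arange(spacing // 2, length, spacing, dtype=np.int64)
        if jitter_sd > 0 and len(grid) > 0:
            jit = rng.normal(0.0, jitter_sd, size=len(grid))
            pos = np.clip(np.round(grid + jit), 0, length - 1).astype(np.int64)
            # enforce strict monotonicity after rounding
            pos = np.maximum.accumulate(pos + np.arange(len(pos))) - np.arange(len(pos))
            pos = np.unique(np.clip(pos, 0, length - 1))
        else:
            pos = grid
        positions[chrom] = pos
    return ProbeMap(positions)


def plant_peaks(
    genome: GenomeLayout,
    n_peaks: int = 50,
    length_range: tuple[int, int] = (1_000, 3_000),
    min_separation: int = 2_000,
    seed: int = 0,
    max_tries: int = 500,
) -> PeakSet:
    """Place non-overlapping enriched regions, uniformly across chromosomes.

    Regions keep at least ``min_separation`` bp between each other so that
    the peak caller's gap rule cannot fuse two distinct planted regions.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    for k in range(n_peaks):
        for attempt in range(max_tries):
            chrom = genome.names[rng.integers(0, len(genome.names))]
            clen = genome.length_of(chrom)
            length = int(rng.integers(lo, hi + 1))
            if length >= clen:
                continue
            start = int(rng.integers(0, clen - length + 1))
            end = start + length
            if all(
                end + min_separation <= s or start >= e + min_separation
                for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                break
        else:
            raise GenerationError(f"could not place peak {k + 1}/{n_peaks}")
    intervals = [
        GenomicInterval(chrom, s, e)
        for chrom in genome.names
        for s, e in sorted(placed[chrom])
    ]
    return PeakSet(intervals, source_label="planted")


def _in_regions_mask(probes: ProbeMap, peaks: PeakSet | None) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    arrays = peaks.arrays_by_chrom() if peaks is not None else {}
    for chrom, pos in probes.positions.items():
        mask = np.zeros(len(pos), dtype=bool)
        if chrom in arrays:
            starts, ends = arrays[chrom]
            idx = np.searchsorted(starts, pos, side="right") - 1
            valid = idx >= 0
            mask[valid] = pos[valid] < ends[idx[valid]]
        masks[chrom] = mask
    return masks


def generate_chip_tracks(
    probes: ProbeMap, truth: ChipSimTruth
) -> tuple[list[SignalTrack], SignalTrack]:
    """Replicate ChIP tracks plus a mock control over one probe map.

    Each ChIP probe value is ``amplitude`` inside a planted peak plus
    independent Gaussian noise per replicate; the mock carries only noise
    (plus any shared artifact regions).  Optional per-replicate multiplicative
    scale factors exercise quantile normalization downstream.
    """
    rng = np.random.default_rng(truth.seed)
    peak_mask = _in_regions_mask(probes, truth.planted_peaks)
    art_mask = _in_regions_mask(probes, truth.artifact_peaks)
    scales = truth.scale_factors if truth.scale_factors is not None else [1.0] * truth.n_replicates
    reps: list[SignalTrack] = []
    for r in range(truth.n_replicates):
        values: dict[str, np.ndarray] = {}
        for chrom, pos in probes.positions.items():
            base = truth.amplitude * peak_mask[chrom].astype(float)
            base += truth.artifact_amplitude * art_mask[chrom].astype(float)
            noise = rng.normal(0.0, truth.noise_sd, size=len(pos)) if truth.noise_sd > 0 else 0.0
            values[chrom] = scales[r] * (base + noise)
        reps.append(SignalTrack(probes, values, label=f"chip_rep{r + 1}"))
    mock_values: dict[str, np.ndarray] = {}
    for chrom, pos in probes.positions.items():
        base = truth.artifact_amplitude * art_mask[chrom].astype(float)
        noise = rng.normal(0.0, truth.noise_sd, size=len(pos)) if truth.noise_sd > 0 else 0.0
        mock_values[chrom] = base + noise
    mock = SignalTrack(probes, mock_values, label="mock")
    return reps, mock


def generate_expression(
    gene_ids: Sequence[str], truth: ExprSimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A genes x samples log2-intensity matrix and its design table.

    ``value(g, s) = baseline(g) + effect_log2 * 1[g is DE and s induced]
    + batch(s) + N(0, noise_sd)``.  Batches are assigned in a balanced
    round-robin within each condition and share one Gaussian batch effect.
    The design table has one row per sample with columns ``condition``
    ({control, induced}) and ``batch``.
    """
    unknown = set(truth.de_gene_ids) - set(gene_ids)
    if unknown:
        raise ValidationError(f"DE gene ids not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(truth.seed)
    genes = list(gene_ids)
    n_g = len(genes)
    conditions = ["control"] * truth.n_per_group + ["induced"] * truth.n_per_group
    batches = [f"b{i % truth.n_batches + 1}" for i in range(truth.n_per_group)] * 2
    samples = [f"s{i + 1:02d}_{c}" for i, c in enumerate(conditions)]
    design = pd.DataFrame({"condition": conditions, "batch": batches}, index=samples)

    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, size=n_g)
    batch_levels = sorted(set(batches))
    batch_eff = {
        b: (rng.normal(0.0, truth.batch_sd) if truth.batch_sd > 0 else 0.0)
        for b in batch_levels
    }
    de = np.array([g in truth.de_gene_ids for g in genes], dtype=float)
    mat = np.empty((n_g, len(samples)))
    for j, (cond, batch) in enumerate(zip(conditions, batches)):
        mu = baseline + truth.effect_log2 * de * (cond == "induced") + batch_eff[batch]
        noise = rng.normal(0.0, truth.noise_sd, size=n_g) if truth.noise_sd > 0 else 0.0
        mat[:, j] = mu + noise
    expr = pd.DataFrame(mat, index=genes, columns=samples)
    return expr, design
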