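"""Peak-to-gene association, feature classification, and enrichment nulls.

Peaks are associated with every gene whose body lies within a fixed flank
(1 kb by default) of the peak boundaries.  For feature classification a peak
counts toward every category it intersects — gene bodies, strand-aware 1 kb
upstream flanks, strand-aware 1 kb downstream flanks — and toward
"intergenic" when it touches none of them.  Observed category frequencies
are compared with a null of random peak sets of identical size, length and
chromosomal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_core import (
    ChromCoverage,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    ValidationError,
    merge_interval_arrays,
)

__all__ = [
    "EnrichmentResult",
    "CATEGORIES",
    "peak_ids",
    "associate_peaks_to_genes",
    "classify_peak_features",
    "random_peak_set",
    "feature_enrichment",
]

CATEGORIES = ("upstream", "downstream", "genes", "intergenic")


@dataclass
class EnrichmentResult:
    """Per-category observed frequency against the random-placement null.

    ``table`` has one row per category with columns observed_frequency,
    null_mean, null_sd, z_score, empirical_p, degenerate.  The empirical p
    is one-sided in the direction of the observed deviation and floored at
    ``1/(n_sim+1)``; a category whose null is constant (sd 0) is flagged
    degenerate and its z reported as 0.
    """

    table: pd.DataFrame
    n_sim: int
    seed: int | None = None


def peak_ids(peaks: PeakSet) -> list[str]:
    return [
        iv.name if iv.name is not None else f"peak_{i + 1}"
        for i, iv in enumerate(peaks)
    ]


def _interval_gene_gap_matrix(
    ps: np.ndarray, pe: np.ndarray, gs: np.ndarray, ge: np.ndarray
) -> np.ndarray:
    """Pairwise basepair gap between peaks (rows) and genes (cols); 0 if overlapping."""
    left = gs[None, :] - pe[:, None]  # gene downstream of peak
    right = ps[:, None] - ge[None, :]  # gene upstream of peak
    return np.maximum(np.maximum(left, right), 0)


def associate_peaks_to_genes(
    peaks: PeakSet, genes: list[GeneModel], flank: int = 1000
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Map peaks to genes whose span lies within ``flank`` bp (gap <= flank).

    The gap between half-open intervals is 0 when they overlap, otherwise the
    basepair distance between the nearest boundaries.  Returns the forward
    map (peak id -> gene ids) and its inverse (gene id -> peak ids); the two
    are inverse images of each other.
    """
    ids = peak_ids(peaks)
    fwd: dict[str, set[str]] = {pid: set() for pid in ids}
    inv: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    by_chrom_genes: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
    by_chrom_peaks: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for pid, iv in zip(ids, peaks):
        by_chrom_peaks.setdefault(iv.chrom, []).append((pid, iv))
    for chrom, plist in by_chrom_peaks.items():
        glist = by_chrom_genes.get(chrom, [])
        if not glist:
            continue
        ps = np.array([iv.start for _, iv in plist])
        pe = np.array([iv.end for _, iv in plist])
        gs = np.array([g.span.start for g in glist])
        ge = np.array([g.span.end for g in glist])
        gap = _interval_gene_gap_matrix(ps, pe, gs, ge)
        hit_p, hit_g = np.nonzero(gap <= flank)
        for i, j in zip(hit_p, hit_g):
            pid = plist[i][0]
            gid = glist[j].gene_id
            fwd[pid].add(gid)
            inv[gid].add(pid)
    return fwd, inv


def _category_coverages(
    genes: list[GeneModel], genome: GenomeLayout, flank: int
) -> dict[str, dict[str, ChromCoverage]]:
    """Merged interval coverage per chromosome for gene-body/upstream/downstream."""
    regions: dict[str, dict[str, list[tuple[int, int]]]] = {
        "genes": {},
        "upstream": {},
        "downstream": {},
    }
    for g in genes:
        L = genome.length_of(g.chrom)
        s, e = g.span.start, g.span.end
        regions["genes"].setdefault(g.chrom, []).append((s, e))
        if g.strand == "+":
            up = (max(0, s - flank), s)
            down = (e, min(L, e + flank))
        else:
            up = (e, min(L, e + flank))
            down = (max(0, s - flank), s)
        if up[1] > up[0]:
            regions["upstream"].setdefault(g.chrom, []).append(up)
        if down[1] > down[0]:
            regions["downstream"].setdefault(g.chrom, []).append(down)
    out: dict[str, dict[str, ChromCoverage]] = {}
    for cat, per_chrom in regions.items():
        out[cat] = {}
        for chrom, ivs in per_chrom.items():
            s = np.array([a for a, _ in ivs], dtype=np.int64)
            e = np.array([b for _, b in ivs], dtype=np.int64)
            out[cat][chrom] = ChromCoverage(*merge_interval_arrays(s, e))
    return out


def _classify_arrays(
    arrays: dict[str, tuple[np.ndarray, np.ndarray]],
    covs: dict[str, dict[str, ChromCoverage]],
) -> dict[str, int]:
    counts = dict.fromkeys(CATEGORIES, 0)
    for chrom, (ps, pe) in arrays.items():
        any_hit = np.zeros(len(ps), dtype=bool)
        for cat in ("upstream", "downstream", "genes"):
            cov = covs[cat].get(chrom)
            if cov is None:
                continue
            hit = cov.overlap_bp(ps, pe) > 0
            counts[cat] += int(hit.sum())
            any_hit |= hit
        counts["intergenic"] += int((~any_hit).sum())
    return counts


def classify_peak_features(
    peaks: PeakSet, genes: list[GeneModel], genome: GenomeLayout, flank: int = 1000
) -> dict[str, int]:
    """Count peaks per genomic-feature category (categories not exclusive).

    A peak counts toward every category it intersects by at least one
    basepair; "intergenic" collects peaks touching no gene body and no flank.
    """
    covs = _category_coverages(genes, genome, flank)
    return _classify_arrays(peaks.arrays_by_chrom(), covs)


def random_peak_set(
    peaks: PeakSet,
    genome: GenomeLayout,
    rng: np.random.Generator,
    disjoint: bool = False,
    max_tries: int = 1000,
) -> PeakSet:
    """A random peak set of identical size, length and chromosomal distribution.

    Each peak keeps its chromosome and length; its start is uniform on
    ``[0, chrom_length - length]``.  By default random peaks may overlap each
    other (the null preserves marginal placement, not disjointness);
    ``disjoint=True`` rejection-samples a mutually disjoint configuration.
    """
    intervals: list[GenomicInterval] = []
    for chrom, (starts, ends) in peaks.arrays_by_chrom().items():
        L = genome.length_of(chrom)
        lengths = ends - starts
        if np.any(lengths > L):
            raise ValidationError(f"peak longer than chromosome {chrom}")
        if not disjoint:
            new_starts = rng.integers(0, L - lengths + 1)
            for s, l in zip(new_starts, lengths):
                intervals.append(GenomicInterval(chrom, int(s), int(s + l)))
        else:
            placed: list[tuple[int, int]] = []
            for l in lengths:
                for _ in range(max_tries):
                    s = int(rng.integers(0, L - l + 1))
                    if all(s + l <= a or s >= b for a, b in placed):
                        placed.append((s, s + int(l)))
                        break
                else:
                    raise ValidationError(f"could not place disjoint random peak on {chrom}")
            intervals.extend(GenomicInterval(chrom, a, b) for a, b in placed)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return _RawPeakCollection(intervals, source_label="random")


class _RawPeakCollection(PeakSet):
    """A peak collection whose members may mutually overlap (random nulls)."""

    def __init__(self, intervals, source_label=""):
        self.intervals = list(intervals)
        self.source_label = source_label
        self.probe_counts = None


def feature_enrichment(
    peaks: PeakSet,
    genes: list[GeneModel],
    genome: GenomeLayout,
    n_sim: int = 1000,
    seed: int | None = None,
    flank: int = 1000,
) -> EnrichmentResult:
    """Feature-category enrichment of a peak set against random placement.

    Draws ``n_sim`` random peak sets of identical size/length/chromosomal
    distribution, recomputes the category frequencies for each, and reports
    per category: z = (observed - null_mean)/null_sd and a one-sided
    empirical p = (1 + #{null as or more extreme})/(n_sim + 1).
    """
    if n_sim < 2:
        raise ValidationError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    n_peaks = len(peaks)
    covs = _category_coverages(genes, genome, flank)
    obs_counts = _classify_arrays(peaks.arrays_by_chrom(), covs)
    null = np.empty((n_sim, len(CATEGORIES)))
    # resample starts directly on arrays to avoid object overhead per draw
    by_chrom = peaks.arrays_by_chrom()
    lengths = {c: e - s for c, (s, e) in by_chrom.items()}
    for it in range(n_sim):
        arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lens in lengths.items():
            L = genome.length_of(chrom)
            s = rng.integers(0, L - lens + 1)
            arrays[chrom] = (s, s + lens)
        counts = _classify_arrays(arrays, covs)
        null[it] = [counts[c] for c in CATEGORIES]
    rows = []
    for j, cat in enumerate(CATEGORIES):
        obs = obs_counts[cat]
        nm, nsd = float(null[:, j].mean()), float(null[:, j].std(ddof=1))
        degenerate = nsd == 0.0
        z = 0.0 if degenerate else (obs - nm) / nsd
        if obs >= nm:
            extreme = int((null[:, j] >= obs).sum())
        else:
            extreme = int((null[:, j] <= obs).sum())
        p = (1 + extreme) / (n_sim + 1)
        denom = n_peaks if n_peaks else 1
        rows.append(
            {
                "category": cat,
                "observed_count": obs,
                "observed_frequency": obs / denom,
                "null_mean": nm / denom,
                "null_sd": nsd / denom,
                "z_score": z,
                "empirical_p": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    return EnrichmentResult(table=table, n_sim=n_sim, seed=seed)
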