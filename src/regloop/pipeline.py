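"""Config-driven orchestration of the three analyses.

Ties the stages into the study's workflow: (1) ChIP signal processing ->
peak calling -> gene association -> feature enrichment; (2) two-factor
overlap statistics (directional peak overlap counts, hypergeometric bound
gene-set overlap, block-bootstrap basepair overlap); (3) Boolean model
comparison.  A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed documented order, so a
rerun with the same config is byte-identical and any stage can be rerun in
isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import chip_signal as cs
from . import synthetic_data as syn
from .boolean_net import build_feedforward_model, build_linear_model, compare_models, parse_network, simulate_probability
from .de_analysis import de_bound_enrichment, presence_filter, select_de
from .genomics_core import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    ValidationError,
    directional_peak_overlap_counts,
    read_bed,
    read_gff3,
    write_bed,
    write_gff3,
)
from .overlap_stats import BootstrapParams, block_bootstrap_overlap, gene_overlap_hypergeom
from .peak_annotation import associate_peaks_to_genes, feature_enrichment, peak_ids
from .peak_calling import PeakCallParams, call_peaks, peak_summary

__all__ = [
    "PipelineConfig",
    "stage_seeds",
    "run_chip_pipeline",
    "run_overlap_pipeline",
    "run_boolnet_pipeline",
    "run_demo",
]

# fixed fan-out order for the global seed
_STAGES = ("simulate", "chip", "annotate", "enrich", "overlap", "de", "boolnet")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds spawned from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Validated stage parameters plus paths; round-trips losslessly to YAML."""

    seed: int = 0
    outdir: str = "regloop_out"
    tracks: list[str] = field(default_factory=list)
    mock_track: str | None = None
    genes: str | None = None
    genome: dict[str, int] = field(default_factory=dict)  # chrom -> length
    peaks_a: str | None = None
    peaks_b: str | None = None
    smoothing_window: int = 3
    subtract_first: bool = False
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    flank: int = 1000
    n_sim: int = 1000
    bootstrap: BootstrapParams = field(default_factory=BootstrapParams)
    de_q: float = 0.05
    de_min_present: int = 4
    expression: str | None = None
    design: str | None = None
    boolnet_transitions: int = 1000

    _PATH_FIELDS = ("mock_track", "genes", "peaks_a", "peaks_b", "expression", "design")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; relative paths resolve against the file's directory."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in cls._PATH_FIELDS + ("outdir",):
            if raw.get(key) and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        if raw.get("tracks"):
            raw["tracks"] = [
                str(base / t) if not Path(t).is_absolute() else t for t in raw["tracks"]
            ]
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        peak_params = PeakCallParams(**raw.pop("peak_params", {}))
        bootstrap = BootstrapParams(**raw.pop("bootstrap", {}))
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(peak_params=peak_params, bootstrap=bootstrap, **raw)

    def to_dict(self, relative_to: str | Path | None = None) -> dict[str, Any]:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k not in ("peak_params", "bootstrap")
        }
        d["peak_params"] = vars(self.peak_params).copy()
        d["bootstrap"] = vars(self.bootstrap).copy()
        if relative_to is not None:
            base = Path(relative_to).resolve()

            def rel(p):
                if p is None:
                    return None
                q = Path(p).resolve()
                try:
                    return str(q.relative_to(base))
                except ValueError:
                    return str(p)

            d["outdir"] = rel(d["outdir"]) or "."
            d["tracks"] = [rel(t) for t in d["tracks"]]
            for key in self._PATH_FIELDS:
                d[key] = rel(d[key])
        return d

    def to_yaml(self, path: str | Path, relative_to: str | Path | None = None) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(relative_to), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(self.outdir), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: PipelineConfig, stages: list[dict[str, Any]]) -> Path:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "artifacts": {
            p.name: _hash_file(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_genome(config: PipelineConfig) -> GenomeLayout:
    if not config.genome:
        raise ValidationError("config.genome (chrom -> length) is required")
    return GenomeLayout(list(config.genome.items()))


def run_chip_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """normalize -> pool -> smooth -> subtract mock -> call peaks -> annotate -> enrich.

    Every artifact lands in ``config.outdir`` and is stamped (via the run
    manifest) with the config hash and seed.
    """
    if not config.tracks:
        raise ValidationError("config.tracks must list at least one replicate track")
    if config.mock_track is None:
        raise ValidationError("config.mock_track is required")
    if config.genes is None:
        raise ValidationError("config.genes (GFF3) is required")
    genome = _load_genome(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    reps = [cs.read_bedgraph(p) for p in config.tracks]
    for t in reps[1:]:
        if t.probe_map != reps[0].probe_map:
            raise ValidationError("replicate tracks do not share one probe map")
    reps = [cs.SignalTrack(reps[0].probe_map, t.values, t.label) for t in reps]
    mock = cs.read_bedgraph(config.mock_track, probe_map=reps[0].probe_map)

    normed = cs.quantile_normalize([cs.median_center(t) for t in reps])
    pooled = cs.pool_replicates(normed)
    mock_centered = cs.median_center(mock)
    if config.subtract_first:
        adjusted = cs.smooth_running_median(
            cs.subtract_mock(pooled, mock_centered), config.smoothing_window
        )
    else:
        adjusted = cs.subtract_mock(
            cs.smooth_running_median(pooled, config.smoothing_window),
            cs.smooth_running_median(mock_centered, config.smoothing_window),
        )
    peaks = call_peaks(adjusted, config.peak_params)

    genes = read_gff3(config.genes)
    fwd, _ = associate_peaks_to_genes(peaks, genes, flank=config.flank)
    enr = feature_enrichment(
        peaks, genes, genome, n_sim=config.n_sim, seed=seeds["enrich"], flank=config.flank
    )

    artifacts: dict[str, Path] = {}
    artifacts["peaks_bed"] = outdir / "peaks.bed"
    write_bed(peaks, artifacts["peaks_bed"])
    artifacts["peak_summary"] = outdir / "peak_summary.tsv"
    peak_summary(peaks).to_csv(artifacts["peak_summary"], sep="\t", header=False)
    artifacts["association"] = outdir / "peak_gene_association.tsv"
    with open(artifacts["association"], "w") as fh:
        fh.write("peak_id\tgene_id\n")
        for pid in peak_ids(peaks):
            for gid in sorted(fwd[pid]):
                fh.write(f"{pid}\t{gid}\n")
    artifacts["enrichment"] = outdir / "feature_enrichment.tsv"
    enr.table.to_csv(artifacts["enrichment"], sep="\t")
    _write_manifest(
        outdir,
        config,
        [{"stage": "chip", "window": config.smoothing_window, "peak_params": vars(config.peak_params).copy()}],
    )
    return artifacts


def run_overlap_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Directional peak overlap, bound-gene hypergeometric, block bootstrap."""
    if config.peaks_a is None or config.peaks_b is None:
        raise ValidationError("config.peaks_a and config.peaks_b are required")
    if config.genes is None:
        raise ValidationError("config.genes (GFF3) is required")
    genome = _load_genome(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    a = read_bed(config.peaks_a, source_label="A")
    b = read_bed(config.peaks_b, source_label="B")
    genes = read_gff3(config.genes)
    count_a, count_b, mean_count = directional_peak_overlap_counts(a, b)
    fwd_a, _ = associate_peaks_to_genes(a, genes, flank=config.flank)
    fwd_b, _ = associate_peaks_to_genes(b, genes, flank=config.flank)
    bound_a = set().union(*fwd_a.values()) if fwd_a else set()
    bound_b = set().union(*fwd_b.values()) if fwd_b else set()
    universe = {g.gene_id for g in genes}
    k, p_hyper = gene_overlap_hypergeom(bound_a, bound_b, universe)
    boot = block_bootstrap_overlap(
        a,
        b,
        genome,
        BootstrapParams(
            n_iterations=config.bootstrap.n_iterations,
            block_length=config.bootstrap.block_length,
            seed=seeds["overlap"],
        ),
    )
    report = pd.DataFrame(
        [
            ("peaks_a", len(a)),
            ("peaks_b", len(b)),
            ("a_overlapping_b", count_a),
            ("b_overlapping_a", count_b),
            ("mean_overlap_count", mean_count),
            ("frac_a_overlapping", count_a / len(a) if len(a) else 0.0),
            ("frac_b_overlapping", count_b / len(b) if len(b) else 0.0),
            ("bound_genes_a", len(bound_a)),
            ("bound_genes_b", len(bound_b)),
            ("bound_gene_overlap", k),
            ("hypergeom_p", p_hyper),
            ("observed_bp_overlap", boot.observed),
            ("bootstrap_null_mean", boot.null_mean),
            ("bootstrap_null_sd", boot.null_sd),
            ("bootstrap_z", boot.z_score),
            ("bootstrap_p_empirical", boot.p_value),
            ("bootstrap_p_normal", boot.p_normal),
            ("bootstrap_iterations", boot.n_iterations),
            ("block_length", boot.block_length),
        ],
        columns=["metric", "value"],
    )
    path = outdir / "overlap_report.tsv"
    report.to_csv(path, sep="\t", index=False)
    _write_manifest(outdir, config, [{"stage": "overlap", "bootstrap": vars(config.bootstrap).copy()}])
    return {"overlap_report": path}


def run_boolnet_pipeline(
    config: PipelineConfig, mc_check: bool = True
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Exact model x scenario probability table with an optional MC column."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    models = {"linear": build_linear_model(), "feedforward": build_feedforward_model()}
    table = compare_models(models, n_transitions=config.boolnet_transitions)
    if mc_check:
        from .boolean_net import SCENARIOS

        for sc, clamp in SCENARIOS.items():
            col = []
            for name, net in models.items():
                r = simulate_probability(
                    net,
                    clamps=clamp,
                    n_transitions=config.boolnet_transitions,
                    mode="monte_carlo",
                    n_runs=10_000,
                    seed=seeds["boolnet"],
                )
                col.append(r.probability_target_active)
            table[f"{sc}_mc"] = col
    path = outdir / "boolnet_probabilities.tsv"
    table.to_csv(path, sep="\t")
    _write_manifest(outdir, config, [{"stage": "boolnet", "transitions": config.boolnet_transitions}])
    return table, {"boolnet_table": path}


def run_demo(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """End-to-end synthetic demonstration exercising every pipeline stage.

    Simulates a small genome with planted ChIP peaks for two factors and a
    two-condition expression matrix, writes the simulated inputs, then runs
    the ChIP, overlap, DE and Boolean analyses.  Deterministic: the same
    seed yields byte-identical artifacts.
    """
    outdir = Path(outdir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    srng = np.random.SeedSequence(seeds["simulate"])
    s_genome, s_probes, s_peaks_a, s_peaks_b, s_chip, s_expr = (
        int(c.generate_state(1, np.uint32)[0] % (2**31)) for c in srng.spawn(6)
    )

    genome, genes = syn.generate_genome(
        n_chrom=2, chrom_length=1_000_000, n_genes=120, seed=s_genome
    )
    probes = syn.generate_probe_map(genome, spacing=300, jitter_sd=30.0, seed=s_probes)
    planted_a = syn.plant_peaks(genome, n_peaks=30, seed=s_peaks_a)
    truth = syn.ChipSimTruth(planted_a, amplitude=2.0, noise_sd=0.3, n_replicates=3, seed=s_chip)
    reps, mock = syn.generate_chip_tracks(probes, truth)
    # a second, partially shifted factor for the overlap analysis
    shifted = [
        GenomicInterval(iv.chrom, max(0, iv.start - 400), max(1, iv.end - 400))
        for iv in planted_a
    ]
    planted_b = PeakSet(sorted(shifted, key=lambda iv: (iv.chrom, iv.start)), "factor_b")

    track_paths = []
    for t in reps:
        p = datadir / f"{t.label}.bedgraph"
        cs.write_bedgraph(t, p)
        track_paths.append(str(p))
    mock_path = datadir / "mock.bedgraph"
    cs.write_bedgraph(mock, mock_path)
    genes_path = datadir / "genes.gff3"
    write_gff3(genes, genes_path)
    truth_path = datadir / "planted_peaks.bed"
    write_bed(planted_a, truth_path)
    peaks_b_path = datadir / "factor_b_peaks.bed"
    write_bed(planted_b, peaks_b_path)

    gene_ids = [g.gene_id for g in genes]
    expr_truth = syn.ExprSimTruth(
        de_gene_ids=frozenset(gene_ids[:20]), effect_log2=1.0, noise_sd=0.25,
        batch_sd=0.3, n_per_group=4, seed=s_expr,
    )
    expr, design = syn.generate_expression(gene_ids, expr_truth)
    expr_path = datadir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t")
    design_path = datadir / "design.tsv"
    design.to_csv(design_path, sep="\t")

    config = PipelineConfig(
        seed=seed,
        outdir=str(outdir),
        tracks=track_paths,
        mock_track=str(mock_path),
        genes=str(genes_path),
        genome={c: l for c, l in genome.chromosomes},
        peaks_a=str(outdir / "peaks.bed"),
        peaks_b=str(peaks_b_path),
        n_sim=200,
        bootstrap=BootstrapParams(n_iterations=500, block_length=100_000, seed=seeds["overlap"]),
        expression=str(expr_path),
        design=str(design_path),
    )
    config.to_yaml(outdir / "config.yaml", relative_to=outdir)

    artifacts = run_chip_pipeline(config)
    artifacts.update(run_overlap_pipeline(config))
    _, bool_art = run_boolnet_pipeline(config)
    artifacts.update(bool_art)

    filtered = presence_filter(expr, min_samples=config.de_min_present)
    de = select_de(filtered, design, q=config.de_q)
    de_path = outdir / "de_results.tsv"
    de.table.to_csv(de_path, sep="\t")
    de_genes = set(de.table.index[de.table["selected"]])
    assoc = pd.read_csv(artifacts["association"], sep="\t")
    bound = set(assoc["gene_id"]) if len(assoc) else set()
    k, p = de_bound_enrichment(de_genes, bound & set(gene_ids), set(gene_ids))
    summary = pd.DataFrame(
        [
            ("de_selected", de.n_selected),
            ("de_p_cutoff", de.p_cutoff),
            ("de_bound_overlap", k),
            ("de_bound_enrichment_p", p),
        ],
        columns=["metric", "value"],
    )
    de_summary_path = outdir / "de_summary.tsv"
    summary.to_csv(de_summary_path, sep="\t", index=False)
    artifacts["de_results"] = de_path
    artifacts["de_summary"] = de_summary_path
    _write_manifest(outdir, config, [{"stage": "demo", "seed": seed}])
    return artifacts
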