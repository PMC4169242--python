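#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a two-chromosome genome with gene models, a ~300 bp tiling probe map,
three-replicate ChIP and mock log2-ratio tracks with 50 planted enriched
regions (amplitude 2.0, probe noise 0.3), a second partially shifted factor
for the overlap analysis, and a two-condition expression matrix (4 vs 4,
two dissection batches, 100 planted 2-fold changes among 2000 genes).

Writes everything under results/data/ as bedGraph/BED/GFF3/TSV.
"""

from pathlib import Path

import numpy as np

from regloop import chip_signal as cs
from regloop import synthetic_data as syn
from regloop.genomics_core import GenomicInterval, PeakSet, write_bed, write_gff3

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rngs = np.random.SeedSequence(SEED).spawn(6)
    s = [int(r.generate_state(1, np.uint32)[0] % 2**31) for r in rngs]

    genome, genes = syn.generate_genome(
        n_chrom=2, chrom_length=5_000_000, n_genes=800, seed=s[0]
    )
    probes = syn.generate_probe_map(genome, spacing=300, jitter_sd=30.0, seed=s[1])
    planted = syn.plant_peaks(genome, n_peaks=50, length_range=(1_000, 3_000), seed=s[2])
    truth = syn.ChipSimTruth(
        planted, amplitude=2.0, noise_sd=0.3, n_replicates=3, seed=s[3]
    )
    reps, mock = syn.generate_chip_tracks(probes, truth)

    # second factor: same regions shifted 400 bp, emulating a co-binding TF
    shifted = sorted(
        (GenomicInterval(iv.chrom, max(0, iv.start - 400), iv.end - 400) for iv in planted),
        key=lambda iv: (iv.chrom, iv.start),
    )
    factor_b = PeakSet(shifted, "factor_b")

    for t in reps:
        cs.write_bedgraph(t, OUT / f"{t.label}.bedgraph")
    cs.write_bedgraph(mock, OUT / "mock.bedgraph")
    write_gff3(genes, OUT / "genes.gff3")
    write_bed(planted, OUT / "planted_peaks.bed")
    write_bed(factor_b, OUT / "factor_b_peaks.bed")

    gene_ids = [g.gene_id for g in genes]
    # DE genes are drawn among genes near planted peaks where possible, so the
    # expression and ChIP arms share targets (as a feed-forward TF pair would)
    near = []
    arrays = planted.arrays_by_chrom()
    for g in genes:
        if g.chrom in arrays:
            starts, ends = arrays[g.chrom]
            gap = np.maximum(np.maximum(starts - g.span.end, g.span.start - ends), 0)
            if (gap <= 1000).any():
                near.append(g.gene_id)
    de_ids = (near + [g for g in gene_ids if g not in near])[:100]
    expr_truth = syn.ExprSimTruth(
        de_gene_ids=frozenset(de_ids), effect_log2=1.0, noise_sd=0.25,
        batch_sd=0.3, n_per_group=4, seed=s[4],
    )
    expr, design = syn.generate_expression(gene_ids, expr_truth)
    expr.to_csv(OUT / "expression.tsv", sep="\t")
    design.to_csv(OUT / "design.tsv", sep="\t")
    (OUT / "de_truth.txt").write_text("".join(f"{g}\n" for g in sorted(de_ids)))
    (OUT / "genome.txt").write_text(
        "".join(f"{c}\t{l}\n" for c, l in genome.chromosomes)
    )
    print(f"genome: {len(genome.names)} chromosomes x 5 Mb, {len(genes)} genes")
    print(f"probes: {probes.n_probes} (~300 bp spacing)")
    print(f"planted: {len(planted)} ChIP peaks, {len(de_ids)} DE genes "
          f"({len(near[:100])} near peaks)")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
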