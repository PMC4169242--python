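#!/usr/bin/env python
"""Expression arm: FDR-controlled selection and the ChIP-DE join.

Filters genes on presence (intensity floor in enough samples), fits per-gene
OLS of log2 intensity on condition + dissection batch, converts FDR 5% into
a p cutoff by Benjamini-Hochberg, and asks whether the selected genes are
enriched for peak-bound genes (hypergeometric).  Writes results/de/.
"""

from pathlib import Path

import pandas as pd

from regloop.de_analysis import de_bound_enrichment, presence_filter, select_de

SEED = 20240901
ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    data = ROOT / "data"
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    expr = pd.read_csv(data / "expression.tsv", sep="\t", index_col=0)
    design = pd.read_csv(data / "design.tsv", sep="\t", index_col=0)
    truth = set((data / "de_truth.txt").read_text().split())

    filtered = presence_filter(expr, min_samples=5)
    res = select_de(filtered, design, q=0.05)
    res.table.to_csv(out / "de_results.tsv", sep="\t")
    sel = set(res.table.index[res.table["selected"]])
    print(f"presence filter kept {len(filtered)}/{len(expr)} genes")
    print(f"BH at FDR 5%: p cutoff {res.p_cutoff:.5f}, {res.n_selected} genes selected")
    tp = len(sel & truth)
    print(f"of {len(sel)} selected, {tp} are planted DE genes "
          f"(FDP {1 - tp / max(len(sel), 1):.3f})")

    assoc = pd.read_csv(ROOT / "chip" / "peak_gene_association.tsv", sep="\t")
    bound = set(assoc["gene_id"])
    universe = set(expr.index)
    k, p = de_bound_enrichment(sel, bound & universe, universe)
    summary = pd.DataFrame(
        [
            ("n_filtered", len(filtered)),
            ("p_cutoff", res.p_cutoff),
            ("n_selected", res.n_selected),
            ("true_positives", tp),
            ("bound_gene_overlap", k),
            ("bound_enrichment_p", p),
        ],
        columns=["metric", "value"],
    )
    summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
    print(f"selected genes vs peak-bound genes: overlap {k}, hypergeometric p = {p:.3g}")


if __name__ == "__main__":
    main()
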