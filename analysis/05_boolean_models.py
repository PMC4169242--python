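#!/usr/bin/env python
"""Boolean-circuit arm: can a linear cascade explain the genetics?

Compares the linear model (dFOXO -> AOP -| PNT -| lifespan) with the
feed-forward model (dFOXO additionally joins PNT in a NAND gate on
lifespan).  For each model, clamps dFOXO, PNT, or both active and computes
the exact probability that lifespan = 1 after 1000 synchronous transitions
(uniform over the remaining initial states), plus a 10000-run Monte-Carlo
cross-check.  Writes results/boolnet/.
"""

from pathlib import Path

from regloop.pipeline import PipelineConfig, run_boolnet_pipeline

SEED = 20240901
ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    config = PipelineConfig(seed=SEED, outdir=str(ROOT / "boolnet"))
    table, _ = run_boolnet_pipeline(config, mc_check=True)
    print(table.to_string())
    print()
    ff, lin = table.loc["feedforward"], table.loc["linear"]
    print("only the feed-forward circuit is synergistic: clamping both factors")
    print(f"collapses lifespan (P = {ff['both_active']}) below either single clamp "
          f"(dFOXO: {ff['dFOXO_active']}, PNT: {ff['PNT_active']});")
    print(f"the linear cascade cannot distinguish PNT alone from both "
          f"(P = {lin['PNT_active']} vs {lin['both_active']}).")


if __name__ == "__main__":
    main()
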