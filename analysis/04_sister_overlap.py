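#!/usr/bin/env python
"""Sister-species overlap across geography and ecology.

Computes Schoener's D for every cherry of the six synthetic clades along
the four dimensions (87 fine geographic units, 5 aggregated regions,
bedrock types, elevation belts) and summarizes the proportion of
zero-overlap pairs and the median overlap per dimension and lineage --
the summary layout of the sister-species analysis.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from montane import read_newick, sister_overlap_table, summarize_overlap
from montane.simulate import sim_occupancy

SEED = 7
BASE = Path(__file__).resolve().parents[1] / "results"
DATA = BASE / "synthetic_dataset"
OUT = BASE / "overlap"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open(DATA / "clades.json") as fh:
        cfg = json.load(fh)["clades"]
    rng = np.random.default_rng(SEED)
    all_records = []
    for name in cfg:
        tree = read_newick(DATA / f"{name}.nwk")
        # plant a known allopatric fraction near the study's fine-scale
        # signal (about a third of sister pairs fully disjoint)
        n_ch = len(tree.cherries())
        k = round(0.37 * n_ch)
        occ = sim_occupancy(tree, allopatric_fraction=k / n_ch,
                            seed=int(rng.integers(2 ** 31)))
        all_records.append(sister_overlap_table(tree, occ, lineage=name))
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(OUT / "overlap_records.csv", index=False)
    summary = summarize_overlap(records, by_lineage=True)
    summary.to_csv(OUT / "overlap_summary.csv", index=False)

    pooled = summary[summary.lineage == "all"].set_index("dimension")
    print(f"{len(records)} sister pairs across six clades")
    print("pooled summary (median D, proportion of zero-overlap pairs):")
    print(pooled[["n_pairs", "median_d", "prop_zero"]].round(3).to_string())
    print("\nzero-overlap proportion at the fine geographic scale "
          f"({pooled.loc['fine_geo', 'prop_zero']:.2f}) recovers the planted "
          "allopatric fraction; aggregation to 5 regions collapses most of "
          "that signal "
          f"({pooled.loc['coarse_geo', 'prop_zero']:.2f}).")


if __name__ == "__main__":
    main()
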