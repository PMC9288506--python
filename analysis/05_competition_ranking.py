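#!/usr/bin/env python
"""Rank candidate targets from the iTRAQ competition pulldown: median
normalization per channel, then ordering by the minimum-across-replicates
log2 fold-change at the highest free-compound dose (800 uM), significance
at log2FC > 2 in both replicates.

Reads results/inputs/competition.tsv; writes results/targets.tsv.
"""

import json
from pathlib import Path

from lipsite.competition import median_normalize, rank_targets, read_competition_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    table = read_competition_table(ROOT / "inputs" / "competition.tsv")
    normalized = median_normalize(table)
    ranking = rank_targets(normalized, threshold=2.0, replicates_required="all")
    ranking.to_csv(ROOT / "targets.tsv", sep="\t", index=False)

    truth = json.loads((ROOT / "inputs" / "truth.json").read_text())
    n_sig = int(ranking["significant"].sum())
    print(f"proteins quantified in all channels of both replicates: {len(ranking)}")
    print(f"significant targets (log2FC > 2 in both replicates): {n_sig}")
    for _, row in ranking.head(3).iterrows():
        mark = " <- planted target" if row["protein_id"] == truth["competition_target"] else ""
        print(
            f"  {row['protein_id']}  min log2FC={row['min_log2_fc']:.2f}  "
            f"peptides={int(row['unique_peptides'])}  "
            f"significant={bool(row['significant'])}{mark}"
        )


if __name__ == "__main__":
    main()
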