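#!/usr/bin/env python
"""Generate the study inputs: a 10-concentration LiP-MS dose-response
experiment (500 peptides, 10 responsive at EC50 1 uM, CV 5%, 3 replicates)
with its toy target structure, and an iTRAQ competition pulldown (vehicle /
8 / 80 / 800 uM, 2 replicates, planted target at log2FC 3).

Writes results/inputs/{lip_quant.tsv, target.pdb, competition.tsv,
truth.json}; later scripts consume these files only.
"""

import json
from pathlib import Path

from lipsite import simulate_competition_experiment, simulate_lip_experiment
from lipsite.quant_io import write_peptide_report, write_structure

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    quant, structure, lip_truth = simulate_lip_experiment(
        n_peptides=500, n_responsive=10, ec50=1e-6, effect_log2=1.5,
        noise_cv=0.05, seed=SEED,
    )
    write_peptide_report(quant, OUT / "lip_quant.tsv")
    write_structure(structure, OUT / "target.pdb")

    comp, comp_truth = simulate_competition_experiment(
        n_proteins=300, target_log2fc=3.0, n_replicates=2, seed=SEED + 6
    )
    comp.to_csv(OUT / "competition.tsv", sep="\t", index=False)

    truth = {
        "seed": SEED,
        "responsive_peptides": list(lip_truth.responsive_peptides),
        "true_ec50_molar": lip_truth.true_ec50,
        "pocket_center": list(map(float, lip_truth.pocket_center)),
        "competition_target": comp_truth.target_protein,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    print(f"LiP table: {len(quant)} rows, {quant['modified_sequence'].nunique()} peptides")
    print(f"responsive (planted): {len(lip_truth.responsive_peptides)} at EC50 1e-06 M")
    print(f"structure: chain A, {structure.n_atoms()} atoms; pocket at {truth['pocket_center']}")
    print(f"competition: {comp['protein_id'].nunique()} proteins, target {comp_truth.target_protein}")


if __name__ == "__main__":
    main()
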