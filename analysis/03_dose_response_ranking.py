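#!/usr/bin/env python
"""Fit the 4-parameter log-logistic dose-response model to every candidate
peptide, rank by R^2, and report the top 3 with their predicted EC50s.

Reads results/inputs/lip_quant.tsv and results/candidates.txt; writes
results/fits.tsv (ranked).
"""

from pathlib import Path

from lipsite.differential import median_center
from lipsite.dose_response import fit_all, fits_to_frame, rank_peptides, select_top
from lipsite.quant_io import read_peptide_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    quant = read_peptide_report(ROOT / "inputs" / "lip_quant.tsv")
    candidates = (ROOT / "candidates.txt").read_text().split()
    centered = median_center(quant)

    fits = fit_all(centered, peptides=sorted(candidates))
    ranking = rank_peptides(fits, r2_threshold=0.9)
    frame = fits_to_frame(ranking)
    frame.to_csv(ROOT / "fits.tsv", sep="\t", index=False)

    top = select_top(ranking, k=3)
    print(f"fitted {len(fits)} candidates; {int(frame['above_threshold'].sum())} with R^2 > 0.9")
    print("top 3 by dose-response correlation:")
    for f in top.fits:
        print(f"  {f.peptide:20s} R^2={f.r_squared:.4f} EC50={f.ec50:.3g} M slope={f.slope:.2f}")


if __name__ == "__main__":
    main()
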