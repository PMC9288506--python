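# Methods

## Model and procedure

The pipeline assumes a LiP-MS dose-response design: one native lysate split
across a compound dilution series plus vehicle, identical limited
proteolysis and trypsinization per sample, and a peptide-level quantity per
(modified peptide, dose, replicate).  Binding is read out as dose-dependent
change in peptide yield; both increases and decreases are meaningful (a
binding event can shield a cleavage site or expose one).

**Normalization.**  All statistics run on log2 quantities after per-sample
(dose x replicate) median-centering across peptides.  This removes loading
and labeling offsets under the assumption that most peptides do not
respond to the compound.  Consequence: in very small tables, or tables in
which a large fraction of peptides respond, the moving median distorts the
centered values; the exact-recovery contracts of the fitter are therefore
stated on uncentered data, and centering is applied in the pipeline where
its robustness assumption (responders are a small minority) holds.

**Differential screen.**  For each of the three comparison doses (defaults
2, 20 and 100 uM — the concentrations above the compound's estimated
cellular IC50) versus vehicle: log2 fold-change of group means and a
two-sided Welch t-test per modified peptide.  Degenerate groups are handled
explicitly: both variances numerically zero gives p = 1 for equal means and
p = 0 otherwise; fewer than two replicates in a group yields a
missing-data marker that is excluded downstream.  q-values are
Benjamini-Hochberg within each comparison (a `global` scope pooling all
comparisons into one family is available; whether the original analysis
adjusted per comparison or globally is not documented, so both are
exposed).  The candidate rule is `any` by default — one comparison passing
q < 0.01 and |log2FC| > 0.46 suffices — with `all` available for the same
reason.

**Dose-response model.**  The 4-parameter log-logistic in log2 intensity:
f(d) = bottom + (top - bottom)/(1 + (EC50/d)^slope).  The vehicle point
(d = 0) is evaluated through the analytic limit f(0) = bottom rather than a
pseudo-dose, so no arbitrary constant enters.  `top - bottom` is free in
sign (direction of the LiP response); the slope is constrained to
[0.01, 10] — proteolytic dose responses have Hill-type slopes near 1, and
the upper bound keeps the optimizer out of a step-function regime that a
10-point series cannot distinguish from noise.  log10(EC50) is the free
parameter, bounded to the dose range widened by two decades on each side.

**Fitting.**  Least squares on replicate-level points (no pre-averaging:
replicate scatter counts against the fit, and R^2 is computed over
replicate points).  The search exploits that the model is linear in
(bottom, top) for fixed (log10 EC50, slope): a vectorized grid over
40 log10(EC50) values x slopes {0.25, 0.5, 1, 2, 4} with exact linear
solves, followed by a bounded trust-region polish from the best grid point
of each of 5 EC50 bands (multi-start across the dose range).  Polish
tolerances 1e-10 (relative cost), 1e-12 (step), 60 evaluations per start.
On noise-free data this recovers all four parameters to ~1e-14 relative
anywhere in the dose range; on a flat noise landscape the evaluation cap
stops a pointless plateau crawl and the fit is reported unconverged.
Fits are degenerate when the response is constant (zero total sum of
squares), when fewer than 5 distinct doses (vehicle included) have data, or
when no start converges; degenerate fits are excluded from ranking but
never raised as exceptions.

**Ranking and selection.**  Non-degenerate fits ordered by R^2 descending;
ties broken by lower EC50 (peptides nearest a binding event show the lowest
EC50s), then lexicographic sequence for full determinism.  Fits below the
R^2 threshold (default 0.9) stay in the ranking but are flagged.  The top
k = 3 peptides feed the structural stage.

**Site triangulation.**  Each top peptide is located as an exact substring
of the chosen chain's one-letter sequence (resolved residues in author
numbering order).  Isoleucine/leucine are distinct by default — MS cannot
tell them apart but the matching is against a structure, which can; an
`il_equivalent` flag folds I onto L for sequences where this matters.  An
ambiguous (multi-position) match is an error listing all positions; an
absent peptide is a non-fatal "unmapped" marker.  Atoms of the matched
residues are pooled across peptides as a union (atoms shared by overlapping
peptides counted once; a flag keeps the multiset instead, since the
original description does not say which was used), and the site is the
mass-weighted center of mass (standard atomic masses by element; geometric
weighting by flag).  Hydrogens are excluded throughout — crystal structures
rarely resolve them.  Neighbourhood: all residues with any atom within
`neighbor_radius` (default 10 A) of the CoM, nearest first.

**Competition ranking.**  Input is a long table of log2 ratios per
(protein, replicate, channel), sign convention competed-positive:
log2(vehicle enrichment / this-dose enrichment), stated here and in the
config because the published axis convention is not printed.  Proteins not
quantified in every channel of every replicate are dropped (complete-cases
rule), then per-(channel, replicate) medians are subtracted — an idempotent
step that leaves every channel's median exactly 0.  Ranking is by the
minimum across replicates of the highest-dose (800 uM) log2 fold-change;
the significance call (default threshold 2) requires all replicates by
default.

## Synthetic data: what it emulates, what it does not

The LiP generator reproduces the experiment's statistical structure: a
10-concentration series (10-fold dilutions from 2 mM, intermediates 1 mM
and 100 uM, vehicle), 3 replicates, multiplicative log-normal measurement
noise (log2-additive Gaussian with sigma = sqrt(ln(1 + CV^2))/ln 2 — the
standard behaviour of MS intensities), a dose-independent majority of
peptides, and a planted minority following the 4PL mean curve with random
response direction.  Default CV is 5%; replicate CVs of real LiP data vary
by instrument and are not documented for this design, so 5% (with tests
also probing larger values) is a generator setting, not a measured value.
Baseline log2 intensities are N(17, 1.5^2), i.e. ~10^5 raw intensity.

The companion structure is a single chain concatenating the responsive
peptides (built as ideal helical segments, centroids uniform in a 6 A ball
around the designated pocket center) plus 10 non-responsive decoy peptides
placed on a 45 A shell.  Inter-segment chain connectivity is deliberately
not physical; the construct exists so that mapping and triangulation have
an exact geometric truth.  `write_toy_structure` separately produces ideal
single-segment helix/extended chains (backbone + C-beta, consecutive
C-alpha ~3.8 A) for format round-trip and geometry tests.

The competition generator plants one target whose competition profile
rises monotonically to exactly the requested log2FC at 800 uM in every
replicate, background proteins at N(0, 0.3^2) plus a shared per-channel
bias (which median normalization must remove), and ~2% missing background
measurements to exercise the complete-cases rule.

Not emulated: raw DIA spectra, fragment-level interference, retention-time
effects, missing values in the LiP table, correlated noise between
neighbouring peptides, or multi-chain/hexamer structures.  Passing tests
therefore demonstrate the correctness of the statistics, the fitter, the
geometry and the plumbing — not robustness to every pathology of real
acquisitions.

## Problem sizes

The recovery analyses run at the study scale: 500 peptides with 10
responsive for screening/fitting, 1000 pure-noise peptides for the
specificity rate, 20 independent seeds for end-to-end site recovery, 200
random p-vectors (length <= 50) for the BH oracle, 1000 random atom sets
for the CoM oracle, and 300 proteins x 2 replicates for the competition
experiment.

## Known limitations

- Exact substring matching cannot place peptides spanning unresolved
  residues mid-peptide or carrying sequence variants; such peptides come
  back "unmapped" and are simply dropped from the pooled atom set.
- The EC50 of a LiP peptide is a proxy, not a binding constant; the
  ranking uses it only as a tie-break.
- The full LiP-Quant composite score (proteome-wide weighting across
  proteins) is out of scope; ranking here is within one protein by R^2
  alone, which is the dominant term of that score.
- q-value scope and candidate-combination rule are genuinely underdetermined
  by the published description; the defaults (per-comparison BH, `any`
  rule) are choices, exposed in `PipelineConfig`.
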