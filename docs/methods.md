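# Methods

`granulescope` implements the quantitative analysis chain used to study
polyphosphate (polyP) granule organization in *Pseudomonas aeruginosa*: a
spectral-counting proteomic screen for granule-associated proteins, long-axis
statistics of fluorescent foci in segmented cells, and TEM granule
morphometrics.  Raw microscopy and mass-spectrometry data are upstream of
this package; it consumes their tabular outputs, and ships seeded synthetic
generators that emulate those tables with known ground truth.

## Proteomic enrichment screen

A protein's abundance in one mass-spectrometry sample is estimated by
spectral counting: its peptide-spectrum-match (PSM) total divided by the
sample's total PSM count, expressed in parts per million.  By construction
ppm sums to 10⁶ within every (replicate, fraction) sample.  Enrichment is
the ratio of the replicate-averaged pellet abundance to the lysate
abundance; proteins detected in only one fraction are reported as
`pellet_only`/`lysate_only` statuses rather than given a pseudocounted
ratio.  Averaging treats a protein undetected in a replicate as 0 ppm by
default (`zero_fill="zero"`): absence under deep sampling is evidence of low
abundance, not missingness.  The `skip` mode (mean over detected replicates
only) is available since upstream conventions vary.

Candidates are proteins in the abundant-and-enriched quadrant: enrichment
≥ 8 and pellet abundance ≥ 5,000 ppm, both cutoffs inclusive so the printed
cutoff values are themselves in-quadrant.  Ribosomal proteins are flagged
and removed from candidate lists (they extract readily under the screen's
salt conditions) while remaining in output tables.  A separate predicate
marks candidates with net charge above +5 at pH 7, since polyP is a dense
polyanion and structural granule proteins are expected to be polycationic.

Net charge is a Henderson–Hasselbalch sum over ionizable groups (N/C
termini, K, R, H, D, E, C, Y) with an EMBOSS-style pKa table; each positive
group contributes 1/(1+10^(pH−pKa)) and each negative group
−1/(1+10^(pKa−pH)).  Because published "calculated charge" values rarely
state their method, a simple (K+R)−(D+E) count is provided as an
alternative; the two can differ by several units for large proteins, and no
attempt is made to reproduce any specific database's values.

### Detection threshold calibration

With a true enrichment of 8-fold and the decision cutoff also at 8, an
(asymptotically unbiased) enrichment estimate sits exactly on the decision
boundary, so each truly enriched protein is called with probability ≈ 0.5
regardless of sequencing depth.  The recovery experiments in
`granulescope.validation` therefore use a calibrated detection threshold of
4.0 — the geometric midpoint between the null ratio (~1) and the true fold
(8), fixed once by an oracle simulation — while the screen's reporting
default remains 8.  At depth 20,000 the null ratios of abundant proteins
have a relative sd of a few percent, so the two populations are separated
by dozens of standard errors and the choice of midpoint is not delicate.

## Foci statistics

All analysis is one-dimensional along the cell's long axis; spot detection
and cell segmentation are upstream.  Focus positions are normalized by cell
length to [0, 1].

**Flipping.**  Before pooling cells into histograms, a cell whose foci all
lie in the left half (< 0.5) is mirrored (r → 1 − r); cells with foci in
both halves, or a focus exactly at mid-cell, are unchanged.  Demograph rows
(per-cell intensity profiles linearly interpolated at segment centers onto
50 bins and divided by their maximum, rows sorted by cell length) are
mirrored when their maximal bins center left of the matrix midline, so the
brightest segment appears on the right.  The tie rule had to be chosen
carefully: interpolation clamping creates exact plateaus, and a naive
"first argmax" rule makes the flip decision depend on the input
orientation.  The implemented rule — flip iff the mean maximal-bin index is
left of center, with an exactly balanced tie broken toward the
lexicographically larger orientation — is mirror-antisymmetric, so
reversing the input segments always yields the identical output row, and a
constant profile is never flipped.

**Count fractions.**  The fractions of 1-, 2- and >2-focus cells are taken
over cells with at least one detected focus: DAPI labeling of live cells is
not perfectly efficient, so a dark cell cannot be distinguished from an
unlabeled one.  The separate `fraction_cells_exceeding` (fraction of cells
with more than a threshold number of foci) deliberately includes zero-count
cells, matching its use for chromosome-origin counting where zero is a real
observation.

**Spacing deviation.**  For a cell with n ordered relative positions x₍ₖ₎,
D = (1/n) Σ |x₍ₖ₎ − idealₖ|.  Two ideal models are shipped: `equal_gap`
(idealₖ = k/(n+1); equal gaps including the poles — 1/3, 2/3 for n = 2) and
`quarter` (idealₖ = (2k−1)/2n; segment midpoints — 1/4, 3/4 for n = 2).
Neither is claimed to be the biological truth; both ideal sets are
symmetric about mid-cell, making D invariant under axis mirroring.

**Two-channel matching.**  Foci of two channels in the same cell are paired
by minimum-cost one-to-one assignment on |posA − posB| (Hungarian
algorithm), with pairs farther apart than `max_dist_frac` (default 0.1 of
cell length) forbidden via a large penalty; this maximizes the number of
feasible pairs first and total proximity second, and is verified against
exhaustive enumeration in the tests.  Unmatched foci are reported — they
correspond to spots detected in one channel only.  Co-localization is then
the Pearson correlation of the pooled matched positions (Spearman
available).  The original study's exact pairing procedure is not published
in its main text, so this reconstruction is configurable.

## TEM morphometrics

Granule volumes come from manually measured diameters under a spherical
model, V = πd³/6; the geometry is an assumption recorded in output
metadata.  Per-cell summaries are count, largest-granule volume and total
granular volume; zero-granule cells enter count distributions but not
volume distributions.  No minimum-size ("satellite" granule) filter is
applied by default, though one is available.

ECDFs are computed on the sorted sample and the confidence band is the
pointwise percentile interval of ECDFs over `n_boot = 1000` seeded
resamples (95% by default).  The band is pointwise, not simultaneous:
joint coverage over the whole curve is lower than the nominal level, which
is why coverage is validated at a single (median) grid point.

Group comparisons follow standard nonparametric practice: two-sided
Mann-Whitney for two groups; Kruskal-Wallis followed by Dunn's post hoc
pairwise z-tests (joint-rank mean differences with tie-corrected variance)
and Bonferroni adjustment for three or more.  Dunn's test is implemented
in-package (no installed library provides it) and is unit-tested against
hand-computed rank arithmetic.  Degenerate all-tied input yields p = 1
with a warning rather than an error.

## Synthetic data

The generators emulate the study's three input kinds, with defaults chosen
as the reference conditions of the validation experiments:

* **PSM tables** — true lysate mass fractions are lognormal (σ = 1.5,
  normalized), a designated enriched subset has pellet fraction exactly
  `enrichment_fold` (default 8) times its lysate fraction, and the
  remaining proteins are scaled by a common factor so pellet fractions sum
  to 1 (their true ratio is a constant slightly below 1).  Each sample is
  a multinomial draw of `depth` (default 20,000) PSMs; three replicates.
  `draw_baseline_ppm` exposes the seed-deterministic baseline so callers
  can plant enriched proteins above the abundance cutoff.
* **Foci cells** — lengths lognormal (median 2.5 µm, σ = 0.2, typical of
  starved *P. aeruginosa*); true focus counts 0–4 with weights
  (0.05, 0.30, 0.45, 0.15, 0.05) peaking at two foci as in starved
  wild-type cells; placements: `even_equal_gap`, `even_quarter`, `uniform`
  (order statistics of U(0,1)), and `fused` (even positions with one
  random adjacent pair merged at its unweighted midpoint with probability
  `fuse_prob`).  Observed positions add Gaussian noise (default sd 2% of
  cell length, clipped to the cell) and are dropped independently per
  channel with probability 0.1, producing realistic unmatched foci; the
  noise and dropout defaults are calibrations, not measured values, since
  the study reports no quantitative estimates.  Zero-foci cells are
  retained in the output (downstream fractions exclude them).
* **TEM tables** — granule counts Poisson(3), diameters lognormal (median
  ≈ 148 nm, σ = 0.3, matching the ~150 nm scale of polyP granules);
  fusion applies Poisson-many pairwise events per cell, each replacing two
  granules by one of summed volume, d = (dᵢ³+dⱼ³)^(1/3), floored so a
  non-empty cell keeps at least one granule.  Untouched diameters are kept
  bitwise, so per-cell total volume is conserved to machine precision and
  the largest granule never shrinks — reproducing the "fewer, larger
  granules with unchanged total volume" contrast.

All generators derive independent substreams from a single integer seed via
`numpy.random.SeedSequence`, and are bit-reproducible given (config, seed).

What the generators do **not** model: pixel-level images or point-spread
functions, 2-D/3-D cell geometry, intensity-weighted fusion positions,
cell-cycle structure, or protein-specific detectability (trypsin bias,
protein length).  Passing validation therefore shows the statistics behave
correctly on data satisfying the stated generative assumptions, not that
the upstream segmentation/detection steps are accurate on real images.

## Validation experiments and problem sizes

`granulescope.validation` fixes the reference conditions: screen recovery
with 10 planted 8-fold proteins among 1,000 at depth 20,000 × 3 replicates;
spacing discrimination with 500 two-focus cells per placement at 2% noise;
matching agreement on 1,000 random cells with ≤ 4 foci per channel; fusion
contrast with 300 cells per group at 1.5 fusion events/cell; ECDF band
coverage over 200 U(0,1) trials of n = 100.  These sizes give stable
results in seconds on one CPU while keeping every check far from its
decision boundary (e.g. the spacing Mann-Whitney p is ~10⁻¹⁶⁰ against a
10⁻⁶ requirement).  One caveat: the fused and unfused groups have
identical per-cell total-volume distributions by construction, so that
comparison's p-value is a draw from the null — "no significant difference"
holds for ~95% of seeds by definition of the test level.

## Pipeline and I/O

All tables are tab-delimited UTF-8 text with a header row; configs and
reports are JSON.  `validate_table` checks required columns, types and row
invariants, failing with the file, row and column named, and warning on
unknown columns.  `run_pipeline` executes stages in dependency order,
validates all external inputs before writing anything, and emits a run
report with the seed, a config echo, per-stage row counts, filter tallies
(rows_in = rows_out + rows_filtered) and SHA-256 digests of every output
file; identical (config, seed, inputs) give byte-identical outputs.  The
`granulescope` CLI is a thin wrapper over the same entry point.
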