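# granulescope

Quantitative analysis of bacterial polyphosphate (polyP) granule
organization, built around three data kinds from studies of granule spacing
in *Pseudomonas aeruginosa*:

* **Proteomic enrichment screen** — label-free spectral counting on
  pellet/lysate PSM tables: ppm abundances, replicate averaging,
  pellet:lysate enrichment, Henderson–Hasselbalch net charge at pH 7,
  ribosomal exclusion, and quadrant classification of candidate
  granule-associated proteins (enrichment ≥ 8, abundance ≥ 5,000 ppm,
  charge > +5).
* **Fluorescence-foci statistics** — long-axis position normalization,
  flipping conventions, demographs, 1/2/>2-focus fractions, a spacing
  deviation statistic D = (1/n) Σ|x₍ₖ₎ − idealₖ| against even-placement
  models, and optimal two-channel focus matching with position correlation.
* **TEM morphometrics** — spherical granule volumes (V = πd³/6), per-cell
  count/largest/total-volume summaries, bootstrap ECDF confidence bands,
  and Mann-Whitney / Kruskal-Wallis + Dunn-Bonferroni group comparisons.

Cell segmentation, spot detection and mass-spectrometry acquisition are
upstream: the package consumes their tabular outputs.  A seeded
synthetic-data module generates all three input kinds with ground truth
(multinomial PSM sampling with planted enriched proteins; cells with 1–4
foci under even / uniform / fused placement, localization noise and
per-channel dropout; Poisson granule counts with lognormal diameters and a
volume-conserving fusion transformation), so every downstream statistic can
be validated against known truth.  See `docs/methods.md` for the models and
conventions.

## Worked example

Simulate a wild-type-like and a fusion-prone TEM group, then compare them:

```sh
granulescope simulate tem --out-dir sim --seed 3
granulescope tem --granules sim/granules.tsv --cells sim/tem_cells.tsv \
    --n-boot 1000 --seed 3 --out tem_out
```

or, running the analysis chain from Python:

```python
>>> from granulescope.validation import fusion_contrast
>>> out = fusion_contrast(seed=20220601)
>>> print(f"median granules/cell: wt={out['count_median_wt']:.0f}, "
...       f"fused={out['count_median_fused']:.0f} (p={out['count_p']:.2e})")
median granules/cell: wt=3, fused=1 (p=1.38e-15)
>>> print(f"largest-granule volume p={out['largest_volume_p']:.2e}, "
...       f"total-volume p={out['total_volume_p']:.2f}")
largest-granule volume p=2.77e-04, total-volume p=0.25
```

Fusion leaves each cell's total granular volume untouched (conserved to
~10⁻¹⁵ relative error) but redistributes it into fewer, larger granules:
counts drop and the largest-granule volume grows, both highly significant,
while the total-volume comparison stays at the null — the signature that
distinguishes a granule-fusion phenotype from a biogenesis defect.

The numbered scripts under `analysis/` run the full synthetic study:
`01_simulate.py` generates all input tables, `02_screen.py` recovers the 10
planted 8-fold-enriched proteins (sensitivity 1.00, FDP 0.00 at the
calibrated detection threshold), `03_foci.py` separates even from uniform
focus placement (mean D 0.016 vs 0.202, Mann-Whitney p ≈ 10⁻¹⁶²) and
measures cross-channel position correlation (r ≈ 0.99), and `04_tem.py`
produces the fusion contrast above.  Outputs land under `results/`.

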