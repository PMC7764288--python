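# ctcpheno

Phenotyping of circulating tumor cells (CTCs) on immunofluorescence
cytospin preparations, from pixels to survival curves.

CTCs found in the peripheral blood of metastatic breast cancer patients —
alone or in multicellular clusters — carry prognostic information, and
their epithelial/mesenchymal (EMT) state and PD-L1 expression identify
subpopulations with distinct clinical behavior.  `ctcpheno` implements
the full quantitative workflow for this kind of study as a tested Python
library with a thin command-line interface:

1. **Quantification** — per-cell *corrected total cell fluorescence* on
   multichannel images (DAPI, pan-keratins, vimentin, PD-L1, plus a
   binary CD45 positivity mask):

   `CTCF = integrated density − cell area × mean background`

   Nuclei are segmented from DAPI (Otsu + watershed), grown into
   whole-cell regions, and the slide background is estimated outside all
   cells.
2. **Calibration** — classification thresholds are anchored to two
   reference breast-cancer cell lines measured with the same protocol:
   MCF-7 (epithelial-like; vim/ker ratio range 0.01–0.28, PD-L1 CTCF
   10–40) and MDA-MB-231 (mesenchymal-like; vim/ker 0.88–22.5, PD-L1
   60–350).  These published ranges ship as the default calibration, or
   can be re-fitted from ≥ 100 measured reference cells per line.
3. **Classification** — a CTC is DAPI⁺/keratins⁺/CD45⁻; its EMT state is
   epithelial (eCTC) when vim/ker ≤ 0.88 and mesenchymal (mCTC) above;
   PD-L1 is negative/low up to CTCF 40 and positive above.  Touching
   CTCs (≥ 2) form clusters; per patient and timepoint the counts of
   every subpopulation (single/cluster × e/m × PD-L1) and their presence
   flags are aggregated, including mesenchymal predominance (mCTCs ≥ 50%
   of CTCs) and low/high quartile strata of the vim/ker distribution.
4. **Cohort statistics** — Wilcoxon signed-rank (paired day-1 vs day-8
   counts), chi-square contingency tests, Kaplan–Meier estimation with
   Greenwood variance and median CIs, log-rank comparisons, and
   univariate/multivariate Cox proportional-hazards regression (Breslow
   ties by default, Efron optional).
5. **Synthetic data** — a generator that renders cytospin fields with
   known per-cell intensities (disk nucleus + cytoplasm, blur/Poisson/
   Gaussian noise), emits measurement tables directly, and simulates
   patient cohorts from a proportional-hazards model with known effects,
   so every stage is validated against analytic ground truth.

## Worked example

`examples/03_survival_analysis.py` simulates 300 patients in which the
presence of cluster mCTCs multiplies the death hazard by 5.145, then
recovers the effect:

```
median OS, cluster-mCTC positive: 2.7 months (95% CI 2.0-3.5)
median OS, cluster-mCTC negative: 11.2 months (95% CI 9.1-13.7)
log-rank: chi2 = 98.5, p = 3.21e-23
Cox HR = 4.379 (95% CI 3.197-5.997), p = 3.44e-20  [truth: 5.145]
```

The carriers' median survival is four times shorter, the log-rank test
rejects decisively, and the Cox confidence interval covers the
generating hazard ratio.  The other examples cover image quantification
(`01`, CTCF exact to ~1e-12 on noiseless scenes), calibration +
classification (`02`), and the end-to-end pipeline (`04`).

The same workflow runs from the shell:

```bash
ctcpheno synth scene --out scene/ --seed 3
ctcpheno quantify --in scene/scene.ome.tiff --out cells.csv
ctcpheno classify --cells cells.csv --out-prefix run1
ctcpheno run-all --out demo_run        # full synthetic pipeline
```

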