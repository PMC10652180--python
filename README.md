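# lacumorph

Osteocyte lacunar morphometry from 3D micro-CT volumes.

Osteocytes live in micrometer-scale voids (lacunae) inside mineralized
bone and remodel their own walls; lacunar size and shape therefore carry
information about osteocyte function in conditions like type 2 diabetes
with microvascular complications. `lacumorph` is the analysis pipeline a
bone-biopsy cohort study needs to extract that information:

* **segmentation** — per-sample Otsu threshold, image inversion,
  26-connected void labeling, classification into noise specks, lacunae
  (default 50–2000 um^3) and large voids (canals, marrow);
* **morphometry** — per lacuna: volume `Lc.V`, mesh surface area `Lc.SA`,
  sphericity `Lc.Sr = pi^(1/3)(6V)^(2/3)/SA`, covariance-fit semi-axes
  `a >= b >= c`, oblateness `Lc.O = 2(b-c)/(a-c) - 1`; per sample: BV/TV,
  cortical thickness (largest-inscribed-sphere), cortical porosity,
  lacunar count and density `Lc.N/BV`;
* **regional split** — Euclidean distance from the bone surface (lacunae
  refilled first), peripheral < 20 um vs central;
* **cohort statistics** — age/sex-adjusted OLS group and exposure models
  (log10 by a Shapiro–Wilk rule), paired Wilcoxon central-vs-peripheral
  tests, median(IQR)/mean(SD) summary tables;
* **synthetic phantoms and cohorts** — ellipsoidal lacunae with exact
  analytic/quadrature ground truth in cortical-slab and trabecular
  random-field bone, rendered with PSF blur and noise, plus a 35-subject
  cohort generator embedding configurable group, exposure and regional
  effects.

Since biopsy scans of this kind are not publicly available, the phantom
generator is first-class: every stage is validated against exact ground
truth, and the whole pipeline runs end to end on synthetic cohorts.
See `docs/methods.md` for the models, conventions and their limits.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
35-subject cohort (20 T2D, 15 T2D+MVD; seed 20230):

```bash
python analysis/01_simulate_cohort.py   # render 70 phantom volumes
python analysis/02_measure_lacunae.py   # segment + measure everything
python analysis/03_cohort_stats.py      # adjusted models + paired tests
python analysis/04_effect_recovery.py   # simulation study of the stats layer
```

Step 02 prints, for this seed:

```
measured 590 lacunae in 70 samples
cortical:   median Lc.V 129 um^3, Lc.N/BV 26134 /mm^3, Ct.Po 6.61 %
trabecular: median Lc.V 100 um^3, Lc.N/BV 10874 /mm^3, BV/TV 15.1 %
```

i.e. the segmentation recovers the embedded densities and the 15.1%
trabecular bone volume fraction; measured volumes sit below the embedded
medians because partial-volume blur erodes voids only a few voxels thick
(quantified in `docs/methods.md`). Step 03 then shows the statistical
texture such a study lives with:

```
cort_lc_v_um3          beta +9.409  p 0.29    (group model, n=35)
cortical   lc_v_um3    central 151 vs peripheral 122   p 0.00684 *
cortical   lc_sr       central 0.926 vs peripheral 0.941  p 0.000563 *
```

a single 35-subject cohort is underpowered for a 7.7% group effect (the
coefficient is positive but p = 0.29), while the larger central-vs-
peripheral contrast is clearly significant. Step 04 confirms the layer is
calibrated and unbiased where the single cohort is merely noisy:

```
group effect: mean beta 0.0324 (target 0.0322) -> 7.74% (embedded 7.7%)
HbA1c slope: 82.5 (target 87)
type-I error: regression 5.6%, Wilcoxon 4.1% (nominal 5%)
```

A `lacumorph` CLI (`simulate`, `segment`, `morph`, `regions`, `stats`,
`run-all`) wraps the same library for shell use; `run-all` executes the
whole pipeline from a YAML config with one seed and writes byte-identical
tables on rerun.

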