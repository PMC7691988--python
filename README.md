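# nucyto

Quantification of nuclear:cytoplasmic protein partitioning in
micropatterned single-cell fluorescence images, with a ground-truth
simulator for validating every stage of the analysis.

## The problem

Cells confined on adhesive fibronectin micropatterns adopt a prescribed
geometry (squares, 1:5 or 1:8 rectangles, areas 500–1800 µm²), which
lets one ask how cell *shape* — independently of spreading area —
shifts the subcellular localisation of shuttling proteins such as
methyltransferases (SMYD3, SETDB1) or the YAP/TAZ coactivators. The
readout is the **nuclear:cytoplasmic ratio**

```
nc_ratio = ⟨I_Nuc⟩ / ⟨I_Cyto⟩
```

the mean background-subtracted marker intensity per nuclear pixel
divided by the mean per cytoplasmic pixel. nucyto implements the full
chain needed to measure it reliably, plus the companion readouts used
in such studies:

- **simulate** — renders micropatterned cells (pattern / DNA / marker /
  actin channels) with a known partition coefficient ρ, shot + read
  noise, optional blur and 5-plane confocal stacks, and two-pool FRAP
  traces; ground truth for every cell.
- **segment** — minimum cross-entropy (Li) thresholding, written both
  as the iterative fixed point and as an exhaustive brute-force scan
  that serves as its oracle; nucleus/cell/cytoplasm compartment masks
  with enforced containment invariants; moment-ellipse shape metrics.
- **quantify** — the N/C ratio statistic, z-stack sum projection, and
  compartment-resolved Pearson colocalisation
  ρ = cov(I_a, I_b)/(σ_a·σ_b) over nucleus and cytoplasm separately.
- **kinetics** — single-exponential FRAP fits; after whole-compartment
  bleaching the nuclear signal relaxes with rate k = k_in + k_out of
  the first-order exchange model, so the fitted rate reads out
  transport directly.
- **stats** — the adaptive test-selection procedure common in this
  field (t-test / ANOVA + Tukey–Kramer for n ≥ 30; Anderson–Darling
  normality screen below that, switching to Wilcoxon rank-sum /
  Kruskal–Wallis + Dunn–Šidák; Levene gate diverting ANOVA to
  Kruskal–Wallis under unequal variances), with full branch provenance.
- **pipeline / CLI** — batch runs from a YAML config with per-cell
  rejection logging and bit-for-bit reproducibility.

## Worked example

```python
from nucyto import RunConfig, run_pipeline
from nucyto.pipeline import _format_report

config = RunConfig(
    scenario={
        "geometries": {
            "square": {"shape": "square", "area": 1200.0},
            "rect5": {"shape": "rectangle", "area": 1200.0, "aspect_ratio": 5.0},
        },
        "n_per_geometry": 50,
        "rho_by_geometry": {"square": 1.3, "rect5": 1.0},
    },
    seed=1,
)
result = run_pipeline(config)
print(_format_report(result))
```

prints

```
nucyto pipeline report
======================

cells measured: 100
cells rejected: 0

geometry contrast (medians):
  rect5: median = 1.0001 (n = 50)
  square: median = 1.3009 (n = 50)
  rect5 vs square: -23.1% (of square median)
  test: student-t (posthoc: None), p = 2.1e-182, alpha = 0.05

regression of metric vs aspect ratio:
  slope = -0.07557, intercept = 1.376, r = -1.000, p = 2.1e-182, n = 100

note: cells from all repeats pooled before testing; no hierarchical correction for replicate structure
```

The scenario encodes stronger nuclear partitioning on squares
(ρ = 1.3) than on rectangles (ρ = 1.0); the pipeline segments each
simulated cell from its DNA and actin channels, recovers both medians
to within a fraction of a percent, picks the t-test branch (n ≥ 30 per
group) and reports the negative slope of nc_ratio against cell aspect
ratio.

The same run is available from the shell:

```sh
nucyto all --config scenario.yaml --seed 1 --out results/
```

with subcommands `simulate`, `measure`, `frap`, `stats` for the
individual stages.

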