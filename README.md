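# contrastsweep

Sensitivity analysis of MRI auto-contouring algorithms across synthetic
contrast weightings.

## The problem

Deep-learning contouring models for radiotherapy planning are usually
trained and validated on a single MRI contrast weighting (say, "T2-weighted"
images), yet two T2-weighted scans acquired with different repetition time
(TR) and echo time (TE) can look quite different: TR controls how much T1
recovery is expressed, TE controls how much T2 decay is expressed. A model
that looks excellent at its training contrast may silently degrade at a
neighbouring (TR, TE) combination — a serious concern for organs at risk
such as the parotid and submandibular glands, whose sparing determines
post-radiotherapy salivary function.

Quantitative relaxometry makes this testable without re-scanning: from
voxelwise T1, T2 and proton-density (PD) maps one can *synthesize* an
inherently co-registered contrast-weighted image at any (TR, TE), then ask
how a fixed segmenter's output drifts across the whole acquisition-parameter
plane. `contrastsweep` implements that methodology end to end:

1. **Synthesis** — spin-echo signal model
   `S = g · B1 · PD · (1 − e^(−TR/T1)) · e^(−TE/T2)`
   (inversion-recovery variant `1 − 2e^(−TI/T1) + e^(−TR/T1)` available),
2. **Ground truth** — STAPLE expectation-maximization fusion of several
   raters' masks into a consensus with per-rater sensitivity/specificity,
3. **Metrics** — Dice similarity coefficient (DSC) and 95th-percentile
   Hausdorff distance (HD95, mm, pooled symmetric convention) in physical
   spacing,
4. **The sweep** — a TR × TE grid (default 18 TR × 16 TE values)
   partitioned into contrast regions: T1-weighted (TR < 1000 ms, TE ≤ 40 ms),
   T2-weighted (TR ≥ 1000 ms, TE > 40 ms), PD-weighted (TR ≥ 1000 ms,
   TE ≤ 40 ms); the mixed region (TR < 1000 ms, TE > 40 ms) is excluded by
   default, leaving 216 evaluated acquisitions (72 per region),
5. **Reporting** — per-structure × region mean/median/min/max tables,
   relative (ΔTR, ΔTE) offsets from a training-anchor acquisition
   (default TR = 1535 ms, TE = 212 ms), interobserver-variability (IOV)
   exceedance fractions with published salivary-gland cutoffs, and heatmaps.

Any segmenter that maps `(image, spacing) → label volume` plugs in. A
built-in digital head phantom (bilateral parotid- and submandibular-like
ellipsoids with literature-plausible 3 T tissue values, simulated raters,
optional B1 bias field) makes the whole pipeline runnable with no data
download, and an anchor-calibrated intensity-window reference segmenter
provides a deterministic stand-in whose performance intentionally depends
on contrast.

## Worked example

Run the end-to-end demo on a compact phantom (64 × 64 × 16 voxels at
1.5 × 1.5 × 5 mm):

```bash
cat > small.yaml <<'YAML'
seed: 1
phantom:
  shape: [64, 64, 16]
  spacing: [1.5, 1.5, 5.0]
YAML
contrastsweep demo --config small.yaml --out runs/demo --seed 1
```

which prints

```
outputs in runs/demo
  parotid_l: DSC exceedance 31%, HD95 exceedance 33%
  parotid_r: DSC exceedance 32%, HD95 exceedance 33%
  submandibular_l: DSC exceedance 27%, HD95 exceedance 27%
  submandibular_r: DSC exceedance 32%, HD95 exceedance 34%
```

i.e. for the left parotid, 31 % of the 216 (TR, TE) combinations score a
DSC at or above the 0.83 human-interobserver cutoff. `runs/demo` then
contains the tidy per-grid-point table (`sweep.csv`), the region summary,
the exceedance table, STAPLE rater-performance estimates, DSC/HD95 heatmaps
and a provenance record. The region summary for the left parotid:

```
structure region  dsc_mean  dsc_min  dsc_max  hd95_median
parotid_l    PDW     0.223      0.0    0.986        7.649
parotid_l    T1W     0.507      0.0    0.986        0.750
parotid_l    T2W     0.323      0.0    0.986       14.495
```

The reference segmenter is calibrated at the T2-weighted anchor, so it is
near-perfect at nearby grid points (DSC max ≈ 0.99) and collapses far from
them; the PD-weighted region — the contrast most dissimilar to the anchor —
has the lowest mean DSC, while parts of the T1-weighted region remain
competitive. That is precisely the sensitivity structure the sweep is
designed to expose; the absolute numbers describe the toy segmenter on the
phantom, not any clinical model.

### Library use

```python
from contrastsweep import (AcquisitionParams, SweepGrid, run_sweep,
                           synthesize_image)
from contrastsweep.phantom import PhantomSpec, build_phantom

maps, labels = build_phantom(PhantomSpec(), seed=0)
image = synthesize_image(maps, AcquisitionParams(tr=1535, te=212))
records = run_sweep(maps, my_segmenter, SweepGrid(),
                    ground_truth={"parotid_l": labels == 1},
                    structure_labels={"parotid_l": 1})
```

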