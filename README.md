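# axomito

Quantification of mitochondrial dynamics along axons in timelapse
fluorescence microscopy.

Embryonic sensory axons respond to neurotrophins (NGF, BDNF, NT3) with a
burst of mitochondrial fission followed by a new steady state of shorter,
denser mitochondria — a process coupled to Drp1 activity, transient axonal
actin patches, organelle transport, and ultimately collateral branching.
`axomito` re-implements the quantification machinery behind that kind of
study as a reusable, tested pipeline: it converts annotated multi-channel
stacks of quasi-1D axons into calibrated arc-length intensity profiles
(kymographs), and from those calls fission/fusion events, classifies
transport, measures morphometry, scores actin-patch and Drp1-punctum
colocalization, and quantifies immunofluorescence and FRAP recovery.
A stochastic synthetic-axon simulator with exact ground truth makes every
stage testable offline.

## The core quantities

* **Fission / fusion calling.** A completed fission requires the
  intensity in the gap between the two emergent mitochondria to fall to
  the background of mitochondria-free axon *and* an edge-to-edge
  separation > 0.6 μm (5 pixels at 0.12 μm/pixel); transient
  constrictions that re-close are not events.  Fusion requires a uniform
  merged profile, additive length (the fused length equals the sum of the
  two parents), and redistribution of intensity when the parents differed.
  Rates are reported as % of mitochondria participating per 10 min.
* **Transport.** Tracks are stalled, oscillating (< 1 μm excursions), or
  transported (> 1 μm).  Transported tracks decompose into *runs* —
  continuous bouts of movement terminated by pauses ≥ 6 s — with summed
  run length regardless of direction switches, per-bout velocities, and
  the fraction of runs containing ≥ 1 switch.
* **Random-overlap probability.** For each fission event, with
  mitochondrion length *A* and summed length *B* of the actin patches on
  it at the time of fission, *C = B/A* is the chance a uniformly random
  site would overlap a patch; the product *C₁·C₂·…·Cₙ* over independent
  events (accumulated in log space) estimates the probability that every
  observed site-patch colocalization arose by chance.
* **Morphometry.** Mitochondrion length (segmented line end-to-end, with
  spatially overlapping mitochondria flagged by their additive signal and
  excluded from length statistics), density per 10 μm, the length ×
  density "mass" index, branches (> 10 μm projections) per 100 μm, and
  distal-50 μm sampling excluding the growth cone.
* **Fluorescence.** Total integrated intensity = ROI area ×
  background-subtracted mean; FRAP recovery = 100·(Iₜ − I₀)/(I_pre − I₀),
  including only axons bleached by ≥ 90 %.

## Worked example

The package bundles a reference dataset of 20 fission events (mitochondrion
length and summed actin-patch length at the time of fission).  Writing it to
CSV and running the statistic:

```python
from axomito.datasets import fission_overlap_dataset
fission_overlap_dataset().to_csv("table.csv", index=False)
```

```
$ axomito overlap-stat table.csv
{
 "n": 20,
 "mean_mito_length_um": 8.318000000000001,
 "sem_mito_length_um": 0.8154619614220616,
 "mean_patch_length_um": 0.8309999999999998,
 "sem_patch_length_um": 0.15537882399918085,
 "product_full": 2.337069451365367e-21,
 "product_rounded_2dp": 1.752827645657094e-21,
 "log10_full": -20.631328381361918,
 "log10_rounded_2dp": -20.75626078568603
}
```

Mitochondria that fissioned averaged 8.3 ± 0.8 μm (mean ± SEM) with
0.83 ± 0.16 μm of actin patch on them; the chance that all 20 observed
site-patch overlaps were coincidental is ~10⁻²¹ — far below any plausible
threshold, supporting a mechanistic link between patches and fission sites.
`product_rounded_2dp` multiplies the proportions after rounding each to
two decimals (the dialect used when proportions are tabulated), while
`product_full` keeps full precision; both are reported.

Simulating an axon and analyzing it end-to-end:

```
$ axomito simulate --seed 5 --channels mito,actin --out fixture/
wrote 5 files to fixture/: 1 fission, 0 fusion events
$ axomito analyze manifest.yaml     # points at the fixture stacks
analyzed 1 axons (0 failed); outputs in out/
```

Other verbs: `axomito frap` (recovery table from a trace CSV) and
`axomito compare` (normality-routed group comparison: Welch t /
Mann-Whitney for two groups, ANOVA + Bonferroni / Kruskal-Wallis + Dunn's
for more).

## Layout

| module | contents |
| --- | --- |
| `axomito.synthetic` | stochastic simulator + PSF/noise renderer + fixture I/O |
| `axomito.kymo` | axon paths, profile extraction, segmentation, tracking, morphometry |
| `axomito.events` | fission/fusion criteria, event rates, post-fission transport |
| `axomito.motility` | stalled/oscillating/transported classes, run decomposition |
| `axomito.patches` | actin patches, Drp1 puncta, overlap table, random-overlap probability |
| `axomito.fluor` | integrated intensity, FRAP recovery |
| `axomito.stats` | normality-routed comparisons, Dunn's post-hoc |
| `axomito.pipeline` / `axomito.cli` | batch orchestration and the command line |

See `docs/methods.md` for the model, parameter and design details.
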