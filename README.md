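# gelquant

Quantitative analysis of tumor-cell migration, invasion and collagen
architecture in 3D gels.

When breast-cancer cells (e.g. MDA-MB-231) are embedded in type-I
collagen of increasing concentration, they can switch from elongated,
protease-dependent *mesenchymal* migration to rounded, bleb-driven
*amoeboid* migration (the mesenchymal-to-amoeboid transition, MAT).
Detecting that switch quantitatively requires a chain of measurements:
single-cell migration statistics from time-lapse tracking, structural
metrics of the collagen network from second-harmonic-generation (SHG)
images, invasion-depth profiles through the gel, 3D cell morphometry,
and simple assay percentages.  `gelquant` implements that chain as a
tested library, with synthetic-data generators providing ground truth
for every stage, so the whole pipeline is verifiable without any
microscopy data.

## What it computes

**Migration statistics** (`gelquant.trajectory_metrics`) — for each
tracked cell sampled at frame interval Δt:

- mean instantaneous speed, ⟨|r(t+Δt) − r(t)|⟩ / Δt (μm/min);
- static classification: total path length < 1.5 cell diameters
  (75 μm for a 50 μm cell) over the acquisition;
- the anomalous-diffusion exponent α, the least-squares slope of
  log MSD(τ) vs log τ, where MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ is the
  time-averaged mean-squared displacement (α = 1 Brownian, α < 1
  subdiffusive/confined, α = 2 ballistic);
- persistence, net displacement ÷ total path length ∈ [0, 1];

plus per-condition cohort summaries (percent static, mean speed, mean
α, percent persistence).  Tracker exports are read from plain CSV or
TrackMate-style XML.

**Collagen architecture** (`gelquant.collagen_structure`) — from 2D
SHG-like images: batch-consistent binarization, sampled skeleton fiber
lengths, the free-space length Lf (side of the largest fiber-free
square, exact or Monte-Carlo), FFT anisotropy (power-spectrum second
moments → ellipse axis ratio and fiber orientation), pore/fiber size
from the radial power profile, and the SHG-positive pixel fraction.

**Morphometry** (`gelquant.morphometry`) — two-channel 3D stacks are
segmented by hierarchical intensity k-means (3 classes, minimum region
size), hole-filled and unioned into a cell mask; volume and the
longitudinal/transverse axes (3D Feret diameter and the widest caliper
perpendicular to it) are measured in μm.

**Invasion** (`gelquant.invasion_analysis`) — depths from the gel top,
250 μm quartile counts up to a 750 μm maximum, median depth with an
order-statistic 95% CI.

**Assays** (`gelquant.assay_stats`) — viability/apoptosis percentages
from per-field counts and collagen-degradation percentage relative to
a collagenase total.

**Synthetic data** (`gelquant.synthetic_data`) — Brownian, fractional
Brownian (α = 2H, exact Cholesky construction) and persistent random
walks; fiber-field renderings whose density presets emulate 1/3/6
mg/mL gels; truncated-exponential invasion depths; two-channel
ellipsoidal cell phantoms with closed-form volume and axes.

## Worked example

The `analysis/` scripts run the chain end to end on synthetic study
conditions.  For migration:

```bash
python analysis/01_simulate_cohorts.py   # writes results/tracks/*.csv
python analysis/02_track_metrics.py
```

prints one row per simulated collagen condition:

```
1 mg/mL: n=135  static=5.9%   speed=0.40 um/min  alpha=0.86  persistence=6.2%
3 mg/mL: n=81   static=45.7%  speed=0.30 um/min  alpha=0.44  persistence=2.0%
6 mg/mL: n=71   static=81.7%  speed=0.07 um/min  alpha=0.24  persistence=1.2%
```

Reading the row for 1 mg/mL: of 135 cells, 5.9% moved less than 75 μm
in 24 h; the motile majority averaged 0.40 μm/min with a mean MSD
exponent of 0.86 — subdiffusive, i.e. migration hindered by the
matrix — and kept only 6% of their path as net displacement.  Denser
conditions show the expected signature: more static cells, slower
motion, smaller α.  The remaining scripts (`03`–`06`) produce the
structure, morphometry, invasion and assay tables under `results/`,
each printing the qualitative trend it checks (e.g. fiber length, Lf
and pore size all decreasing with density).

As a library:

```python
import numpy as np
from gelquant import synthetic_data as sd, trajectory_metrics as tm

config = sd.SimConfig(n_steps=144, frame_interval=10.0, seed=0)
track = sd.simulate_fbm_track(config, hurst=0.3, scale=2.0)
metrics = tm.compute_track_metrics(track)
print(round(metrics.alpha, 2))   # ≈ 0.6 (= 2·H) on average over tracks
```

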