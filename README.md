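# tailbud

Quantitative image analysis for zebrafish tailbud experiments: how does
removing progenitor cells (by two-photon ablation or genetic means)
change tissue proportions, gene-expression states and cell movement in
the elongating tail?

The package implements the full measurement chain such studies rely on,
as a tested, reusable library plus CLI:

- **3D nuclear segmentation** of DAPI-stained stacks: adaptive histogram
  equalisation (10 µm kernel cube, the average nuclear diameter), a
  difference-of-Gaussians band-pass (σ = 1, 3) thresholded at 0,
  per-slice 2D labelling (pluggable backend; a classical reference
  labeller ships with the package), and 2D→3D stitching of labels by
  footprint intersection-over-union at a 0.6 threshold.
- **Per-nucleus HCR quantification**: two rounds of 0.8 µm median
  filtering, background estimation as the median nuclear intensity of
  each gene in its off-tissue (*sox2* in notochord, *tbxta* in spinal
  cord), expression classification, and for *sox2⁺/tbxta⁺*
  (neuromesodermal-competent, NMC) nuclei the relative-level index
  `(a − b)/(a + b)` on background-subtracted intensities (+1 pure sox2
  bias, −1 pure tbxta bias).
- **Cross-embryo registration and mapping**: closed-form rigid
  (Kabsch) landmark alignment with an ICP fallback, neighbourhood
  averaging of expression over an 11 µm radius (≈ 14 nearest neighbours,
  the count of a perfect body-centred cubic lattice), ablation-ROI
  nucleus counts and ROI overlap heatmaps.
- **Cell-track motion metrics** from TrackMate/Mastodon-style exports:
  the time-averaged mean squared displacement MSD(τ) and its log–log
  exponent α (α ≈ 1 diffusive, α ≈ 2 ballistic), directionality calls at
  α > 1.1, corrected straightness, mean angular alignment, signed
  dorsoventral displacement with a 60 µm distance cutoff, and reporter
  intensity dynamics.
- **Tail morphometrics**: segmented-line tissue lengths with per-somite
  landmarks, µm/somite normalisation, spinal-cord/paraxial-mesoderm
  ratios, apoptosis fractions, and Mann–Whitney–Wilcoxon group
  comparisons (exact by enumeration for combined n ≤ 20) with the usual
  significance tiers.

Because such studies rarely deposit raw imaging, the package includes a
first-class **synthetic-data module**: tailbud-like nuclear phantoms
with opposing dorsoventral expression gradients and a co-expression
band, simulated diffusive/persistent/ballistic/confined tracks, point
clouds under known rigid transforms, and tail polylines with exact
somite lengths — all with ground truth attached, so every stage is
verifiable end-to-end.

## Worked example

```python
import numpy as np
from tailbud.synthetic import (EmbryoPhantomSpec, TrackSimSpec,
                               generate_nuclear_stack, generate_tracks)
from tailbud.segmentation import segment_nuclei, extract_nuclei
from tailbud.expression import classify_expression, region_counts
from tailbud.tracks import track_alpha, classify_directional

spec = EmbryoPhantomSpec(n_nuclei=50, min_separation_factor=1.4, seed=11)
stack, gt_labels, truth = generate_nuclear_stack(spec)
labels = segment_nuclei(stack)
table = extract_nuclei(labels, stack)
print(f"segmented {labels.max()} nuclei (ground truth: {len(truth)})")

classified = classify_expression(table, {"sox2": 0.02, "tbxta": 0.02})
print("class counts:", region_counts(classified))
dp = classified[classified.expr_class == "double_positive"]
print(f"median NMC index of co-expressers: {dp.nmc_index.median():+.3f}")

ts = generate_tracks(TrackSimSpec(kind="diffusive", n_tracks=200, n_steps=100, seed=1))
alphas = np.array([track_alpha(t)[0] for t in ts])
n_dir = sum(bool(classify_directional(a)) for a in alphas)
print(f"mean MSD exponent: {alphas.mean():.3f}; "
      f"directional tracks (alpha > 1.1): {n_dir}/200")
```

prints

```
segmented 50 nuclei (ground truth: 50)
class counts: {'sox2_only': 19, 'tbxta_only': 17, 'double_positive': 14, 'background': 0}
median NMC index of co-expressers: +0.017
mean MSD exponent: 0.958; directional tracks (alpha > 1.1): 41/200
```

All 50 phantom nuclei are recovered; the expression classes follow the
phantom's dorsoventral gradient with co-expressers in the middle band,
whose NMC index centres near 0 (balanced sox2/tbxta); and purely
diffusive tracks calibrate the MSD exponent to ≈ 1, with a minority
crossing the 1.1 directionality threshold by sampling noise.

The same stages are available from the shell:

```sh
tailbud simulate --seed 4 --out run/
tailbud segment --stack run/phantom.tif --out run/
tailbud tracks --tracks run/tracks.csv --out run/
tailbud morphometry --polylines run/polylines.csv --somites 30 --out run/
```

Each run writes a `manifest.json` (config hash, seed, version), and
identical config + seed reruns are byte-identical.

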