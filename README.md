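# dendropatch

Quantitative analysis of dendritic membrane patches and filopodia dynamics,
with the tissue-expression mining stage that nominates candidate regulators.

Developing neurons probe their surroundings with exploratory filopodia that
preferentially emerge from transient thickened regions of the dendritic shaft
("nodes"), where acto-myosin patches deform the plasma membrane and
curvature-sensing proteins (e.g. the N-BAR protein ArhGAP44) accumulate.
`dendropatch` implements the three quantitative stages such a study needs, as
a tested, reusable library:

1. **Expression ranking** — normalize a probes × tissues intensity atlas
   (median renormalization per array, log₂, per-probe mean centering),
   cluster probes with Pearson-correlation distance *d* = 1 − *r* and
   unweighted average linkage, select the cluster enriched in marker tissues,
   and rank genes by a between-tissue expression ratio validated against
   reference genes of known laterality.
2. **Ratiometric patch quantification** — Gaussian low-pass, local background
   subtraction (mean background within a 40 µm radius of each pixel),
   POI/cytosol ratio images, patch detection as connected components whose
   ratio exceeds 3× the mean dendrite ratio (">200 % above the average"),
   and the background-corrected relative enrichment

   ```
   E = [(POI_patch − POI_bg) / (Cyto_patch − Cyto_bg)]
     / [(POI_dend  − POI_bg) / (Cyto_dend  − Cyto_bg)]
   ```

   where each term is a region-mean intensity, the background per channel is
   the average of four sectors outside the cell, and *E* = 1 means no
   enrichment over the adjacent dendrite. Before/after drug-response
   quantification and Welch's two-tailed unequal-variance t-test round out
   the stage.
3. **Protrusion dynamics** — binarize time-lapse movies, render temporal
   color-code overlays, extract protrusion and node tracks, classify each
   protrusion as *static* (present throughout), *stabilized* (appears later,
   persists ≥ 3 min to the end), *collapsed* (present from the start,
   persists ≥ 3 min, gone before the end) or *transient* (everything else),
   and aggregate the dynamic-per-static rate, the node-emergence fraction of
   de novo protrusions, and the filopodia density over the proximal 100 µm
   of each dendrite.

A synthetic-data module generates dendrite scenes, protrusion track sets and
expression atlases with exactly known ground truth, so every estimator is
tested against planted values without any external data.

## Worked example

```python
import numpy as np
from dendropatch import (
    SceneConfig, PatchEvent, generate_scene, tissue_ratio,
    classify_track, ProtrusionTrack,
)
from dendropatch.ratio import ChannelImage
from dendropatch.patches import (
    place_background_sectors, dendrite_reference_mask, measure_regions,
    relative_enrichment,
)

# 1. a printed reference-gene ratio
print(f"adult brain / spinal cord ratio for PMP22: "
      f"{tissue_ratio(720.55, 2516.35):.6f}")

# 2. measure a planted 1.8-fold patch at signal-to-noise 10
cfg = SceneConfig(
    patch_events=[PatchEvent(arc_pos_um=20.0, onset=0, offset=1,
                             enrichment=1.8, radius_um=1.0)],
    background_level=100.0, noise_sigma=100.0, seed=42,
)
stack, truth = generate_scene(cfg)
poi = ChannelImage(stack.channels["poi"][0], cfg.pixel_size, "poi")
cyto = ChannelImage(stack.channels["cytosol"][0], cfg.pixel_size, "cytosol")
patch = truth.patches[0]
sectors = place_background_sectors(truth.frame_masks[0], patch.centroid)
ref = dendrite_reference_mask(truth.shaft_mask, patch.footprint,
                              patch.footprint, cfg.pixel_size)
m = measure_regions(poi, cyto, patch.footprint, ref, sectors)
e = relative_enrichment(m)
print(f"planted enrichment 1.8, measured {e:.3f} "
      f"({(e - 1) * 100:.1f}% over the shaft)")

# 3. classify a protrusion track (10 min movie, one frame per minute)
track = ProtrusionTrack(onset=2, offset=10, lengths_um=np.full(9, 2.5))
ct = classify_track(track, movie_minutes=10, frame_interval=60)
print(f"protrusion appearing at frame 2 and persisting to the end: {ct.label}")
```

Output:

```
adult brain / spinal cord ratio for PMP22: 0.286347
planted enrichment 1.8, measured 1.822 (82.2% over the shaft)
protrusion appearing at frame 2 and persisting to the end: stabilized
```

The PMP22 ratio below 0.3 marks a spinal-cord-enriched (Schwann-cell) gene;
the measured 1.822 recovers the planted 1.8-fold patch enrichment through the
full six-region measurement despite the noise; and the track is *stabilized*
because it appeared after the first frame and persisted at least 3 minutes
through the end of the acquisition.

A command-line interface mirrors the library:
`dendropatch simulate-scene | simulate-expression | rank | cluster | ratio |
quantify | drug-response | dynamics | colorcode` (see `dendropatch --help`).

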