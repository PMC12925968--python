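# periplaque

Quantification of pre-synaptic bouton loss around amyloid-β plaques in
multi-channel fluorescence images — with a synthetic-scene simulator that
makes every stage of the pipeline verifiable by ground-truth recovery.

## Who this is for

Groups imaging fluorescently labelled pre-synaptic boutons (e.g. an
HA-tagged synaptophysin reporter) together with dense-core plaques (X34),
an optional post-synaptic marker (Homer1) and manually traced axons, who
want reproducible, scriptable answers to the standard spatial questions:

* Is synapse density reduced *inside* plaques and in the first few µm
  around them, and how far does the loss extend?
* Does local loss propagate to whole-axon bouton density?
* Are inter-bouton spacings disturbed on axons passing near plaques?
* What fraction of plaques harbour a dystrophic (swollen) axon segment?
* What fraction of pre-synaptic puncta have an apposed post-synaptic
  punctum?

## What it computes

Given a calibrated image (or a simulated scene), the pipeline runs

1. **Detection** — multi-scale Laplacian-of-Gaussian puncta detection with
   sub-pixel centroids; plaque segmentation (Otsu or fixed threshold +
   morphology); size/flux-based classification of dystrophic swellings;
   snapping of puncta to annotated axon polylines.
2. **Spatial analysis** — a signed Euclidean distance field d(x) from the
   plaque union (negative inside); concentric-annulus density profiles over
   bins {interior, 0–5, 5–15, 15–25, 25–35 µm} with per-subject
   percentages p_k = (n_k/A_k) / Σ_j(n_j/A_j) × 100; per-axon closest
   approach min_s d(γ(s)); NND-3 (mean arc-length distance from each
   bouton to its 3 nearest same-axon boutons, axons with <4 boutons
   excluded); linear density per 100 µm with the >1,000 µm per-subject
   inclusion rule; greedy one-to-one HA–Homer1 colocalization; and the
   dystrophies-per-plaque fraction.
3. **Statistics** — repeated-measures one-way ANOVA (subject as block)
   with Dunnett post hoc against the 25–35 µm reference ring; one-way
   ANOVA + Dunnett; two-way ANOVA (type-II SS); unpaired t test.  Dunnett
   adjusted p-values are computed by deterministic quadrature of the
   equicorrelated multivariate-t probability.

The simulator (`periplaque.simulate`) draws plaques as perturbed-circle
polygons, axons as persistent random walks, boutons as a gamma renewal
process along each axon (with per-axon rate heterogeneity), plaque-proximal
bouton depletion (configurable probability inside the plaque and within a
depletion radius), dystrophic swellings at plaque–axon contacts, and
renders HA/X34/Homer1/axon channels with Gaussian PSF, Poisson shot noise
and read noise.  Every random element is recorded in ground-truth tables.

## Worked example

Simulate a depleted scene, analyze it end to end, and test the annulus
profile of three such subjects:

```python
import pandas as pd
from periplaque import (SceneConfig, sample_scene, rm_anova_dunnett)
from periplaque.spatial import AnnulusBinSpec, annulus_profile_exact

bins = AnnulusBinSpec()          # plaque, 0-5, 5-15, 15-25, 25-35 um
rows = []
for s in range(3):               # three subjects
    cfg = SceneConfig(seed=s)    # 800x800 um, 50 plaques, 0.8 depletion <5 um
    scene = sample_scene(cfg)
    kept = scene.kept_boutons
    prof = annulus_profile_exact(
        kept, scene.plaque_polygons, cfg.field_size_um, bins=bins,
        bouton_distances_um=kept["dist_plaque_um"].to_numpy(),
    )
    rows.append(prof.set_index("bin_label")["percentage"])
mat = pd.DataFrame(rows)
print(mat.round(1))
res = rm_anova_dunnett(mat, reference="25-35 um")
print(f"RM-ANOVA F({res.df[0]:.0f}, {res.df[1]:.0f}) = "
      f"{res.statistic:.2f}, p = {res.p_value:.4f}")
for label, p in res.posthoc:
    print(f"  Dunnett {label}: p = {p:.4f}")
```

Output:

```
bin_label   plaque  0-5 um  5-15 um  15-25 um  25-35 um
percentage     7.0     6.6     28.8      28.9      28.7
percentage     6.1     6.6     27.9      29.7      29.6
percentage     4.7     5.5     29.9      29.3      30.6
RM-ANOVA F(4, 8) = 510.41, p = 0.0000
  Dunnett plaque vs 25-35 um: p = 0.0000
  Dunnett 0-5 um vs 25-35 um: p = 0.0000
  Dunnett 5-15 um vs 25-35 um: p = 0.7462
  Dunnett 15-25 um vs 25-35 um: p = 0.9739
```

Reading: with 80 % depletion confined to the plaque interior and the first
5 µm, those two bins hold ~6 % of the area-normalized synapse share instead
of the flat ~20 %, the comparisons against the far ring are significant,
and the outer rings are statistically indistinguishable from the
reference — localized loss with no far-field effect.

The same analysis runs from the shell:

```bash
periplaque simulate --out scene/ --seed 3
periplaque run --config config.yaml          # detect -> analyze -> stats
periplaque detect scene/scene.ome.tif --out puncta.csv
```

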