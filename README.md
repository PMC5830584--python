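# neurocatmap

Voxel-wise encoding models and cortical category-organization analysis on
hierarchical (layered) stimulus features, exercised end-to-end on synthetic
data with a planted category hierarchy.

The pipeline chains:

1. **synth** — layered feature time series with planted
   superordinate/subgroup/category structure, ground-truth voxel populations,
   HRF-convolved noisy responses with session/repeat structure, category
   exemplar sets, a toy is-a taxonomy, and label vectors.
2. **features** — hemodynamic convolution (double-gamma kernel peaking at
   4 s), TR-window downsampling, standardization, and two-stage PCA
   (per-layer, then across 1/√p_l-scaled concatenated layers, each retaining
   ≥ 99% variance); single-layer ablation.
3. **encode** — per-voxel ridge regression with 9-fold cross-validated
   regularization, session-wise prediction accuracy, block-permutation
   significance with Benjamini–Hochberg FDR, Monte-Carlo noise ceiling from
   response repeats, and per-voxel best-layer assignment.
4. **catmap** — category maps as exemplar-averaged model predictions and d′
   category selectivity.
5. **cluster** — inter-category representational similarity over predictable
   voxels, k-means clustering with signed-modularity model selection,
   edge-shuffle permutation tests, cluster-specific regions (two-sample t,
   Bonferroni), and sub-clustering.
6. **semantics** — taxonomy path similarity (−log p/2d) and label-vector
   cosine similarity, with Mantel-style permutation-tested correlation
   against the cortical similarity (Fisher z on the cortical side).
7. **layers** — single-layer ablation profiles of similarity, modularity and
   semantic correlation.

## CLI

One console script with a sub-group per stage. Stage commands operate on a
workspace directory and resume completed upstream stages automatically:

```bash
neurocatmap validate --config examples/desk.yaml
neurocatmap run      --config examples/desk.yaml --out ws/   # everything
neurocatmap synth make      --config examples/desk.yaml --out ws/
neurocatmap features fit-pca --config examples/desk.yaml --out ws/
neurocatmap encode evaluate  --config examples/desk.yaml --out ws/
neurocatmap cluster fit      --config examples/desk.yaml --out ws/ --kmin 2 --kmax 8
neurocatmap cluster sub      --config examples/desk.yaml --out ws/ --cluster-id 1
neurocatmap semantics correlate --config examples/desk.yaml --out ws/
neurocatmap layers profile   --config examples/desk.yaml --out ws/
```

Omitting `--config` uses desk-scale defaults (500 voxels, 6 layers,
32 categories). All outputs are plain text (TSV/JSON) plus a `manifest.json`
with sha256 checksums per stage; reruns with the same config and seed are
byte-identical, and `--resume` recomputes only missing stages.

## Library use

```python
import numpy as np
from neurocatmap import synth, features as feat, encoding as enc

cfg = synth.GeneratorConfig(seed=0)
hier = synth.CategoryHierarchySpec()
kernel = feat.hrf_kernel(cfg.time_step)
movie = synth.make_layered_features(cfg, hier)
truth = synth.make_voxel_population(cfg)
train, test = synth.simulate_responses(movie, truth, kernel, cfg)

prepared, std = feat.prepare_series(movie, kernel, cfg.tr)
bases = feat.fit_pca(prepared, variance_threshold=0.99, standardizers=std)
design = feat.transform(prepared, bases)
```

See `src/neurocatmap/pipeline.py` for the full stage wiring.
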