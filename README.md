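# vpngrad

From retinotopic maps to synaptic weight gradients: an analysis pipeline for
the output connectivity of *Drosophila* visual projection neurons (VPNs).

Each VPN type (LC4, LPLC2, ...) is a population of 20–200 cells whose
dendrites tile the lobula retinotopically while their axons converge into a
single optic glomerulus. Stimulus location is therefore encoded by *which*
cells of a type fire — and the question is how that spatial code survives the
glomerular bottleneck. The answer this pipeline quantifies: the number of
synapses an individual VPN cell makes onto a downstream partner (for example
a descending neuron, DN) varies systematically with the cell's dendritic
position, so a retinotopic map is re-expressed as a **synaptic weight
gradient**, and partners reading opposite ends of the map acquire opposite
looming tuning and drive opposite escape directions.

The package is aimed at connectomics and systems-neuroscience analysts: it
takes neuron skeletons (SWC), synapse tables (CSV), tracked kinematics and
membrane-potential traces, and ships a synthetic-connectome generator with
planted ground truth so every stage is verifiable without EM data downloads.

## What it computes

- **Connectivity clustering** (`VPNClusterer`, sklearn-compatible): cells ×
  partners synapse-count matrix → drop partners with < 50 total synapses and
  within-type connections, standardize columns, PCA (≤ 10 components), and
  k-means with k from the within-cluster sum-of-squares scree elbow. Partner
  similarity is the pairwise Spearman ρ over the top 25 partners (300 unique
  pairs), ordered by average-linkage hierarchical clustering of 1 − ρ.
- **Spatial gradients**: per-cell dendritic centroids projected on a lobula
  cut-plane; per-partner synapse-weighted input centroids (component-wise
  weighted median); the *median separation line* built from perpendicular
  bisectors of the most anticorrelated partner pairs (threshold chosen to
  maximize the |correlation| between centroid distances and connectivity
  correlations); signed partner distances along the perpendicular
  *projection line*; per-partner regressions of counts vs position.
- **Glomerulus statistics**: per anticorrelated pair, a soft-margin linear
  SVM separating plane between postsynaptic-site clouds (cross-fitted:
  plane estimated on half of each cloud, statistics on the held-out half),
  the median plane across pairs, the two-sample Kolmogorov–Smirnov D of the
  projected sites, an axo-dendritic overlap vs synapse-count correlation,
  and a permutation-tested axon-topography index.
- **Anatomical receptive fields**: a quadratic surface fit to all dendritic
  arbors; each cell becomes a unit-height circular Gaussian in eye
  coordinates, σ = radius of the circle with the area of the projected
  dendritic polygon; a DN's receptive field is the synapse-weighted Gaussian
  sum, and its predicted looming response is
  Σᵢ (synapses from cell i) × (fraction of cell i's RF covered by the
  stimulus at its maximum 30° size).
- **Stimulus kinematics**: constant-velocity looming θ(t) = 2 tan⁻¹(l/(v|t|))
  with contact at t = 0 (θ → 180°) and constant-angular-velocity θ(t) = vₐt.
- **Behaviour and physiology**: gap interpolation + smoothing of 600 Hz
  tracking, takeoff vectors from centre-of-mass displacement, mean resultant
  length R̄ = |Σ e^{iθⱼ}|/n, the exact Hodges–Ajne uniformity test,
  Δ[T2 leg angle] postural lean with Butterworth filtering, slope-threshold
  spike detection, and the 150-ms integrated response potential (ms·mV).

## Worked example

Generate a 60-cell connectome with two partners planted on exactly opposite
anterior–posterior gradients (Poisson count noise), then run the full
pipeline:

```python
import numpy as np
import vpngrad as v

cfg = v.SyntheticConfig(seed=1, partner_specs=v.antiparallel_pair_specs())
arbors, matrix, sites, truth = v.generate_connectome(cfg)
rho = v.pair_spearman(matrix["DN_A"], matrix["DN_P"])

plane = v.CutPlane(anchor=[0, 0, -5], normal=[0, 0, 1], axes=[[1, 0, 0], [0, 1, 0]])
pmap = v.project_dendrites(arbors, plane, weights=matrix)
corr, _ = v.partner_correlation_matrix(matrix, top_n=2)
geom = v.anticorrelated_separation(corr, pmap, matrix)
res, median_plane = v.site_separation(sites, truth.anticorrelated_pairs)
```

Output (seed 1):

```
cells x partners: (60, 2)
count range: 10 - 89
Spearman rho(DN_A, DN_P) = -0.860
projection line at 2.9 deg from the planted A-P axis
centroid separation |d(DN_A, DN_P)| = 3.16 units
glomerulus D_KS = 0.282 (p = 4.17e-48), median offset 2.94 units
tuning-curve correlation = -0.880
preferred azimuths: DN_A 40 deg, DN_P 95 deg
```

Reading: the two partners' per-cell synapse counts are strongly
anticorrelated (ρ = −0.86); the recovered projection line lies within 3° of
the planted gradient axis; their postsynaptic sites segregate inside the
glomerulus (D_KS = 0.28 on ~1,300 held-out sites per class); and the
receptive-field model converts the opposing weight gradients into
anticorrelated looming tuning curves preferring opposite azimuths.

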