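# cortex3d

3D reconstruction, morphometry and columnar spatial statistics for
serial-section light microscopy of cortex.

Serial semi-thin sections (300–400 nm, toluidine-blue stained) imaged at
~0.27 μm/pixel make it possible to reconstruct every neuronal soma in a
cortical biopsy and ask quantitative questions that 2D histology cannot
answer: how large are layer-III pyramidal cells in 3D, how elongated and
how oriented are they relative to the pial surface, and are they arranged
in minicolumns? `cortex3d` is a Python toolkit for that analysis chain,
aimed at quantitative neuroanatomists and microscopy-image analysts:

* **acquisition** — biopsy-placement sampling on a delineated region,
  entropy-based section detection on slide montages, sequential rigid
  (mutual-information) stack alignment;
* **segmentation** — a classical reference segmenter for synthetic stacks,
  ingestion of masks from any external segmenter, and confusion-matrix
  validation (sensitivity TP/(TP+FN), precision TP/(TP+FP), F1);
* **reconstruct** — 26-connected 3D labeling with artifact filters, and
  per-cell morphometry on anisotropic voxels: volume, centroid, surface
  area (marching cubes), sphericity ψ = π^{1/3}(6V)^{2/3}/A, maximum Feret
  diameter in 2D/3D, and orientation angle θ = arccos|u·u₀| to the pial
  axis u₀ = (1,0,0);
* **classify** — layer-III windowing from centroid density, a 2-component
  Gaussian mixture over (volume, sphericity) separating pyramidal from
  small round cells, log-Feret outlier removal, number density;
* **nucleator** — stereological 2D size estimates from rays between the
  profile centroid and boundary, Volume = (4/3)π l̄³, Diameter = 2 l̄,
  against the 3D sphere-equivalent diameter (6V/π)^{1/3};
* **pointpattern** — the cylindrical K-function
  K̂_u(r,t) (translation-corrected; 2πr²t under CSR) with extreme-rank-
  length (ERL) global envelope tests against CSR to detect cylindrical
  clustering along a direction u;
* **synthetic** — a fully seeded scene generator (columnar point process,
  ellipsoid somata, rendered 16-bit stacks with PSF and noise) so the
  entire pipeline is testable against exact ground truth;
* **validation** — objectwise centroid-in-profile matching, point-count
  areal shrinkage, and cross-subject mean / population-SD / CV summaries.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Generate a synthetic layer-III block at the default study conditions
(pyramidal density 28,155 mm⁻³, mean volume 795 μm³, mean folded
orientation ≈29°), push it through the pipeline, and test for columnarity:

```python
import numpy as np
from cortex3d import generate_scene
from cortex3d.segmentation import reference_segment
from cortex3d.reconstruct import label_and_filter, measure_cells
from cortex3d.classify import (cells_to_frame, gmm_split, outlier_filter,
                               number_density)
from cortex3d.pointpattern import global_envelope_test

scene = generate_scene(seed=7)
mask = reference_segment(scene.stack)
cells = measure_cells(label_and_filter(mask, min_voxels=8))
table = cells_to_frame(cells)
table["label"] = outlier_filter(table, gmm_split(table, seed=0).labels)
pyr = table[table["label"] == "pyramidal"]

window_mm3 = np.prod(scene.params.window_box) * 1e-9
print(f"number density: {number_density(len(pyr), window_mm3):,.0f} mm^-3")
print(f"mean pyramidal volume: {pyr['volume_um3'].mean():.0f} um^3")
print(f"mean orientation angle: {pyr['theta_deg'].mean():.1f} deg")

env = global_envelope_test(scene.pattern, direction="x",
                           r_grid=np.linspace(0, 25, 16),
                           t_grid=np.linspace(0, 80, 16),
                           nsim=199, seed=1)
print(f"ERL test (direction x): p = {env.p:.3f}")
```

Output:

```
number density: 34,259 mm^-3
mean pyramidal volume: 943 um^3
mean orientation angle: 28.3 deg
ERL test (direction x): p = 0.015
```

This seed drew a denser-than-average block (97 reconstructed cells; the
per-seed density fluctuates with a ~20% coefficient of variation at this
window size, and averages to the nominal 28,155 mm⁻³ across seeds). The
classifier removed 23 small round cells; the mean folded orientation of
28.3° shows the long axes pointing toward the pial surface; and the ERL
envelope test rejects complete spatial randomness in the pial direction
(p = 0.015), detecting the columnar arrangement the generator built in.

A command-line interface mirrors the stages
(`cortex3d simulate | detect-sections | align | segment | pixel-metrics |
reconstruct | classify | nucleator | ppa | validate-objects | summarize`);
run `cortex3d --help` for details.

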