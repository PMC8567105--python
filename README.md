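# minltv

Low-dose cone-beam CT (CBCT) reconstruction and denoising in Python:
an analytical filtered-backprojection chain with both a pixel-driven (PDB)
and a Siddon ray-driven (RDB) backprojector, followed by a
**mutual-information non-local total-variation (MI-NLTV) denoiser** for
images acquired at a low tube-current (mAs) setting, where Poisson photon
noise dominates.

CBCT is the workhorse image-guidance system in radiotherapy; every imaging
session adds dose, so there is sustained interest in reconstructing
clinically useful volumes from low-mAs projections. Conventional non-local
TV regularizers weight the TV penalty by non-local-means (NLM) patch
similarity, which degrades at low dose because the patches themselves are
noise-corrupted. MI-NLTV replaces the NLM similarity with an
information-theoretic measure that is far less sensitive to per-pixel noise.

## The method

**Reconstruction.** Projections are cosine pre-weighted
(`sdd/sqrt(sdd² + u² + v²)`), optionally Parker-weighted for short scans,
and ramp-filtered row-wise with a Shepp–Logan × raised-cosine (Hann)
frequency response. The RDB then backprojects with exact Siddon
intersection lengths *l<sub>jk</sub>* between voxel *V<sub>j</sub>* and the
ray from detector pixel *P<sub>k</sub>* to the focal spot:

```
mu_j = ( Σ_k l_jk · P_k ) / ( Σ_k l_jk )
```

**Denoising.** For every pixel *j* of each axial slice, a stationary patch
(5×5) is compared against all patches of a 21×21 search window through one
pooled joint intensity histogram (128×128 bins), giving the statistical
measure

```
M_j = MI(I_A, I_B^Ω) / H(I_A),          MI = H(A) + H(B) − H(A,B)
```

and the smoothing weight

```
w_j = exp( −(V_j/τ)^ρ · M_j ),     τ = 90th intensity percentile, ρ = 10.
```

Structured, repeating patches (high MI, low entropy) and high-intensity
voxels get small weights (preserved); featureless noisy regions get
weights near one (smoothed). The weighted TV objective
`R(V) = Σ_j w_j · D(V_j)` (backward-difference gradient magnitude `D`) is
minimized by 20 steepest-descent steps with the gradient normalized to
unit Euclidean norm and an adaptive step `λ = γ·RMS(V)·s`; γ shrinks by
0.8 whenever `R` increases. An NLM-weighted baseline (`weight_mode="nlm"`)
shares the whole pathway for controlled comparisons.

No scanner data is required: `minltv.phantom` builds a Catphan-like digital
phantom (seven density inserts, a uniformity module, 1–3 lp/cm bar
patterns) and simulates low-mAs acquisitions with a Poisson transmission
noise model (`counts ~ Poisson(I0·e^{−p})`).

## Worked example

```python
import numpy as np
from minltv import (GridSpec, ScanGeometry, DenoiseParams,
                    make_catphan_like, simulate_projections,
                    reconstruct_fbp, denoise, mu_to_hu)
from minltv.phantom import spec_for_grid
from minltv.pipeline import phantom_rois
from minltv.metrics import cnr

grid = GridSpec.centered((16, 96, 96), (1.0, 1.0, 1.0))      # 96×96×16 mm
geo  = ScanGeometry.circular(n_views=60, arc_deg=360, sad=1000, sdd=1536,
                             det_nu=128, det_nv=128, det_du=1.6, det_dv=1.0)
spec  = spec_for_grid(grid)
truth = make_catphan_like(grid, spec)
proj  = simulate_projections(truth, geo, i0=2e4, seed=1)      # low dose
proj  = proj.with_data(proj.data, stage="raw")

rec      = reconstruct_fbp(proj, grid, backprojector="rdb")
dn, hist = denoise(rec, DenoiseParams())                      # MI-NLTV

rois = phantom_rois(spec, grid)
for name, roi in rois["cnr_rois"][:3]:
    print(name, round(cnr(mu_to_hu(rec), roi, rois["bg_roi"]), 1),
          "->", round(cnr(mu_to_hu(dn), roi, rois["bg_roi"]), 1))
```

prints (seed 1):

```
delrin 8.4 -> 59.4
teflon 25.0 -> 191.2
air 25.8 -> 192.6
```

i.e. the contrast-to-noise ratio of every sensitometry insert rises by
several fold because the background noise σ drops ~8× while insert
contrast is preserved by the weight map. `hist[z].r_history` carries the
per-slice objective trace (monotonically decreasing on this fixture).

The same study is available from the shell:

```bash
minltv run --config config.yaml --out results_dir --seed 1
```

which writes the six volumes (PDB, RDB, each ± NLTV / MI-NLTV), weight
maps, objective logs, a metrics report CSV and a reproducibility manifest.

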