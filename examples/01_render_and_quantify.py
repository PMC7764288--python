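"""Render a synthetic cytospin field and quantify per-cell CTCF.

Builds a noiseless scene with known planted intensities, runs nuclear
segmentation + region expansion + background-corrected quantification,
and checks the measurements against the ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from ctcpheno import QuantifyConfig, SceneSpec, quantify_sample, render_scene

spec = SceneSpec(
    n_cells_per_class={"epithelial-CTC": 5, "mesenchymal-CTC": 5, "pbmc": 20},
    background_level={"dapi": 0.0, "ker": 0.0, "vim": 0.0, "pdl1": 0.0},
    psf_sigma_px=0.0,
    gaussian_noise_sd=0.0,
    seed=7,
)
stack, truth = render_scene(spec)
result = quantify_sample(stack, QuantifyConfig(dilation_px=6))

print(f"planted cells: {len(truth)}, detected cells: {len(result.cells)}")

# match detections to planted cells by nearest centroid
_, idx = cKDTree(truth[["x", "y"]].to_numpy()).query(result.cells[["x", "y"]].to_numpy())
err = np.abs(
    result.cells["ctcf_ker"].to_numpy() - truth["tru_intden_ker"].to_numpy()[idx]
)
print(f"max |CTCF - planted intensity| on the keratin channel: {err.max():.2e}")
print(result.cells[["cell_id", "area_px", "ctcf_ker", "ctcf_vim", "cd45_positive"]].head())

# In a noiseless, blur-free scene the corrected total cell fluorescence
# (integrated density minus area x mean background) equals the planted
# per-cell intensity to floating-point precision; CD45-positive rows are
# the leukocyte distractors that the CTC definition later excludes.
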