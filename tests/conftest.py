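"""Shared fixtures: noiseless scenes and matched quantification results."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ctcpheno import QuantifyConfig, SceneSpec, quantify_sample, render_scene

ZERO_BACKGROUND = {"dapi": 0.0, "ker": 0.0, "vim": 0.0, "pdl1": 0.0}


def noiseless_spec(**overrides) -> SceneSpec:
    """A scene with no background, blur, or noise (analytic ground truth)."""
    kwargs = dict(
        background_level=dict(ZERO_BACKGROUND),
        psf_sigma_px=0.0,
        gaussian_noise_sd=0.0,
        use_poisson_noise=False,
        seed=0,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


def quantify_scene(spec: SceneSpec, **config_overrides):
    """Render + quantify a scene; returns (result, truth)."""
    stack, truth = render_scene(spec)
    cfg = QuantifyConfig(
        dilation_px=spec.cell_radius_px - spec.nucleus_radius_px + 2,
        min_peak_distance=max(2, int(spec.nucleus_radius_px)),
        **config_overrides,
    )
    return quantify_sample(stack, cfg), truth


def match_to_truth(cells, truth):
    """Index into ``truth`` of the planted cell nearest each detected cell."""
    tree = cKDTree(truth[["x", "y"]].to_numpy())
    dist, idx = tree.query(cells[["x", "y"]].to_numpy())
    return idx, dist


@pytest.fixture(scope="session")
def small_noiseless():
    """A small noiseless mixed scene quantified once per session."""
    spec = noiseless_spec(
        n_cells_per_class={"epithelial-CTC": 8, "mesenchymal-CTC": 8, "pbmc": 15},
        seed=11,
    )
    result, truth = quantify_scene(spec)
    return spec, result, truth
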