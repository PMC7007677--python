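"""Shared fixtures: the desk-scale synthetic study conditions.

The scenes used for the U-Net-vs-Frangi comparison are 200x200 px with 1-2
pale tubular roots of variable width and contrast, soil-textured background,
pixel noise, and two bright scratch artifacts per image (the known
false-positive source for vesselness-style segmenters on real rhizotron
glass). Heavy artifacts (the CMA-ES-tuned baseline and the trained
reduced-width network) are session-scoped so every test shares one run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from rootseg import frangi, quantify, synthetic, training

#: pixel scale adopted for synthetic scenes (they are not native-resolution
#: photographs); 2 px/mm puts a 10 mm grid line every 20 px on a 200 px scene
SYNTH_PX_PER_MM = 2.0


def make_study_scenes(n: int, seed0: int, n_scratches: int = 2):
    """Seeded scene sets with scratch artifacts drawn on the images only."""
    scenes = synthetic.make_dataset(n, synthetic.SceneConfig(), seed=seed0)
    out = []
    for k, sc in enumerate(scenes):
        img = synthetic.add_scratches(sc.image, n_scratches, seed=1000 + seed0 + k)
        out.append(dataclasses.replace(sc, image=img))
    return out


@pytest.fixture(scope="session")
def val_scenes():
    return make_study_scenes(5, 7)


@pytest.fixture(scope="session")
def train_scenes():
    return make_study_scenes(20, 11)


@pytest.fixture(scope="session")
def tuned_frangi(val_scenes):
    """CMA-ES-tuned Frangi baseline on the validation scenes (budget 300)."""
    images = [s.image for s in val_scenes]
    masks = [s.mask for s in val_scenes]
    init = frangi.FrangiParams()
    init_objective = frangi.objective(init, images, masks)
    params, objective = frangi.optimize_params(
        images, masks, frangi.OptimizerBudget(max_evaluations=300, init_params=init, seed=3)
    )
    return {
        "params": params,
        "objective": objective,
        "init_objective": init_objective,
        "scenes": val_scenes,
    }


@pytest.fixture(scope="session")
def scaled_training_run(train_scenes, val_scenes):
    """Reduced-width U-Net (base 8, 348-px tiles) trained on the study scenes."""
    config = training.TrainConfig(
        epochs=15,
        seed=0,
        tile_in_side=348,
        base_channels=8,
        n_candidates=8,
        tile_cap=2,
        batch_size=4,
    )
    model, history = training.fit(train_scenes, val_scenes, config)
    return {"model": model, "history": history, "config": config}


@pytest.fixture(scope="session")
def density_sweep():
    """Skeleton lengths and 10 mm grid-intersect intensities over 30 scenes
    spanning the root-density band."""
    cfg = dataclasses.replace(synthetic.SceneConfig(), n_roots=4, height=320, width=320)
    scenes = synthetic.make_dataset(30, cfg, seed=21)
    grid = quantify.GridSpec(spacing_mm=10, px_per_mm=SYNTH_PX_PER_MM)
    lengths = [quantify.skeleton_length_px(s.mask) for s in scenes]
    intensities = [quantify.grid_intersect_intensity(s.mask, grid) for s in scenes]
    return np.array(lengths), np.array(intensities)
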