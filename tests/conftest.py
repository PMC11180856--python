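"""Shared fixtures: a noise-free phantom bundle reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from svdquant.phantom import (PhantomSpec, generate_phantom_masks,
                              make_class_library, make_truth_maps,
                              simulate_dce_study, simulate_pet_study)
from svdquant.schedules import FrameSchedule


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.geometric()


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd_dce=0.0, noise_sd_pet=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec, schedule):
    """Noise-free phantom: masks, truth, library, DCE and PET simulations."""
    rng = np.random.default_rng(11)
    masks = generate_phantom_masks(clean_spec)
    truth = make_truth_maps(masks, clean_spec, rng)
    library = make_class_library(clean_spec, schedule, rng)
    dce = simulate_dce_study(masks, truth.ki, truth.vp, truth.t1_ms,
                             clean_spec, rng)
    pet = simulate_pet_study(masks, truth.r1, truth.k2, truth.bp, truth.vb,
                             library, schedule, clean_spec, rng)
    return {"spec": clean_spec, "masks": masks, "truth": truth,
            "library": library, "dce": dce, "pet": pet}
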