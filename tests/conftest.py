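"""Shared fixtures: schedules, noise-free synthetic curve pairs, phantoms.

Everything is generated programmatically; session scope keeps the heavier
objects (fine-grid curves, phantom) built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from refkin import synth
from refkin.datasets import VOI_VOLUMES_CM3, VOXEL_SIZE_MM
from refkin.tac import make_default_schedule


@pytest.fixture(scope="session")
def schedule():
    return make_default_schedule()


@pytest.fixture(scope="session")
def fine(schedule):
    """Fine grid, plasma input and the shared reference (cerebellum) curve."""
    t = synth.fine_grid(schedule.duration_min)
    cp = synth.feng_aif(t)
    ref_curve = synth.simulate_1t(cp, synth.DEFAULT_REF_TISSUE, t)
    return {"t": t, "cp": cp, "ref_curve": ref_curve}


@pytest.fixture(scope="session")
def wt_truth():
    """WT-like ground truth: receptor-rich striatum, unit delivery ratio."""
    return synth.SRTMTruth(r1=1.0, k2=0.35, bpnd=11.54)


@pytest.fixture(scope="session")
def noise_free_pair(schedule, fine, wt_truth):
    """Noise-free (striatum, cerebellum) TAC pair consistent with SRTM."""
    t = fine["t"]
    target_curve = synth.srtm_forward(fine["ref_curve"], wt_truth, t)
    tgt = synth.frame_average(target_curve, t, schedule, "striatum")
    ref = synth.frame_average(fine["ref_curve"], t, schedule, "cerebellum")
    return tgt, ref


@pytest.fixture(scope="session")
def low_bp_pair(schedule, fine):
    """Noise-free pair with modest binding (BPND = 1.5), faster dynamics."""
    truth = synth.SRTMTruth(r1=1.0, k2=0.4, bpnd=1.5)
    t = fine["t"]
    target_curve = synth.srtm_forward(fine["ref_curve"], truth, t)
    tgt = synth.frame_average(target_curve, t, schedule, "striatum")
    ref = synth.frame_average(fine["ref_curve"], t, schedule, "cerebellum")
    return tgt, ref, truth


@pytest.fixture(scope="session")
def phantom(schedule):
    """32^3 digital phantom with study-sized striatum and cerebellum VOIs."""
    img, labels = synth.build_phantom(
        (32, 32, 32),
        [VOXEL_SIZE_MM] * 3,
        {
            "striatum": VOI_VOLUMES_CM3["striatum_wt"],
            "cerebellum": VOI_VOLUMES_CM3["cerebellum"],
        },
        schedule,
    )
    return img, labels


@pytest.fixture(scope="session")
def filled_phantom(phantom, noise_free_pair):
    tgt, ref = noise_free_pair
    img, labels = phantom
    filled = synth.fill_regions(img, labels, {"striatum": tgt, "cerebellum": ref})
    return filled, labels


def add_voxel_noise(img, labels, base_tacs, alpha, seed):
    """Independent per-voxel Gaussian noise with the count-statistics sigma."""
    from refkin.synth import NoiseModel, noise_sigma
    from refkin.tac import DynamicImage

    rng = np.random.default_rng(seed)
    vox = img.voxels.copy()
    for region, base in base_tacs.items():
        m = labels.mask(region)
        sig = noise_sigma(base, NoiseModel(alpha=alpha))
        vox[m] += rng.normal(size=(int(m.sum()), img.schedule.n_frames)) * sig
    return DynamicImage(vox, img.voxel_size_mm, img.schedule)
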