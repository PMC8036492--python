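"""Shared fixtures: phantom study conditions and a trained model.

The expensive fixtures (toy atlas, labelled cohort, per-subject ROI
registrations, trained network) are session-scoped so the end-to-end and
precision tests share one atlas-registration pass and one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from hipposeg import (PhantomSpec, RoiConfig, TrainConfig, TrainingCrop,
                      augment_blur, build_network, generate_atlas,
                      generate_cohort, generate_retest_pair, scaled_config,
                      split_cohort)
from hipposeg.atlas import RoiCrop
from hipposeg.net import train as net_train
from hipposeg.pipeline import SIDE_LABELS, locate_rois, preprocess

#: study-condition phantom grid for end-to-end runs (64-96 mm FOV band)
E2E_SHAPE = (64, 64, 64)
N_TRAIN, N_VAL, N_TEST = 20, 3, 5
N_RETEST_PAIRS = 20
COHORT_SEED = 20_001
RETEST_SEED = 30_000


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    return PhantomSpec(shape=E2E_SHAPE)


@pytest.fixture(scope="session")
def atlas64(spec64):
    return generate_atlas(spec64, seed=0)


@pytest.fixture(scope="session")
def cohort64(spec64):
    """20 train / 3 val / 5 test labelled phantoms."""
    n = N_TRAIN + N_VAL + N_TEST
    subjects = generate_cohort(spec64, n, seed=COHORT_SEED)
    tr, va, te = split_cohort(n, (N_TRAIN / n, N_VAL / n, N_TEST / n))
    assert len(tr) == N_TRAIN and len(va) == N_VAL and len(te) == N_TEST
    return {
        "train": [subjects[i] for i in tr],
        "val": [subjects[i] for i in va],
        "test": [subjects[i] for i in te],
    }


@pytest.fixture(scope="session")
def cohort_rois(cohort64, atlas64):
    """One atlas-registration + ROI pass per cohort subject, shared by all
    end-to-end tests (containment, training, held-out evaluation)."""
    rois = {}
    for split, subjects in cohort64.items():
        for j, (v, _) in enumerate(subjects):
            rois[(split, j)] = locate_rois(preprocess(v), atlas64, RoiConfig())
    return rois


def crops_from_rois(cohort64, cohort_rois, split, augment):
    """TrainingCrops for one split, optionally with blur augmentation."""
    out = []
    for j, (_, truth) in enumerate(cohort64[split]):
        for side, crop in cohort_rois[(split, j)].items():
            sl = tuple(slice(l, h) for l, h in zip(crop.bbox_lo, crop.bbox_hi))
            t = truth.data[sl] == SIDE_LABELS[side]
            out.append(TrainingCrop(crop, t))
            if augment:
                for blurred in augment_blur(crop.image, (0.5, 1.0)):
                    out.append(TrainingCrop(
                        RoiCrop(blurred, crop.dilated_mask.copy(),
                                crop.bbox_lo, crop.parent_shape, side), t))
    return out


@pytest.fixture(scope="session")
def retest_pairs64(spec64):
    return [generate_retest_pair(spec64, RETEST_SEED + i)
            for i in range(N_RETEST_PAIRS)]


@pytest.fixture(scope="session")
def trained_model(cohort64, cohort_rois):
    """Scaled-down network trained on the 20-phantom cohort."""
    cfg = TrainConfig(epochs=10, batches_per_epoch=25, output_side=17,
                      seed=0, lr_init=0.02)
    return net_train(build_network(scaled_config(), seed=0),
                     crops_from_rois(cohort64, cohort_rois, "train", True),
                     crops_from_rois(cohort64, cohort_rois, "val", False),
                     cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
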