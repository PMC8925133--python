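"""Shared fixtures: random mask generators and (lazily) trained toy models."""

from __future__ import annotations

import numpy as np
import pytest

from ctrkit.geometry import clean_mask, iou, measure_ctr
from ctrkit.models import (
    build_model,
    predict_masks,
    toy_config,
    toy_train_config,
    train,
)
from ctrkit.phantom import CTRDistribution, generate_cohort

ARCHS = ("albunet", "vgg11_unet", "vgg16_unet", "segnet")


def random_blob_mask(rng: np.random.Generator, shape=(24, 32), n_blobs=3) -> np.ndarray:
    """Union of random filled rectangles/ellipses — arbitrary topology."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    y, x = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, n_blobs + 1)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(1, h / 3), rng.uniform(1, w / 3)
        if rng.random() < 0.5:
            mask |= (np.abs(y - cy) <= ry) & (np.abs(x - cx) <= rx)
        else:
            mask |= ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0
    return mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast, low-resolution cohort for smoke tests."""
    return generate_cohort(
        8, CTRDistribution.normal(0.50, 0.06, 0.38, 0.65), seed=5, image_size=64
    )


@pytest.fixture(scope="session")
def trained_models():
    """All four architectures trained at toy scale on one phantom cohort.

    Expensive (minutes per architecture on one CPU) and therefore built once
    per session, on first request.  Returns per-architecture dicts with the
    model and its held-out evaluation: mean lung/heart IoU, per-sample CTRs
    and grades against the ground-truth reference.
    """
    from ctrkit.assist import grade_single

    train_coh = generate_cohort(200, seed=11, image_size=256)
    test_coh = generate_cohort(40, seed=99, image_size=256)
    results = {}
    for arch in ARCHS:
        model = build_model(toy_config(arch), seed=0)
        model, trace = train(model, train_coh, toy_train_config(arch, seed=0))
        lung_ious, heart_ious, grades, ctrs = [], [], [], []
        for s in test_coh:
            lm, hm = predict_masks(model, s.image)
            lm = clean_mask(lm, keep_components=2)
            hm = clean_mask(hm, keep_components=1)
            lung_ious.append(iou(lm, s.lung_mask))
            heart_ious.append(iou(hm, s.heart_mask))
            if not lm.any() or not hm.any():
                grades.append("poor")
                ctrs.append(np.nan)
                continue
            m = measure_ctr(lm, hm)
            ctrs.append(m.ctr)
            grades.append(grade_single(m.ctr, s.truth_ctr))
        results[arch] = {
            "model": model,
            "trace": trace,
            "test_cohort": test_coh,
            "lung_iou": float(np.mean(lung_ious)),
            "heart_iou": float(np.mean(heart_ious)),
            "grades": grades,
            "ctrs": ctrs,
        }
    return results
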