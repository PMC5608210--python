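"""Shared fixtures: expensive phantom/segmentation artifacts built once."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from lungmorph import BinaryVolume
from lungmorph.curvature import extract_surface, normal_cycle_curvature, smooth_mesh
from lungmorph.phantom import DEFAULT_IMAGING, PhantomSpec, generate_foam, inflate, render_image, trend_spec
from lungmorph.segment import RidgeParams, SegmentationParams, segmentation_ensemble

logging.getLogger("lungmorph").setLevel(logging.WARNING)

PHANTOM_SEED = 7


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def make_ball_mask(radius: int, spacing: float = 1.0, pad: int = 3) -> BinaryVolume:
    """Tissue everywhere except a lattice-centred digital air ball."""
    n = 2 * radius + 2 * pad + 1
    c = n // 2
    z, y, x = np.mgrid[:n, :n, :n]
    ball = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius * radius
    return BinaryVolume(~ball, spacing)


@pytest.fixture(scope="session")
def default_truth():
    return generate_foam(PhantomSpec(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def default_render(default_truth):
    return render_image(default_truth, DEFAULT_IMAGING)


@pytest.fixture(scope="session")
def trend_truths():
    """Baseline + inflated trend phantoms (large field of view, 2.9 µm)."""
    base = generate_foam(trend_spec(0))
    return {1.0: base, 1.3: inflate(base, 1.3), 1.5: inflate(base, 1.5)}


@pytest.fixture(scope="session")
def curvature_trend_truths():
    """Trend phantoms sized for mesh-based analyses."""
    base = generate_foam(trend_spec(0, (80, 80, 80)))
    return {1.0: base, 1.3: inflate(base, 1.3), 1.5: inflate(base, 1.5)}


def nine_variants() -> list[SegmentationParams]:
    return [
        SegmentationParams(ridge=RidgeParams(1, mw, mm, np.inf), variant_id=f"m{mm}w{mw}")
        for mm in (10, 12, 14)
        for mw in (9, 11, 13)
    ]


@pytest.fixture(scope="session")
def ensemble_setup():
    """Trend phantom + rendered volume + 9 segmentation variants."""
    truth = generate_foam(trend_spec(PHANTOM_SEED))
    vol = render_image(truth, DEFAULT_IMAGING)
    masks = segmentation_ensemble(vol, nine_variants())
    return truth, vol, masks


@pytest.fixture(scope="session")
def ensemble_fields(ensemble_setup):
    """Per-variant curvature fields for the 9-variant ensemble."""
    _, _, masks = ensemble_setup
    fields = []
    for m in masks:
        mesh = smooth_mesh(extract_surface(m), 20, 0.5)
        fields.append(normal_cycle_curvature(mesh, 3.5))
    return fields


@pytest.fixture(scope="session")
def sphere_mesh():
    """Smoothed marching-cubes mesh of a 25 µm air ball at 1 µm spacing."""
    return smooth_mesh(extract_surface(make_ball_mask(25, 1.0, 4)), 20, 0.5)


@pytest.fixture(scope="session")
def sphere_field(sphere_mesh):
    return normal_cycle_curvature(sphere_mesh, 5.0)
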