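"""Shared fixtures: small ground-truth phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from clemtarget import phantom, segmentation
from clemtarget.transform import Transform3D


def make_three_class_scene() -> phantom.Scene:
    """One lysosome, one mitochondrion, one ER tubule; identity transform."""
    orgs = [
        phantom.Organelle(
            label=1, cls="lysosome", kind="ellipsoid",
            center=(700.0, 700.0, 700.0), radii=(280.0, 280.0, 280.0),
        ),
        phantom.Organelle(
            label=2, cls="mitochondrion", kind="tube",
            path=np.array([[300.0, 1500.0, 400.0], [1700.0, 1600.0, 500.0]]),
            radius=150.0,
        ),
        phantom.Organelle(
            label=3, cls="ER_tubule", kind="tube",
            path=np.array(
                [[1500.0, 300.0, 900.0], [1700.0, 900.0, 1000.0],
                 [1500.0, 1500.0, 1100.0]]
            ),
            radius=80.0,
        ),
    ]
    return phantom.Scene(
        organelles=orgs,
        fiducials=np.empty((0, 3)),
        fiducial_intracellular=np.empty(0, dtype=bool),
        substrate_z=0.0,
        true_transform=Transform3D(),
    )


@pytest.fixture(scope="session")
def three_class_scene() -> phantom.Scene:
    return make_three_class_scene()


@pytest.fixture(scope="session")
def em_template_10nm():
    return phantom.make_template((200, 200, 140), (10.0, 10.0, 10.0))


@pytest.fixture(scope="session")
def gt_labels(three_class_scene, em_template_10nm):
    return phantom.scene_labels(three_class_scene, em_template_10nm)


@pytest.fixture(scope="session")
def prompt_book(gt_labels):
    book: dict[str, dict[str, list]] = {
        c: {} for c in ("lysosome", "mitochondrion", "ER")
    }
    for ori in segmentation.ORIENTATIONS:
        for cls, lst in segmentation.scripted_prompter(gt_labels, ori).items():
            book[cls][ori] = lst
    return book


@pytest.fixture(scope="session")
def em_clean(three_class_scene, em_template_10nm):
    return phantom.render_em_volume(
        three_class_scene, em_template_10nm, check_bounds=False
    )


@pytest.fixture(scope="session")
def em_snr5(three_class_scene, em_template_10nm):
    # SNR 5 on the weakest relevant contrast (membrane 0.80 vs resin 0.40)
    return phantom.render_em_volume(
        three_class_scene,
        em_template_10nm,
        noise=phantom.NoiseModel(gaussian_sd=0.08),
        seed=5,
        check_bounds=False,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    s = int(a.sum()) + int(b.sum())
    return 2.0 * float(np.sum(a & b)) / s if s else float("nan")
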