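import pytest

from ommascore import (
    EyeSceneSpec,
    Modality,
    detect_ommatidia,
    localize_eye,
    make_lattice,
    render,
    score_pointset,
)


@pytest.fixture(scope="session")
def bf_scene():
    """Default wild-type bright-field scene, zero jitter, seed 1."""
    spec = EyeSceneSpec(modality=Modality.BRIGHTFIELD, seed=1)
    gt = make_lattice(spec)
    return spec, gt, render(gt, spec)


@pytest.fixture(scope="session")
def sem_scene():
    spec = EyeSceneSpec(modality=Modality.SEM, seed=1)
    gt = make_lattice(spec)
    return spec, gt, render(gt, spec)


@pytest.fixture(scope="session")
def bf_mask(bf_scene):
    _, _, img = bf_scene
    return localize_eye(img)


@pytest.fixture(scope="session")
def sem_mask(sem_scene):
    _, _, img = sem_scene
    return localize_eye(img)


@pytest.fixture(scope="session")
def bf_centers(bf_scene, bf_mask):
    _, _, img = bf_scene
    return detect_ommatidia(img, bf_mask)


def run_pipeline(spec, morph=None, det=None, N=200):
    """Render a scene and push it through the full pipeline."""
    gt = make_lattice(spec)
    img = render(gt, spec)
    mask = localize_eye(img, morph)
    centers = detect_ommatidia(img, mask, det)
    result = score_pointset(centers, eye_center=mask.centroid, N=N)
    return gt, mask, centers, result
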