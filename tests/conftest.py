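"""Shared fixtures: speckle images, small phantoms, full fast-preset runs."""

from __future__ import annotations

import numpy as np
import pytest

from qelast import RunConfig, run_pipeline
from qelast.materials import ElasticMaterial
from qelast.phantom import (
    PhantomSpec,
    hard_phantom,
    inclusion_phantom,
    make_speckle,
    render_sequence,
    soft_phantom,
)
from qelast.pipeline import default_rois


@pytest.fixture(scope="session")
def speckle_128():
    return make_speckle((128, 128), density=0.05, psf_sigma=1.2, seed=42)


def _small_spec(**overrides) -> PhantomSpec:
    """Quick 128 px / 10-frame homogeneous phantom for unit-level tests."""
    kw = dict(image_size_px=128, n_frames=10, seed=7)
    kw.update(overrides)
    return PhantomSpec(body=ElasticMaterial(10e3, 0.495), **kw)


@pytest.fixture(scope="session")
def small_spec():
    return _small_spec()


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return render_sequence(small_spec)


def _run(spec):
    ds = render_sequence(spec)
    cfg = RunConfig(geometry=spec.geometry,
                    rois=default_rois(spec.inclusion is not None))
    return ds, cfg, run_pipeline(ds.frames, ds.force_log, cfg)


@pytest.fixture(scope="session")
def hard_run():
    spec = hard_phantom(seed=1).fast()
    return (spec, *_run(spec))


@pytest.fixture(scope="session")
def soft_run():
    spec = soft_phantom(seed=2).fast()
    return (spec, *_run(spec))


@pytest.fixture(scope="session")
def inclusion_run():
    spec = inclusion_phantom(seed=3).fast()
    return (spec, *_run(spec))
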