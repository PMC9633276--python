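"""Shared fixtures: small deterministic phantoms and mask builders."""

import numpy as np
import pytest

import pvsmaps as p


@pytest.fixture(scope="session")
def small_phantom():
    """A 64-cube phantom with 8 tubes, noiseless, default blur."""
    spec = p.PhantomSpec(shape=(64, 64, 64), n_tubes=8, seed=5)
    vol, truth, tissue, table = p.generate_phantom(spec)
    return vol, truth, tissue, table


@pytest.fixture(scope="session")
def small_domain(small_phantom):
    _, _, tissue, _ = small_phantom
    return p.phantom_search_domain(tissue)


@pytest.fixture()
def mask_factory():
    def make(data, **kw):
        return p.Mask(np.asarray(data, dtype=bool), **kw)

    return make


def tiny_block_world(shape=(14, 14, 14), dark=((7, 7, 7),), base=0.7, dip=0.3):
    """A tiny uniform volume with hand-placed dark voxels and a full-cube
    search domain — the substrate for loop-oracle comparisons."""
    data = np.full(shape, base)
    for ijk in dark:
        data[ijk] = base - dip
    vol = p.Volume(data, id="tiny")
    everything = p.Mask(np.ones(shape, dtype=bool), label="search")
    wm = p.Mask(np.ones(shape, dtype=bool), label="WM")
    empty = p.Mask(np.zeros(shape, dtype=bool), label="ventricles")
    domain = p.SearchDomain(search=everything, wm=wm, excluded_ventricles=empty)
    return vol, domain
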