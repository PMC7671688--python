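import numpy as np
import pytest

from confluence import depths, surfaces
from confluence.synthetic import (
    ProfileModel,
    ToyConfluenceSpec,
    make_intensity_volume,
    make_toy_confluence,
)


@pytest.fixture(scope="session")
def toy():
    return make_toy_confluence(
        ToyConfluenceSpec(n_iso_rows=14, n_allo_rows=14, n_columns=8, seed=0)
    )


@pytest.fixture(scope="session")
def stitched(toy):
    bh = surfaces.find_bridgeheads(toy.allo_inner)
    matches = surfaces.match_bridgeheads_to_isocortex(bh, toy.allo_inner,
                                                      toy.iso_inner)
    model = surfaces.stitch_confluence(
        (toy.iso_inner, toy.iso_outer), (toy.allo_inner, toy.allo_outer),
        bh, matches)
    surfaces.compute_axis(model)
    return model


@pytest.fixture(scope="session")
def big_toy():
    """Finer toy used by the recovery-style tests."""
    return make_toy_confluence(
        ToyConfluenceSpec(n_iso_rows=30, n_allo_rows=30, n_columns=10, seed=1)
    )


@pytest.fixture(scope="session")
def big_model(big_toy):
    bh = surfaces.find_bridgeheads(big_toy.allo_inner)
    matches = surfaces.match_bridgeheads_to_isocortex(
        bh, big_toy.allo_inner, big_toy.iso_inner)
    model = surfaces.stitch_confluence(
        (big_toy.iso_inner, big_toy.iso_outer),
        (big_toy.allo_inner, big_toy.allo_outer), bh, matches)
    surfaces.compute_axis(model)
    return model


@pytest.fixture(scope="session")
def noisefree_profiles(stitched, toy):
    model = ProfileModel(noise_sd=0.0)
    vol, affine = make_intensity_volume(toy, model, 0.1)
    depth_set = depths.equivolumetric_surfaces(stitched, 16)
    return depths.sample_profiles(vol, affine, depth_set, stitched), model


@pytest.fixture(scope="session")
def big_profiles(big_model, big_toy):
    """Noisy (about 10 percent of dynamic range) profiles on the fine toy."""
    model = ProfileModel(noise_sd=1.5)
    vol, affine = make_intensity_volume(big_toy, model, 0.1, seed=7)
    depth_set = depths.equivolumetric_surfaces(big_model, 16)
    return depths.sample_profiles(vol, affine, depth_set, big_model), model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
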