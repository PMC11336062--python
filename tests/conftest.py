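"""Shared fixtures: one small synthetic island reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from vector_enm.config import RunConfig
from vector_enm.raster import EnvStack, RasterLayer
from vector_enm.simulate import (
    LandscapeSpec,
    generate_landscape,
    generate_survey,
    generate_virtual_species,
    preset_species_specs,
)


@pytest.fixture(scope="session")
def island():
    """A 100x100 synthetic island stack (10 m cells)."""
    return generate_landscape(LandscapeSpec(nrows=100, ncols=100, seed=11))


@pytest.fixture(scope="session")
def virtual_species(island):
    """The four preset virtual species on the shared island."""
    specs = preset_species_specs(n_presences=40, seed=11)
    return {name: generate_virtual_species(island, sp) for name, sp in specs.items()}


@pytest.fixture(scope="session")
def survey(island, virtual_species):
    """A multi-species survey table over the shared island."""
    return generate_survey(island, list(virtual_species.values()), seed=17)


@pytest.fixture()
def fast_config():
    """A light pipeline configuration for unit tests."""
    return RunConfig(
        seed=3,
        background_n=500,
        n_hinge_knots=4,
        n_null=20,
        n_permutations=3,
    )


def make_layer(values, kind="continuous", cell_size=10.0, name="layer",
               mask=None, labels=None, origin=(0.0, 0.0)):
    values = np.asarray(values)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return RasterLayer(name=name, kind=kind, values=values, nodata_mask=mask,
                       cell_size=cell_size, origin=origin, category_labels=labels)


@pytest.fixture()
def small_two_layer_stack():
    """A 5x5 stack with one continuous gradient and one categorical layer."""
    grad = np.arange(25, dtype=float).reshape(5, 5)
    cats = np.ones((5, 5), dtype=int)
    cats[2:, 2:] = 2
    return EnvStack(
        [
            make_layer(grad, name="gradient"),
            make_layer(cats, kind="categorical", name="habitat",
                       labels={1: "low", 2: "high"}),
        ]
    )
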