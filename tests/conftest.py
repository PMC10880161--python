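from collections import namedtuple

import pytest

import nomolog as nl

Built = namedtuple("Built", "model scales pm")


def build(model, p_max=100.0):
    """Full construction pipeline for a model: scales + probability map."""
    scales = nl.build_point_scales(model, p_max=p_max)
    return Built(model, scales, nl.build_probability_map(model, scales))


def random_built(seed, d=4, styles=("unit", "wide", "binary")):
    model = nl.random_model(nl.FixtureConfig(d=d, range_styles=styles, seed=seed))
    return build(model)


@pytest.fixture(scope="session")
def cmv():
    """The published CMV model, fully constructed."""
    return build(nl.cmv_model())


@pytest.fixture
def cmv_template(tmp_path):
    path = tmp_path / "cmv.csv"
    nl.write_model_template(nl.cmv_model(), path)
    return path
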