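import numpy as np
import pytest

from stressmet.model import (
    CompartmentDef,
    ModelSpec,
    ReactionDef,
    SpeciesDef,
    SubstrateDef,
    reference_model,
)


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture()
def linear_model():
    """dC/dt = vmax - k*C with closed-form steady state vmax/k."""
    return ModelSpec(
        name="linear",
        species=[SpeciesDef(id="c", initial=1.0)],
        compartments=[CompartmentDef(id="plasma", volume=1.0)],
        parameters={"vmax": 2.0, "k": 0.5},
        reactions=[
            ReactionDef(id="src", vmax="vmax", products={"c": 1}),
            ReactionDef(
                id="deg", vmax="k", substrates=[SubstrateDef(species="c", km=None)]
            ),
        ],
    )


@pytest.fixture()
def chain_model():
    """Mass-action chain: source -> a -> b -> sink (all linear steps)."""
    return ModelSpec(
        name="chain",
        species=[SpeciesDef(id="a", initial=1.0), SpeciesDef(id="b", initial=1.0)],
        compartments=[CompartmentDef(id="plasma", volume=1.0)],
        parameters={"v_in": 2.0, "k_ab": 1.0, "k_out": 0.5},
        reactions=[
            ReactionDef(id="source", vmax="v_in", products={"a": 1}),
            ReactionDef(
                id="a_to_b",
                vmax="k_ab",
                substrates=[SubstrateDef(species="a", km=None)],
                products={"b": 1},
            ),
            ReactionDef(
                id="b_out",
                vmax="k_out",
                substrates=[SubstrateDef(species="b", km=None)],
            ),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
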