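import pytest
from hypothesis import settings

import earmech as em
from earmech.model import MiddleEarModel

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def normal_model() -> MiddleEarModel:
    return em.build_normal_model()


@pytest.fixture(scope="session")
def normal_curve(normal_model):
    return em.transmission_curve(normal_model)


@pytest.fixture(scope="session")
def catalog():
    return em.scenario_catalog()


def make_sdof_model(k=1.0, m=1.0, c=1e-3, loss_factor=0.0, pressure=1.0):
    """Single-oscillator model: one free node on a spring to ground, driven
    directly, with the cochlear load acting as the (optional) damper."""
    return MiddleEarModel(
        materials={
            "spring": em.MaterialSpec(name="spring", young_modulus=k, loss_factor=loss_factor)
        },
        nodes=[
            em.NodeSpec(id="fp", position=(0.0, 0.0, 0.0), dofs=("x",)),
            em.NodeSpec(id="g", position=(1.0, 0.0, 0.0), dofs=()),
        ],
        elements=[
            em.ElasticElement(
                id="spring", node_a="fp", node_b="g", material="spring",
                cross_section_area=1.0, length=1.0,
            )
        ],
        inertias=[em.RigidInertia(body="malleus", mass=m, attached_nodes=("fp",))],
        drive=em.TympanicDrive(effective_area=1.0, pressure_pa=pressure, drive_node="fp"),
        cochlear_load=em.CochlearLoad(
            resistance=c, compliance=1e9, footplate_node="fp", footplate_area=1.0
        ),
    )


@pytest.fixture
def sdof_model():
    return make_sdof_model()
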