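import pytest

from portalwalk import FluidProperties, WalkConfig, build_tree


@pytest.fixture
def blood():
    """Bulk blood: density 1050 kg/m^3, viscosity 3.5 mPa s."""
    return FluidProperties(mass_density=1050.0, dynamic_viscosity=3.5e-3)


@pytest.fixture
def three_segment_descriptors():
    """Main trunk with left/right first-order branches; trunk diameter maximal."""
    return [
        {
            "id": "mpv",
            "name": "main_portal_vein",
            "diameter": 13.0,
            "length": 60.0,
            "parent": None,
            "mean_velocity": 0.26,
        },
        {
            "id": "left",
            "name": "left_branch",
            "diameter": 9.0,
            "length": 40.0,
            "parent": "mpv",
            "mean_velocity": 0.18,
        },
        {
            "id": "right",
            "name": "right_branch",
            "diameter": 8.0,
            "length": 40.0,
            "parent": "mpv",
            "mean_velocity": 0.16,
        },
    ]


@pytest.fixture
def three_segment_tree(three_segment_descriptors):
    return build_tree(three_segment_descriptors)


@pytest.fixture
def lattice_walk():
    """The 4-direction lattice walk (k = 1/90), the enumerable reference case."""
    return WalkConfig(k=1.0 / 90.0, step_length=1.0)
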