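import pytest

from intermtr import ProtocolParams, SliceGeometry, get_tissue


@pytest.fixture(scope="session")
def wm():
    return get_tissue("white_matter")


@pytest.fixture(scope="session")
def gm():
    return get_tissue("gray_matter")


@pytest.fixture(scope="session")
def saline():
    return get_tissue("saline")


@pytest.fixture(scope="session")
def phantom_geometry():
    """Slice geometry of the cylindrical-phantom acquisition (base offset 3840 Hz)."""
    return SliceGeometry(
        rf_bandwidth_hz=1600.0,
        slice_thickness_mm=4.0,
        interslice_gap_mm=5.6,
        slice_order="descending",
        gradient_polarity=1,
    )


@pytest.fixture(scope="session")
def fast_protocol(phantom_geometry):
    """Reduced-size protocol for generic property tests (short pulse trains)."""
    return ProtocolParams(
        geometry=phantom_geometry,
        tr=4.56e-3,
        te=2.28e-3,
        flip_deg=50.0,
        n_pe_steps=32,
        n_dummy_pe=8,
        pe_order="centric",
        rf_duration=1.0e-3,
        n_prior_slices=2,
        n_dummy_slices=2,
    )
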