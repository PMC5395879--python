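import numpy as np
import pytest

from airwaymech import OgdenMaterial, TissueLibrary, TracheaConfig, build_trachea_mesh


@pytest.fixture(scope="session")
def library() -> TissueLibrary:
    """The default tissue library (preterm-lamb fits + engineered mucosa)."""
    return TissueLibrary.default()


@pytest.fixture(scope="session")
def mucosa(library) -> OgdenMaterial:
    return library["mucosa"]


@pytest.fixture(scope="session")
def cartilage(library) -> OgdenMaterial:
    return library["cartilage"]


@pytest.fixture(scope="session")
def coarse_mesh_10():
    """Coarse 10 mm trachea mesh shared across geometry/analysis tests."""
    return build_trachea_mesh(TracheaConfig.coarse(diameter=10.0))


@pytest.fixture(scope="session")
def default_mesh_10():
    """Default-density 10 mm mesh (finer; used for mesh-quality checks)."""
    return build_trachea_mesh(TracheaConfig(diameter=10.0))
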