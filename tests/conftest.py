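import numpy as np
import pytest

from phenomet import synthetic as syn


@pytest.fixture(scope="session")
def side_tray():
    """One noise-free side view with senescent tissue on both plants."""
    spec = syn.SideViewSpec(
        plants=(
            syn.PlantSpec(height_px=120, area_px=800, senescent_fraction=0.2),
            syn.PlantSpec(height_px=90, area_px=500, senescent_fraction=0.1,
                          senescent_class="grey"),
        ),
        seed=11,
    )
    img, gt = syn.generate_side_view(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def top_tray():
    spec = syn.TopViewSpec(areas_px=(300, 450, 220, 1000), seed=12)
    img, gt = syn.generate_top_view(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def severe_metabolome():
    return syn.generate_metabolome(syn.MetabolomeSpec.severe_drought(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
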