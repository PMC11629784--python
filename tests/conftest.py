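import numpy as np
import pytest

from psam import (
    MarkerPanel,
    MultiplexImage,
    ReferenceLibrary,
    ReferencePseudoSpectrum,
    SimulationConfig,
    simulate_tissue,
)


@pytest.fixture
def tiny_library() -> ReferenceLibrary:
    """Three-marker library: one nucleus, two membrane references."""
    panel = MarkerPanel(markers=("DNA", "A", "B"), pixel_size_um=0.1507)
    return ReferenceLibrary(
        panel=panel,
        references=(
            ReferencePseudoSpectrum("nuc", "nucleus", np.array([1.0, 0, 0])),
            ReferencePseudoSpectrum("a cell", "membrane", np.array([0, 1.0, 0])),
            ReferencePseudoSpectrum("b cell", "membrane", np.array([0, 0.5, 1.0])),
        ),
    )


def make_image(data, names=None, pixel_size_um=0.1507):
    data = np.asarray(data, dtype=float)
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return MultiplexImage(data=data, channel_names=tuple(names),
                          pixel_size_um=pixel_size_um)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noiseless simulation with protrusions; exact ground truth."""
    cfg = SimulationConfig(
        seed=11, n_cells=40, image_size=(256, 256),
        noise_sd=0.0, autofluorescence_level=0.0,
        interstitial_protrusion_rate=0.5,
    )
    img, blank, truth = simulate_tissue(cfg)
    return cfg, img, blank, truth


@pytest.fixture(scope="session")
def noisy_sim():
    cfg = SimulationConfig(
        seed=5, n_cells=60, image_size=(320, 320),
        noise_sd=0.1, autofluorescence_level=0.0,
        interstitial_protrusion_rate=0.3,
    )
    img, blank, truth = simulate_tissue(cfg)
    return cfg, img, blank, truth
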