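import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from memprobe.synthetic import SyntheticConfig, generate_system


@pytest.fixture(scope="session")
def clean_system():
    """Thermal-noise system, no boundary frames: 2 peptides/leaflet."""
    cfg = SyntheticConfig(n_frames=60, noise=0.5, artifact_fraction=0.0, seed=101)
    return generate_system(cfg)


@pytest.fixture(scope="session")
def noise_free_system():
    """Exact planted geometry: zero noise, no boundary frames."""
    cfg = SyntheticConfig(n_frames=3, noise=0.0, artifact_fraction=0.0, seed=102)
    return generate_system(cfg)


@pytest.fixture(scope="session")
def dimer_system():
    """Planted mature dimer with exactly 16 interpeptide contacts."""
    cfg = SyntheticConfig(
        n_frames=8, noise=0.3, artifact_fraction=0.0,
        dimer=True, dimer_contacts=16, seed=103,
    )
    return generate_system(cfg)
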