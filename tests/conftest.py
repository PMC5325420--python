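import pytest

from crosstalksim import (
    ScreenConfig,
    combination_screen,
    single_drug_screen,
    stimulus_scan,
    strength_scan,
)


@pytest.fixture(scope="session")
def default_single():
    """Single-drug screen under the standard protocol (S0, dose 1, h=0.01)."""
    return single_drug_screen(ScreenConfig())


@pytest.fixture(scope="session")
def default_combo():
    """Combination screen under the standard protocol."""
    return combination_screen(ScreenConfig())


@pytest.fixture(scope="session")
def default_strength():
    """Strength scan on the geometric 1 -> 10 grid, standard protocol."""
    return strength_scan(ScreenConfig())


@pytest.fixture(scope="session")
def coarse_cfg():
    """Coarser RK4 step for the qualitative sweeps; RK4 at h=0.05 agrees
    with h=0.01 to well below any threshold used here."""
    return ScreenConfig(h=0.05)


@pytest.fixture(scope="session")
def coarse_stimulus_scan(coarse_cfg):
    return stimulus_scan(coarse_cfg)


@pytest.fixture(scope="session")
def coarse_combo(coarse_cfg):
    return combination_screen(coarse_cfg)
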