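import numpy as np
import pytest

from anisovdw.fitting import FitOptions, apply_exchange_threshold, fit_families
from anisovdw.geometry import build_hydrogen_halide, build_water
from anisovdw.synthetic import generate_surface, paper_mimic_config


@pytest.fixture(scope="session")
def hi():
    return build_hydrogen_halide("I")


@pytest.fixture(scope="session")
def water():
    return build_water()


@pytest.fixture(scope="session")
def hi_mimic_surface():
    """Scaled-down noisy HI mimic surface (0.25 A spacing) for fitting tests."""
    config = paper_mimic_config("HI", seed=11, spacing=0.25)
    return apply_exchange_threshold(generate_surface(config))


@pytest.fixture(scope="session")
def hi_mimic_fits(hi_mimic_surface):
    """Spherical, cos and vsite exchange fits sharing one baseline."""
    return fit_families(
        hi_mimic_surface,
        ["spherical", "cos", "vsite"],
        "exchange",
        options=FitOptions(seed=11, n_starts=8, vsite_free_distance=True),
    )


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )
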