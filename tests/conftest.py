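import numpy as np
import pytest

from rubbergrade import Grade, GRADE_TABLE, SceneConfig, make_scene

# Printed per-grade reference values: mean RGB -> XYZ (raw matrix path),
# CIELAB (sRGB-piecewise path) and yellowness index (table-consistent
# coefficients on the raw path).
REFERENCE_ROWS = {
    Grade.WHITE_CREPE: {
        "rgb": (124.7, 122.3, 120.2),
        "xyz": (116.9, 122.7, 131.3),
        "lab": (51.5, 0.52, 1.43),
        "yi": 8.52,
    },
    Grade.STR5: {
        "rgb": (129.0, 107.6, 43.2),
        "xyz": (99.5, 107.5, 56.4),
        "lab": (46.3, 0.61, 38.1),
        "yi": 62.84,
    },
    Grade.STR5L: {
        "rgb": (128.9, 109.9, 40.9),
        "xyz": (99.8, 109.0, 54.5),
        "lab": (46.9, -0.88, 39.8),
        "yi": 64.31,
    },
    Grade.RSS3: {
        "rgb": (80.4, 59.1, 21.2),
        "xyz": (58.1, 60.9, 28.7),
        "lab": (26.5, 4.85, 26.4),
        "yi": 72.15,
    },
    Grade.RSS5: {
        "rgb": (27.6, 25.0, 19.4),
        "xyz": (23.8, 25.2, 22.0),
        "lab": (8.86, 0.02, 4.17),
        "yi": 28.79,
    },
}

ALL_GRADES = list(REFERENCE_ROWS)


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic white-crepe acquisition, shared across tests."""
    return make_scene(SceneConfig(grade=Grade.WHITE_CREPE, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
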