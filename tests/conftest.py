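import numpy as np
import pytest

from oneback.metrics import MetricConfig
from oneback.shapes import (
    ClosedCurve,
    GeneratorConfig,
    generate_stimulus_set,
    resample_perimeter,
)


def circle_outline(radius_mm, spacing_mm=0.1, n_dense=4000, center=(0.0, 0.0)):
    th = np.linspace(0.0, 2 * np.pi, n_dense, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius_mm * np.cos(th), center[1] + radius_mm * np.sin(th)]
    )
    return resample_perimeter(ClosedCurve(points=pts), spacing_mm)


def square_outline(side_mm=10.0, spacing_mm=0.1):
    pts = np.array([[0, 0], [side_mm, 0], [side_mm, side_mm], [0, side_mm]], float)
    return resample_perimeter(ClosedCurve(points=pts), spacing_mm)


def rectangle_outline(w_mm, h_mm, spacing_mm=0.1):
    pts = np.array([[0, 0], [w_mm, 0], [w_mm, h_mm], [0, h_mm]], float)
    return resample_perimeter(ClosedCurve(points=pts), spacing_mm)


@pytest.fixture(scope="session")
def circle():
    return circle_outline(12.5)


@pytest.fixture(scope="session")
def square():
    return square_outline()


@pytest.fixture(scope="session")
def fast_config():
    """Coarse but dominance-preserving metric config for bulk simulations."""
    return MetricConfig(rotation_step_deg=15.0, search_points=128, turning_grid=256)


@pytest.fixture(scope="session")
def shape_pool():
    """A 48-shape stimulus set shared across tests (seeded, deterministic)."""
    shapes, manifest = generate_stimulus_set(48, GeneratorConfig(seed=42))
    return shapes


@pytest.fixture(scope="session")
def small_pool():
    shapes, _ = generate_stimulus_set(8, GeneratorConfig(seed=7))
    return shapes
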