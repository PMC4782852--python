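import numpy as np
import pytest

from shagginess.phantom import CrossSectionSpec, PhantomSpec, rasterize_phantom


def circle_contour_points(R=10.0, n=720, center=(0.0, 0.0)):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)])


def ellipse_contour_points(a=15.0, b=10.0, n=720):
    """Ellipse sampled uniformly in arc length (via dense parametric resampling)."""
    t = np.linspace(0.0, 2 * np.pi, 200_001)
    x, y = a * np.cos(t), b * np.sin(t)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    si = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(si, s, x), np.interp(si, s, y)])


@pytest.fixture(scope="session")
def small_lobed_phantom():
    """Short lobed tube shared by pipeline-level tests (60 mm keeps runs fast)."""
    section = CrossSectionSpec("lobed", R=10.0, epsilon=0.10, k=6)
    return rasterize_phantom(PhantomSpec(path="straight", length_mm=60.0, section=section))


@pytest.fixture(scope="session")
def small_circle_phantom():
    return rasterize_phantom(
        PhantomSpec(path="straight", length_mm=60.0, section=CrossSectionSpec("circle", R=10.0))
    )
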