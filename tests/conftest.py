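import numpy as np
import pytest
from hypothesis import settings

import follistat as fs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def square_window():
    """0.5 x 0.5 mm rectangle window on a coarse 2 um grid (fast setcov)."""
    return fs.rectangle_window(500.0, 500.0, 2.0, label="FL")


@pytest.fixture(scope="session")
def small_window():
    """0.25 x 0.25 mm rectangle window at the instrument's 0.74 um grid."""
    return fs.rectangle_window(250.0, 250.0, 0.74, label="FL")


@pytest.fixture(scope="session")
def follicle_windows():
    """One 400 x 400 um elliptical follicle split into LZ/DZ at the 0.74 um grid."""
    return fs.make_follicle_window(400.0, 400.0, 0.5, 0.74)


def quadrat_chi2_pvalue(pp: fs.PointPattern, k: int = 5) -> float:
    """Chi-square quadrat test of CSR on a rectangular window (test oracle).

    Splits the window into k x k equal quadrats and compares observed counts
    with the equal expectation, conditional on n.
    """
    from scipy import stats

    x0, y0, x1, y1 = pp.window.bbox_um()
    xi = np.clip(((pp.points[:, 0] - x0) / (x1 - x0) * k).astype(int), 0, k - 1)
    yi = np.clip(((pp.points[:, 1] - y0) / (y1 - y0) * k).astype(int), 0, k - 1)
    counts = np.bincount(yi * k + xi, minlength=k * k)
    expected = pp.n / (k * k)
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, k * k - 1))


@pytest.fixture(scope="session")
def quadrat_test():
    return quadrat_chi2_pvalue
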