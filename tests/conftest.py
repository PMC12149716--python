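"""Shared fixtures and independent brute-force oracles.

The brute-force signal oracle integrates D*h on uniform midpoint grids in
coordinates mapped to remove the square-root edge behaviour of circular
footprints (rho = r sin t); it evaluates the footprint height function
directly and shares no quadrature nodes or weights with the implementation.
"""

import numpy as np
import pytest

from smallfield import workflow
from smallfield.response import SensitiveVolume, footprint_height, measured_signal


def brute_signal(model, geom: SensitiveVolume, x0=0.0, y0=0.0, n=400):
    """Midpoint-grid (n x n) footprint integral of D*h in mapped coordinates."""
    r, L = geom.radius, geom.length
    circular = geom.shape == "sphere" or geom.orientation == "parallel"

    def accum(X, Y, W):
        return float(np.sum(W * footprint_height(geom, X, Y)
                            * model.dose(X + x0, Y + y0)))

    if circular:
        t = (np.arange(n) + 0.5) * (0.5 * np.pi / n)
        th = (np.arange(n) + 0.5) * (2.0 * np.pi / n)
        rho = r * np.sin(t)
        jac = r * np.cos(t) * rho * (0.5 * np.pi / n) * (2.0 * np.pi / n)
        X = rho[:, None] * np.cos(th)[None, :]
        Y = rho[:, None] * np.sin(th)[None, :]
        return accum(X, Y, np.broadcast_to(jac[:, None], X.shape))

    # perpendicular orientations: x via r sin t, y uniform per sub-region
    t = -0.5 * np.pi + (np.arange(n) + 0.5) * (np.pi / n)
    x = r * np.sin(t)
    jx = r * np.cos(t) * (np.pi / n)

    def rect_part(y_lo, y_hi):
        y = y_lo + (np.arange(n) + 0.5) * ((y_hi - y_lo) / n)
        X, Y = np.meshgrid(x, y, indexing="ij")
        W = np.broadcast_to((jx * ((y_hi - y_lo) / n))[:, None], X.shape)
        return accum(X, Y, W)

    if geom.shape == "cylinder":
        return rect_part(-L / 2.0, L / 2.0)

    # hemisphere-tipped cylinder, perpendicular: cylinder rectangle plus cap
    s = geom.centroid_shift
    total = rect_part(-L / 2.0 - s, L / 2.0 - s)
    th = (np.arange(n) + 0.5) * (np.pi / n)  # cap half-disk, y' >= 0
    tt = (np.arange(n) + 0.5) * (0.5 * np.pi / n)
    rho = r * np.sin(tt)
    jac = r * np.cos(tt) * rho * (0.5 * np.pi / n) * (np.pi / n)
    X = rho[:, None] * np.cos(th)[None, :]
    Y = rho[:, None] * np.sin(th)[None, :] + L / 2.0 - s
    total += accum(X, Y, np.broadcast_to(jac[:, None], X.shape))
    return total


def brute_window_average(model, geom, window, x0=0.0, y0=0.0, n=41):
    """Midpoint average of the (implementation) signal over the square window."""
    ux = (x0 if window.wx == 0
          else x0 - window.wx + (np.arange(n) + 0.5) * (2 * window.wx / n))
    uy = (y0 if window.wy == 0
          else y0 - window.wy + (np.arange(n) + 0.5) * (2 * window.wy / n))
    ux = np.atleast_1d(ux)
    uy = np.atleast_1d(uy)
    vals = [measured_signal(model, geom, xi, yi) for xi in ux for yi in uy]
    return float(np.mean(vals))


def random_concave_model(rng, halfwidth=10.0):
    from smallfield.geometry import DoseProfileModel

    a2 = -10 ** rng.uniform(-3, -1.3)  # curvature 0.001..0.05 per mm^2
    b2 = -10 ** rng.uniform(-3, -1.3)
    a1 = rng.uniform(-0.005, 0.005)
    b1 = rng.uniform(-0.005, 0.005)
    return DoseProfileModel(1.0, a1, a2, rng.uniform(0.8, 1.2), b1, b2,
                            valid_halfwidth=halfwidth)


ALL_GEOMETRIES = [
    SensitiveVolume("sphere", 1.0, 0.0, "parallel"),
    SensitiveVolume("sphere", 1.0, 0.0, "perpendicular"),
    SensitiveVolume("cylinder", 0.5, 1.0, "parallel"),
    SensitiveVolume("cylinder", 0.5, 1.0, "perpendicular"),
    SensitiveVolume("cylinder_hemisphere_tip", 1.0, 2.6, "parallel"),
    SensitiveVolume("cylinder_hemisphere_tip", 1.0, 2.6, "perpendicular"),
]


@pytest.fixture(scope="session")
def noisy_study():
    """One synthetic study at the study conditions (0.1% noise, 3 repeats)."""
    return workflow.make_study(noise_rel=0.001, n_repeats=3)


@pytest.fixture(scope="session")
def clean_study():
    """Zero-noise study for exact round-trip checks."""
    return workflow.make_study(noise_rel=0.0, n_repeats=1)
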