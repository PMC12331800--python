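import math

import numpy as np
import pytest

from numblind import stimulus_design as sd


def rasterize_luminance(side, n_px: int = 500, model: str = "rgb_mean") -> float:
    """Brute-force pixel-average luminance oracle.

    Rasterizes one display side onto an n_px x n_px canvas of area equal to
    the void (32 units) centered on the square, classifying every pixel
    center as dot, square or background, and averages the per-pixel
    luminance. Independent of the analytic area bookkeeping in
    stimulus_design.mean_luminance.
    """
    L = math.sqrt(sd.VOID_AREA)
    xs = (np.arange(n_px) + 0.5) / n_px * L - L / 2
    X, Y = np.meshgrid(xs, xs)

    def lum(rgb):
        return float(np.mean(rgb))

    lum_bg = lum(side.background_color)
    lum_sq = lum(side.square_color) if side.square_drawn else lum_bg
    img = np.full((n_px, n_px), lum_bg)

    half = math.sqrt(side.square_area) / 2
    c, s = math.cos(side.square_rotation), math.sin(side.square_rotation)
    U = c * X + s * Y  # rotate into the square's frame
    V = -s * X + c * Y
    in_square = (np.abs(U) <= half) & (np.abs(V) <= half)
    img[in_square] = lum_sq

    r2 = side.dot_area / math.pi
    dot_lum = {"white": 1.0, "black": 0.0, "ring": 0.5}
    for x, y, color in side.dots:
        img[(X - x) ** 2 + (Y - y) ** 2 <= r2] = dot_lum[color]
    return float(img.mean())


@pytest.fixture(scope="session")
def small_cohorts():
    """One modest cohort per architecture (shared across tests)."""
    from numblind import observer_sim as obs

    out = {}
    for arch, tpl in [
        ("number_primary", obs.number_primary_observer()),
        ("density_primary", obs.density_primary_observer()),
    ]:
        cfg = obs.CohortConfig(n_participants=60, seed=20240917)
        out[arch] = obs.simulate_cohort(cfg, tpl)
    return out
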