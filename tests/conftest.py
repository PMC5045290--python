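import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def feret_bruteforce(mask: np.ndarray) -> float:
    """Max pairwise distance over ALL corner points of boundary pixels.

    O(n^2) reference for the convex-hull implementation; usable on masks
    up to a few hundred pixels.
    """
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    boundary = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3)))
    ys, xs = np.nonzero(boundary)
    pts = []
    for y, x in zip(ys, xs):
        for dy in (-0.5, 0.5):
            for dx in (-0.5, 0.5):
                pts.append((x + dx, y + dy))
    pts = np.asarray(pts)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def onset_bruteforce(t, y, direction, min_arm=2):
    """Exhaustive changepoint search with an explicit per-candidate fit.

    For every candidate breakpoint tb the continuous two-segment model is
    parameterized as (value at tb, pre slope, post slope) and solved by
    least squares in that basis — an independent path from the package's
    hinge parameterization.  Returns (t_break, sse) or (None, None).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    sign = 1.0 if direction == "increase" else -1.0
    scale = max(np.ptp(y), np.abs(y).max(), 1.0) / max(np.ptp(t), 1.0)
    best = None
    for j in range(min_arm - 1, t.size - min_arm):
        tb = t[j]
        pre = np.minimum(t - tb, 0.0)
        post = np.maximum(t - tb, 0.0)
        design = np.column_stack([np.ones_like(t), pre, post])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        s1, s2 = coef[1], coef[2]
        if sign * (s2 - s1) <= 1e-9 * scale:
            continue
        resid = y - design @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[1] - 1e-12 * (1 + best[1]):
            best = (float(tb), sse)
    return best if best is not None else (None, None)


def random_blob(rng: np.random.Generator, n_target: int = 120) -> np.ndarray:
    """Random connected pixel blob grown from a seed pixel."""
    size = 32
    mask = np.zeros((size, size), bool)
    frontier = [(size // 2, size // 2)]
    mask[frontier[0]] = True
    n = 1
    while n < n_target and frontier:
        y, x = frontier[rng.integers(len(frontier))]
        dy, dx = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        ny, nx = y + dy, x + dx
        if 0 <= ny < size and 0 <= nx < size and not mask[ny, nx]:
            mask[ny, nx] = True
            frontier.append((ny, nx))
            n += 1
    return mask


@pytest.fixture
def feret_oracle():
    return feret_bruteforce


@pytest.fixture
def onset_oracle():
    return onset_bruteforce


@pytest.fixture
def blob_factory():
    return random_blob


# ---------------------------------------------------------------------------
# Shared synthetic inputs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noiseless_ph():
    """Noiseless default pH series with its ground truth."""
    from hypoquant import PHSeriesConfig, generate_ph_series

    return generate_ph_series(PHSeriesConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_growth():
    """Noiseless, jitter-free elongation series with its ground truth."""
    from hypoquant import GrowthSeriesConfig, generate_elongation_series

    cfg = GrowthSeriesConfig(length_noise_sd_px=0.0, angle_jitter_deg=0.0)
    return generate_elongation_series(cfg)
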