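import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_line_image():
    """Factory: clean straight Gaussian-profile line at a given angle.

    Returns (image, (cy, cx, theta_rad)); the line passes through
    (cy, cx) with direction theta and is rendered with cross-section
    sd = width/2 and centre-line peak `peak`.
    """
    import math

    import scipy.ndimage as ndi

    def make(theta_deg, shape=(128, 128), width=3.0, peak=100.0, length=100,
             centre_offset=0.3):
        H, W = shape
        cy, cx = H / 2 + centre_offset, W / 2
        th = math.radians(theta_deg)
        s = np.linspace(-length / 2, length / 2, int(length * 4))
        ys = cy + s * math.sin(th)
        xs = cx + s * math.cos(th)
        sig = width / 2
        canvas = np.zeros(shape)
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        fy = ys - y0
        fx = xs - x0
        w = peak * math.sqrt(2 * math.pi) * sig * (s[1] - s[0])
        for dy, dx, ww in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                           (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
            np.add.at(canvas, (y0 + dy, x0 + dx), w * ww)
        return ndi.gaussian_filter(canvas, sig, mode="constant"), (cy, cx, th)

    return make


def brute_force_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Independent rolling-ball background: explicit-loop grayscale
    opening by a spherical-cap structuring element, edge-clamped."""
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy * dy + dx * dx
    fp = d2 <= r * r
    h = np.zeros_like(d2, float)
    h[fp] = np.sqrt(r * r - d2[fp])
    offs = [(int(a), int(b), h[a + r, b + r])
            for a in range(-r, r + 1) for b in range(-r, r + 1) if fp[a + r, b + r]]
    pad = np.pad(img.astype(float), r, mode="edge")
    PH, PW = pad.shape

    def sweep(src, sign):
        out = np.full((PH, PW), sign * np.inf)
        for a, b, hh in offs:
            ys = np.clip(np.arange(PH) + a, 0, PH - 1)
            xs = np.clip(np.arange(PW) + b, 0, PW - 1)
            shifted = src[np.ix_(ys, xs)]
            if sign > 0:  # erosion: min(src(p+o) - h(o))
                out = np.minimum(out, shifted - hh)
            else:  # dilation: max(src(p+o) + h(o))
                out = np.maximum(out, shifted + hh)
        return out

    eroded = sweep(pad, +1)
    opened = sweep(eroded, -1)
    return opened[r:-r, r:-r]


def feret_all_pairs(points: np.ndarray):
    """O(n^2) brute-force Feret diameter and angle (degrees from the
    column axis in [0, 180)), ties resolved to the first index pair."""
    import math

    pts = np.asarray(points, float)
    best = -1.0
    pair = (0, 0)
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            d2 = float((pts[i, 0] - pts[j, 0]) ** 2 + (pts[i, 1] - pts[j, 1]) ** 2)
            if d2 > best:
                best = d2
                pair = (i, j)
    p1, p2 = pts[pair[0]], pts[pair[1]]
    ang = math.degrees(math.atan2(p2[0] - p1[0], p2[1] - p1[1])) % 180.0
    return math.sqrt(best), ang
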