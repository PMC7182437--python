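import numpy as np
import pytest
import trimesh

from kneessm import synthetic as syn


@pytest.fixture(scope="session")
def template():
    """Canonical calibrated neutral knee, shared across tests."""
    return syn.build_template()


@pytest.fixture(scope="session")
def small_template():
    """Low-resolution template for registration-heavy tests."""
    return syn.build_template(resolution=0.35)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere():
    return trimesh.creation.icosphere(subdivisions=3)  # 642 vertices, unit radius


def point_triangle_distance(p, a, b, c):
    """Independent per-pair closest-distance oracle (projected clamping).

    Minimizes |p - (a + s e0 + t e1)| over the triangle via the closed-form
    region analysis of the quadratic in (s, t).
    """
    e0, e1 = b - a, c - a
    d = a - p
    aa, bb, cc = e0 @ e0, e0 @ e1, e1 @ e1
    dd, ee = e0 @ d, e1 @ d
    det = aa * cc - bb * bb
    s, t = bb * ee - cc * dd, bb * dd - aa * ee
    if s + t <= det:
        if s < 0:
            if t < 0:  # region 4
                if dd < 0:
                    s, t = min(max(-dd / aa, 0.0), 1.0), 0.0
                else:
                    s, t = 0.0, min(max(-ee / cc, 0.0), 1.0)
            else:  # region 3
                s, t = 0.0, min(max(-ee / cc, 0.0), 1.0)
        elif t < 0:  # region 5
            s, t = min(max(-dd / aa, 0.0), 1.0), 0.0
        else:  # region 0
            s, t = s / det, t / det
    else:
        if s < 0:  # region 2
            tmp0, tmp1 = bb + dd, cc + ee
            if tmp1 > tmp0:
                numer, denom = tmp1 - tmp0, aa - 2 * bb + cc
                s = min(max(numer / denom, 0.0), 1.0)
                t = 1.0 - s
            else:
                s, t = 0.0, min(max(-ee / cc, 0.0), 1.0)
        elif t < 0:  # region 6
            tmp0, tmp1 = bb + ee, aa + dd
            if tmp1 > tmp0:
                numer, denom = tmp1 - tmp0, aa - 2 * bb + cc
                t = min(max(numer / denom, 0.0), 1.0)
                s = 1.0 - t
            else:
                s, t = min(max(-dd / aa, 0.0), 1.0), 0.0
        else:  # region 1
            numer = cc + ee - bb - dd
            if numer <= 0:
                s = 0.0
            else:
                denom = aa - 2 * bb + cc
                s = min(max(numer / denom, 0.0), 1.0)
            t = 1.0 - s
    q = a + s * e0 + t * e1
    return float(np.linalg.norm(p - q))
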