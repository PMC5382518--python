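import numpy as np
import pytest

import civstrain as cs


@pytest.fixture(scope="session")
def small_spec():
    return cs.GridSpec(image_size=96, cell_size=11, line_width=4)


@pytest.fixture(scope="session")
def small_grid(small_spec):
    return cs.generate_synthetic_grid(small_spec)


@pytest.fixture(scope="session")
def small_flow():
    return cs.AnalyticFlow(0.01, 0.02, center=(48.0, 48.0))


@pytest.fixture(scope="session")
def small_pair(small_grid, small_flow):
    return small_grid, cs.warp_image(small_grid, small_flow)


@pytest.fixture(scope="session")
def small_params():
    return cs.CivParams(correlation_box=15, search_box=31)


@pytest.fixture(scope="session")
def small_fit(small_pair, small_params):
    img1, img2 = small_pair
    return cs.CIVModel(img1, img2, small_params).fit()


@pytest.fixture(scope="session")
def tagged_image():
    return cs.generate_tagged_image(112, 7, directions=2)


@pytest.fixture(scope="session")
def ncc_bruteforce():
    """Exhaustive zero-mean NCC search; independent of the estimator."""

    def search(img1, img2, center, cb, sb):
        cx, cy = center
        hc, hs = cb // 2, sb // 2
        t = img1[cy - hc : cy - hc + cb, cx - hc : cx - hc + cb]
        t = t - t.mean()
        best, arg = -np.inf, None
        for dv in range(-(hs - hc), hs - hc + 1):
            for du in range(-(hs - hc), hs - hc + 1):
                r0, c0 = cy + dv - hc, cx + du - hc
                if (r0 < 0 or c0 < 0 or r0 + cb > img2.shape[0]
                        or c0 + cb > img2.shape[1]):
                    continue
                p = img2[r0 : r0 + cb, c0 : c0 + cb]
                p = p - p.mean()
                denom = np.sqrt((t ** 2).sum() * (p ** 2).sum())
                if denom == 0:
                    continue
                val = (t * p).sum() / denom
                if val > best + 1e-12:
                    best, arg = val, (du, dv)
        return arg, best

    return search


@pytest.fixture(scope="session")
def analytic_dense():
    """Dense analytic displacement on a 128x128 frame about its centre."""
    flow = cs.AnalyticFlow(center=(64.0, 64.0))
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    u, v = cs.analytic_displacement(xx, yy, flow)
    return flow, u, v
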