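import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def speckle_image():
    """Speckle texture with ~1 px correlation width, good PIV tracer field."""
    rng = np.random.default_rng(20240917)
    return ndimage.gaussian_filter(rng.random((256, 256)), 1.0)


def brute_force_autocorrelation(field):
    """O(N^2) double-loop oracle for the nematic autocorrelation.

    Groups pairs by exact squared lattice distance, mirroring the stated
    distance-class definition, but via plain Python loops independent of
    the vectorised implementation.
    """
    rr, cc = np.nonzero(field.mask)
    th = np.deg2rad(field.theta[rr, cc])
    sums, counts = {}, {}
    n = len(rr)
    for i in range(n):
        for j in range(i, n):
            k = (int(rr[i]) - int(rr[j])) ** 2 + (int(cc[i]) - int(cc[j])) ** 2
            val = 2.0 * np.cos(th[i] - th[j]) ** 2 - 1.0
            sums[k] = sums.get(k, 0.0) + val
            counts[k] = counts.get(k, 0) + 1
    ks = sorted(sums)
    d = np.sqrt(np.array(ks, dtype=float))
    c = np.array([sums[k] / counts[k] for k in ks])
    return d, c


def brute_force_local_order(field, window=4):
    """Per-window order parameter by direct enumeration."""
    h, w = field.shape
    out = np.full((h - window + 1, w - window + 1), np.nan)
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            ths = []
            for a in range(window):
                for b in range(window):
                    if field.mask[i + a, j + b]:
                        ths.append(field.theta[i + a, j + b])
            if len(ths) < 2:
                continue
            z = np.mean([np.exp(2j * np.deg2rad(t)) for t in ths])
            out[i, j] = abs(z)
    return out
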