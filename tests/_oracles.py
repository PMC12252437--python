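"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the SSIM oracle is
a literal per-voxel evaluation of the windowed formula on padded
arrays, and the MI oracle is a direct histogram computation.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def ssim_bruteforce(x, y, dynamic_range, sigma=1.5, half_width=5, k1=0.01, k2=0.03):
    """Mean SSIM by literal evaluation of the windowed formula per voxel."""
    hw = half_width
    ax = np.arange(-hw, hw + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    w = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    w /= w.sum()
    xp = np.pad(np.asarray(x, np.float64), hw, mode="edge")
    yp = np.pad(np.asarray(y, np.float64), hw, mode="edge")
    win = (2 * hw + 1,) * 3
    X = sliding_window_view(xp, win)
    Y = sliding_window_view(yp, win)
    ux = np.einsum("abcijk,ijk->abc", X, w)
    uy = np.einsum("abcijk,ijk->abc", Y, w)
    vx = np.einsum("abcijk,ijk->abc", X * X, w) - ux**2
    vy = np.einsum("abcijk,ijk->abc", Y * Y, w) - uy**2
    cov = np.einsum("abcijk,ijk->abc", X * Y, w) - ux * uy
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cov + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    return float(s.mean())


def mutual_information_bruteforce(x, y, bins=64):
    """MI in nats from an explicit joint histogram, summed bin by bin."""
    x = np.asarray(x, np.float64).ravel()
    y = np.asarray(y, np.float64).ravel()
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    mi = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            pij = joint[i, j] / n
            if pij > 0:
                mi += pij * np.log(pij / (px[i] * py[j]))
    return float(mi)
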