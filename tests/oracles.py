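"""Independent brute-force SLATM oracle used to cross-check the package.

Deliberately unoptimized: plain Python loops over beads and triplets, with
the Gaussian kernel evaluated through scipy's normal pdf.  Shares no code
with ``cgslatm.slatm``.
"""

import math

import numpy as np
from scipy.stats import norm


def kernel(value, centers, sigma, width, fold_edges=None):
    g = norm.pdf(centers, loc=value, scale=sigma)
    if fold_edges is not None:
        lo, hi = fold_edges
        g = g + norm.pdf(centers, loc=2 * lo - value, scale=sigma)
        g = g + norm.pdf(centers, loc=2 * hi - value, scale=sigma)
    return g * width


def brute_force_two_body(positions, types, zmap, center, neighbor_type, params):
    centers = (np.arange(params.n_bins_r) + 0.5) * params.bin_width_r
    hist = np.zeros(params.n_bins_r)
    zi = zmap[types[center]]
    for j in range(len(positions)):
        if j == center or types[j] != neighbor_type:
            continue
        r = math.dist(positions[center], positions[j])
        if r > params.r_cutoff:
            continue
        w = 0.5 * zi * zmap[types[j]] / r**6
        hist += w * kernel(r, centers, params.sigma_r, params.bin_width_r)
    return hist


def _angle(a, b, c):
    """Interior angle at vertex b of triangle a-b-c."""
    u, v = np.asarray(a) - b, np.asarray(c) - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.acos(max(-1.0, min(1.0, cos)))


def brute_force_three_body(positions, types, zmap, center, pair, params):
    centers = (np.arange(params.n_bins_theta) + 0.5) * params.bin_width_theta
    support = params.n_bins_theta * params.bin_width_theta
    hist = np.zeros(params.n_bins_theta)
    tj, tk = pair
    zi = zmap[types[center]]
    n = len(positions)
    seen = set()
    for j in range(n):
        for k in range(n):
            if len({center, j, k}) != 3:
                continue
            if types[j] != tj or types[k] != tk:
                continue
            if frozenset((j, k)) in seen:
                continue
            seen.add(frozenset((j, k)))
            rij = math.dist(positions[center], positions[j])
            rik = math.dist(positions[center], positions[k])
            if rij > params.r_cutoff or rik > params.r_cutoff:
                continue
            rjk = math.dist(positions[j], positions[k])
            ti = _angle(positions[j], positions[center], positions[k])
            taj = _angle(positions[center], positions[j], positions[k])
            tak = _angle(positions[center], positions[k], positions[j])
            geom = 1.0 + 3.0 * math.cos(ti) * math.cos(taj) * math.cos(tak)
            v = (
                (1.0 / 3.0)
                * zi
                * zmap[tj]
                * zmap[tk]
                * geom
                / (rij * rik * rjk) ** 3
            )
            hist += v * kernel(
                ti,
                centers,
                params.sigma_theta,
                params.bin_width_theta,
                fold_edges=(0.0, support),
            )
    return hist
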