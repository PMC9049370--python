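"""Independent brute-force reference implementations used only by tests.

These deliberately favour literal, loop-based evaluation of the
definitions over vectorization so that they stay independent of the
library code paths they check.
"""

import numpy as np


def clbp_brute_force(gray, P=8, R=1.0, magnitude_threshold_mode="local"):
    """Literal per-pixel evaluation of the CLBP sign/magnitude/center codes.

    Shares only the declared sampling convention with the library:
    neighbor p at angle 2πp/P starting at (0, +R), counter-clockwise in
    image coordinates, bilinear interpolation, offsets snapped to
    integers within 1e-6.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    b = int(np.ceil(R))
    offsets = []
    for p in range(P):
        dy = -R * np.sin(2 * np.pi * p / P)
        dx = R * np.cos(2 * np.pi * p / P)
        if abs(dy - round(dy)) < 1e-6:
            dy = round(dy)
        if abs(dx - round(dx)) < 1e-6:
            dx = round(dx)
        offsets.append((dy, dx))

    def sample(y, x):
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        ty, tx = y - y0, x - x0
        value = 0.0
        for sy, wy in ((y0, 1 - ty), (y0 + 1, ty)):
            for sx, wx in ((x0, 1 - tx), (x0 + 1, tx)):
                if wy * wx > 0:
                    value += wy * wx * gray[sy, sx]
        return value

    def step(x):
        return 1 if x >= 0 else 0

    centers = [gray[y, x] for y in range(b, h - b) for x in range(b, w - b)]
    g_n = float(np.mean(centers))
    all_mags = []
    per_pixel = []
    for y in range(b, h - b):
        for x in range(b, w - b):
            gc = gray[y, x]
            gps = [sample(y + dy, x + dx) for dy, dx in offsets]
            mags = [abs(gp - gc) for gp in gps]
            all_mags.extend(mags)
            per_pixel.append((y, x, gc, gps, mags))
    global_dc = float(np.mean(all_mags))

    S = np.zeros((h - 2 * b, w - 2 * b), dtype=np.int64)
    M = np.zeros_like(S)
    C = np.zeros_like(S)
    for y, x, gc, gps, mags in per_pixel:
        d_c = float(np.mean(mags)) if magnitude_threshold_mode == "local" else global_dc
        S[y - b, x - b] = sum(step(gp - gc) << p for p, gp in enumerate(gps))
        M[y - b, x - b] = sum(step(m - d_c) << p for p, m in enumerate(mags))
        C[y - b, x - b] = step(gc - g_n)
    return S, M, C


def correlogram_brute_force(indexed, distances, n_colors):
    """Exhaustive ordered-pair enumeration of the color auto-correlogram."""
    indexed = np.asarray(indexed)
    h, w = indexed.shape
    out = np.zeros((n_colors, len(distances)))
    for ki, k in enumerate(distances):
        match = np.zeros(n_colors)
        total = np.zeros(n_colors)
        for y1 in range(h):
            for x1 in range(w):
                c1 = indexed[y1, x1]
                for y2 in range(h):
                    for x2 in range(w):
                        if max(abs(y1 - y2), abs(x1 - x2)) == k:
                            total[c1] += 1
                            if indexed[y2, x2] == c1:
                                match[c1] += 1
        nz = total > 0
        out[nz, ki] = match[nz] / total[nz]
    return out.ravel()


def auc_pairwise(scores, positive):
    """AUC as P(score_pos > score_neg) + ½·P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos = scores[positive]
    neg = scores[~positive]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def soft_threshold_solution(W, v, lam):
    """Closed-form non-negative LASSO solution for orthonormal columns."""
    W = np.asarray(W, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    return np.maximum(0.0, W.T @ v - lam)
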