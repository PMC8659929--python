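"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plain sliding-window
min/max loops and an iterate-until-stable geodesic dilation, with the same
boundary conventions (erosion pads +inf, dilation pads -inf, reconstruction
is geodesic with 8-connectivity and no padding).
"""

import numpy as np


def _offsets(footprint):
    fp = np.asarray(footprint, dtype=bool)
    ch, cw = fp.shape[0] // 2, fp.shape[1] // 2
    return [(i - ch, j - cw) for i in range(fp.shape[0])
            for j in range(fp.shape[1]) if fp[i, j]]


def brute_erosion(f, footprint):
    f = np.asarray(f, dtype=float)
    rows, cols = f.shape
    out = np.empty_like(f)
    offs = _offsets(footprint)
    for r in range(rows):
        for c in range(cols):
            vals = [f[r + dr, c + dc] for dr, dc in offs
                    if 0 <= r + dr < rows and 0 <= c + dc < cols]
            out[r, c] = min(vals) if vals else np.inf
    return out


def brute_dilation(f, footprint):
    f = np.asarray(f, dtype=float)
    rows, cols = f.shape
    out = np.empty_like(f)
    offs = _offsets(footprint)
    for r in range(rows):
        for c in range(cols):
            vals = [f[r + dr, c + dc] for dr, dc in offs
                    if 0 <= r + dr < rows and 0 <= c + dc < cols]
            out[r, c] = max(vals) if vals else -np.inf
    return out


def brute_opening(f, footprint):
    return brute_dilation(brute_erosion(f, footprint), footprint)


def brute_closing(f, footprint):
    return brute_erosion(brute_dilation(f, footprint), footprint)


def brute_reconstruct(marker, mask):
    """Iterate elementary geodesic dilation (8-connected) to stability."""
    marker = np.minimum(np.asarray(marker, dtype=float),
                        np.asarray(mask, dtype=float))
    mask = np.asarray(mask, dtype=float)
    se = np.ones((3, 3), dtype=bool)
    while True:
        grown = np.minimum(brute_dilation(marker, se), mask)
        if np.array_equal(grown, marker):
            return grown
        marker = grown
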