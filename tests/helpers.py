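"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity with a different, simpler
algorithm (explicit scans and flood fills) so they share no code path with
the package.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def brute_force_holes(s, x, threshold, w_min, L):
    """Circular run-length scan for sub-threshold runs, sample by sample.

    Returns a list of (start, end, width) with linearly interpolated
    threshold-crossing boundaries, runs below ``w_min`` dropped.
    """
    n = len(x)
    ds = L / n
    below = [v < threshold for v in x]
    if all(below):
        return [(0.0, 0.0, L)] if L >= w_min else []
    if not any(below):
        return []
    # rotate so position 0 is above threshold
    k = below.index(False)
    runs = []
    i = 0
    while i < n:
        j = (k + i) % n
        if below[j]:
            start = i
            while i < n and below[(k + i) % n]:
                i += 1
            runs.append((start, i))  # rotated sample indices [start, i)
        else:
            i += 1
    out = []
    for a, b in runs:
        ia_prev = (k + a - 1) % n
        ia = (k + a) % n
        ib_last = (k + b - 1) % n
        ib = (k + b) % n
        fa = (x[ia_prev] - threshold) / (x[ia_prev] - x[ia])
        start_s = (s[ia_prev] + fa * ds) % L
        fb = (x[ib_last] - threshold) / (x[ib_last] - x[ib])
        end_s = (s[ib_last] + fb * ds) % L
        width = (end_s - start_s) % L
        if width >= w_min - 1e-12:
            out.append((start_s, end_s, width))
    out.sort(key=lambda t: t[0])
    return out


def brute_force_prominences(a):
    """Exhaustive saddle search: prominence of every regional maximum.

    For each regional-max plateau of value v, descend through the unique
    image values; the death level is the highest u at which the connected
    component of ``a >= u`` containing the plateau includes a strictly
    higher pixel.  Survivors die at the image minimum.

    Returns a list of (centroid_row, centroid_col, value, prominence).
    """
    a = np.asarray(a, dtype=float)
    results = []
    # regional max plateaus: equal-value components none of whose neighbours is higher
    structure = np.ones((3, 3), bool)
    for v in np.unique(a)[::-1]:
        labels, nlab = ndi.label(a == v, structure=structure)
        for lab in range(1, nlab + 1):
            plateau = labels == lab
            dil = ndi.binary_dilation(plateau, structure=structure)
            if (a[dil & ~plateau] > v).any() if (dil & ~plateau).any() else False:
                continue  # touches higher ground: not a regional max
            death = float(a.min())
            for u in np.unique(a)[::-1]:
                if u > v:
                    continue
                comp_labels, _ = ndi.label(a >= u, structure=structure)
                comp_id = comp_labels[plateau][0]
                if (a[comp_labels == comp_id] > v).any():
                    death = float(u)
                    break
            rows, cols = np.nonzero(plateau)
            results.append((rows.mean(), cols.mean(), float(v), float(v) - death))
    return results


def brute_force_otsu(values, n_bins=256):
    """Exhaustive between-class-variance scan over histogram bin edges."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    total = hist.sum()
    for k in range(1, n_bins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, (edges[k - 1] + edges[k]) / 2
    return best_t
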