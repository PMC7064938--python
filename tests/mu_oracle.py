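"""Brute-force reference for movement-unit segmentation.

Independent of the package implementation: extrema are found by direct
frame scanning, and the merge loop re-derives everything from an explicit
list of surviving extrema on every iteration.  Used only as a test oracle.
"""

import numpy as np


def _scan_extrema(v):
    """(minima, maxima) by direct scanning; plateau extrema are recorded at
    the frame where the next non-zero slope begins, boundary minima are
    inserted so maxima alternate with minima."""
    n = len(v)
    kinds = []  # (index, 'min'|'max')
    slope = 0
    for i in range(n - 1):
        d = v[i + 1] - v[i]
        if d > 0:
            if slope < 0:
                kinds.append((i, "min"))
            slope = 1
        elif d < 0:
            if slope > 0:
                kinds.append((i, "max"))
            slope = -1
    if kinds and kinds[0][1] == "max":
        kinds.insert(0, (0, "min"))
    if kinds and kinds[-1][1] == "max":
        kinds.append((n - 1, "min"))
    mins = [i for i, k in kinds if k == "min"]
    maxs = [i for i, k in kinds if k == "max"]
    return mins, maxs


def oracle_movement_units(v, a, min_delta_v=20.0, min_accel=5.0):
    """Apply the movement-unit rule literally, merging the weakest failing
    peak into the neighbour across its higher bounding minimum until all
    surviving peaks rise and fall by at least ``min_delta_v``; then reject
    units whose peak acceleration magnitude stays below ``min_accel``.
    Returns (start, peak, end) triples.
    """
    v = np.asarray(v, float)
    a = np.asarray(a, float)
    mins, peaks = _scan_extrema(v)
    while peaks:
        prominences = []
        for j, p in enumerate(peaks):
            rise = v[p] - v[mins[j]]
            fall = v[p] - v[mins[j + 1]]
            prominences.append(min(rise, fall))
        failing = [j for j, pr in enumerate(prominences) if pr < min_delta_v]
        if not failing:
            break
        j = min(failing, key=lambda k: (prominences[k], k))
        if len(peaks) == 1:
            peaks = []
            break
        merge_left = j > 0 and (j == len(peaks) - 1
                                or v[mins[j]] >= v[mins[j + 1]])
        if merge_left:
            keep_left = v[peaks[j - 1]] >= v[peaks[j]]
            del mins[j]
            del peaks[j if keep_left else j - 1]
        else:
            keep_right = v[peaks[j + 1]] >= v[peaks[j]]
            del mins[j + 1]
            del peaks[j if keep_right else j + 1]
    out = []
    for j, p in enumerate(peaks):
        s, e = mins[j], mins[j + 1]
        if max(abs(x) for x in a[s : e + 1]) >= min_accel:
            out.append((s, p, e))
    return out
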