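"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-implement the documented rules with O(n^2) scans and
no scipy, so they stay independent of the code paths they check.
"""

import numpy as np


def oracle_peaks(series, dt=1.0, pool=1.0, distance_min=20.0, prom_frac=0.001):
    """Exhaustive peak detection: local maxima, distance filter with
    higher-then-earlier priority, prominence by full-series scan."""
    series = np.asarray(series, float)
    n = series.size
    candidates = [
        i for i in range(1, n - 1) if series[i - 1] < series[i] > series[i + 1]
    ]
    order = sorted(candidates, key=lambda i: (-series[i], i))
    keep = []
    dist = int(np.ceil(distance_min / dt))
    removed = set()
    for i in order:
        if i in removed:
            continue
        keep.append(i)
        for j in candidates:
            if j != i and abs(j - i) < dist:
                removed.add(j)
    keep.sort()
    out = []
    for i in keep:
        left = series[: i + 1]
        higher = np.nonzero(left > series[i])[0]
        lo = higher[-1] + 1 if higher.size else 0
        left_base = left[lo : i + 1].min()
        right = series[i:]
        higher = np.nonzero(right > series[i])[0]
        hi = higher[0] if higher.size else right.size
        right_base = right[: hi + 1 if hi < right.size else None].min()
        prom = series[i] - max(left_base, right_base)
        if prom >= prom_frac * pool:
            out.append(i)
    return np.array(out, dtype=int)


def bump(t, center, width, height):
    return height * np.exp(-0.5 * ((np.asarray(t, float) - center) / width) ** 2)
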