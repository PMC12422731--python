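"""Independent brute-force oracles used by the test suite.

These are deliberately naive (quadratic scans, explicit loops) and share no
code with the package implementation they check.
"""

from __future__ import annotations

import numpy as np


def brute_sleep_seconds(x, min_run=40, frac=0.95):
    """Union of all intervals >= min_run long, >= frac immobile, starting and
    ending on an immobile second.  O(n^2)."""
    x = np.asarray(x, dtype=int)
    n = len(x)
    cs = np.concatenate([[0], np.cumsum(x)])
    asleep = np.zeros(n, dtype=bool)
    for i in range(n):
        if not x[i]:
            continue
        for j in range(i + min_run, n + 1):
            if x[j - 1] and cs[j] - cs[i] >= frac * (j - i) - 1e-12:
                asleep[i:j] = True
    return asleep


def brute_sleep_bouts(counts, threshold=3, min_len=1):
    """Maximal runs of minutes with count > threshold, as (start, end) pairs."""
    bouts = []
    start = None
    for i, c in enumerate(counts):
        if c > threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                bouts.append((start, i))
            start = None
    if start is not None and len(counts) - start >= min_len:
        bouts.append((start, len(counts)))
    return bouts


def brute_activity_bouts(x, threshold=3, max_gap=21):
    """Activity bouts as (start, end): a bout ends only after >= max_gap
    consecutive sub-threshold minutes."""
    bouts = []
    cur_start = cur_last = None
    quiet = 0
    for i, v in enumerate(x):
        if v >= threshold:
            if cur_start is None:
                cur_start = i
            cur_last = i
            quiet = 0
        elif cur_start is not None:
            quiet += 1
            if quiet >= max_gap:
                bouts.append((cur_start, cur_last + 1))
                cur_start = cur_last = None
                quiet = 0
    if cur_start is not None:
        bouts.append((cur_start, cur_last + 1))
    return bouts


def brute_qp(x, p_bins):
    """Chi-square periodogram statistic by direct ANOVA-style fold."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    num = 0.0
    for h in range(p_bins):
        col = x[h::p_bins]
        num += len(col) * (col.mean() - m) ** 2
    return n * num / np.sum((x - m) ** 2)
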