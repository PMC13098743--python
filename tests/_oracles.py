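"""Independent brute-force oracles used by the test suite only."""

from itertools import product

import numpy as np


def enumerate_signed_rank_p(diffs, alternative):
    """Exact signed-rank p-value by enumeration of all sign assignments.

    Ranks the magnitudes, enumerates all 2^n equally likely sign patterns
    under the null, and counts patterns with a positive-rank sum at least
    (greater) / at most (less) / as extreme as (two-sided) the observed one.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    mags = np.abs(d)
    # midranks: average position of equal magnitudes
    order = np.argsort(mags, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_mags = mags[order]
    while i < n:
        j = i
        while j < n and sorted_mags[j] == sorted_mags[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)
        i = j
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    count = 0
    for signs in product([0, 1], repeat=n):
        w = float(np.dot(signs, ranks))
        if alternative == "greater":
            count += w >= w_obs
        elif alternative == "less":
            count += w <= w_obs
        else:
            count += min(w, total - w) <= min(w_obs, total - w_obs)
    return count / 2.0**n
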