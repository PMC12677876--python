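"""Independent oracles used by the tests: brute-force window enumeration and
exact Mann-Whitney enumeration. Deliberately naive implementations that share
no code with the package."""

from itertools import combinations

import numpy as np


def brute_force_best_total(values, valid, lo, hi, window, k, mode):
    """Best summed total over all k nonoverlapping valid window placements,
    by exhaustive enumeration. Returns the optimal total (sum over windows of
    window sums, in original units)."""
    x = np.asarray(values, dtype=np.int64)
    valid = np.asarray(valid, dtype=bool)
    sign = 1 if mode == "max" else -1
    starts = [
        s for s in range(lo, hi - window + 1) if valid[s: s + window].all()
    ]
    sums = {s: int(x[s: s + window].sum()) for s in starts}
    best = None
    for combo in combinations(starts, k):
        if any(combo[i + 1] - combo[i] < window for i in range(k - 1)):
            continue
        tot = sum(sign * sums[s] for s in combo)
        if best is None or tot > best:
            best = tot
    if best is None:
        return None
    return sign * best


def exact_mannwhitney_p(x, y):
    """Two-sided exact p for the Mann-Whitney U by full enumeration of the
    C(n1+n2, n1) group assignments (tie-aware via 0.5 credits)."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)

    def ustat(idx_set):
        xs = [pooled[i] for i in idx_set]
        ys = [pooled[i] for i in range(n) if i not in idx_set]
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = ustat(set(range(n1)))
    center = n1 * (n - n1) / 2.0
    null = [ustat(set(c)) for c in combinations(range(n), n1)]
    return float(
        np.mean([abs(u - center) >= abs(u_obs - center) - 1e-12 for u in null])
    )
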