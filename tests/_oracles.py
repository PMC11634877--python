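"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own code paths: they re-derive the
expected result by direct enumeration or closed form.
"""

import numpy as np


def brute_force_youden(y_true, scores):
    """Exhaustive Youden search: max J over all observed score thresholds.

    Classification rule is strict (positive iff score > threshold); ties in
    J break toward the lowest threshold.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    best_j, best_t = -np.inf, None
    for t in sorted(set(s)):
        sens = np.mean(s[y] > t)
        spec = np.mean(s[~y] <= t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


def brute_force_consensus(caller_flags, tumor_vaf, normal_vaf):
    """Direct evaluation of the 3-clause conjunction for one variant."""
    return sum(caller_flags) >= 2 and tumor_vaf >= 0.05 and normal_vaf < 0.05


def brute_force_brcaness(hrr_mut, hrd, sig3, beta):
    """Direct 4-term disjunction; sig3/beta of None mean assay missing."""
    return bool(
        hrr_mut
        or hrd >= 63
        or (sig3 is not None and sig3 > 0.25)
        or (beta is not None and beta > 0.7)
    )
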