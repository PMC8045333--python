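"""Independent brute-force evaluation of the bin-vs-gene statistics.

Deliberately written with explicit per-bin loops and no shared code with
the package engine, so the two can serve as mutual checks.
"""

import math

import numpy as np


def diffsplice_oracle(beta, u, s2_post, method, s_gene=None):
    """Return (B, C, D, t) arrays for one gene's bins.

    beta, u: per-bin coefficients and unscaled standard deviations;
    s2_post: per-bin posterior variances (used by the improved method);
    s_gene: gene-level posterior standard deviation (legacy method).
    """
    n = len(beta)
    B = np.zeros(n)
    C = np.zeros(n)
    D = np.full(n, np.nan)
    t = np.zeros(n)
    if method == "diffsplice2":
        w = np.array([1.0 / (s2_post[i] * u[i] ** 2) for i in range(n)])
    else:
        w = np.array([1.0 / u[i] ** 2 for i in range(n)])
    for k in range(n):
        num = 0.0
        den = 0.0
        for i in range(n):
            if i == k:
                continue
            num += w[i] * beta[i]
            den += w[i]
        B[k] = num / den
        C[k] = beta[k] - B[k]
        if method == "diffsplice2":
            t[k] = C[k] / (u[k] * math.sqrt(s2_post[k]))
        else:
            D[k] = C[k] * math.sqrt(1.0 - w[k] / w.sum())
            t[k] = D[k] / (u[k] * s_gene)
    return B, C, D, t


def simes_oracle(p):
    """Direct formula: min over i of n * p_(i) / i, capped at 1."""
    ps = sorted(p)
    n = len(ps)
    best = 1.0
    for i, v in enumerate(ps, start=1):
        best = min(best, n * v / i)
    return best
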