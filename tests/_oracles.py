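"""Independent brute-force oracles used by the test suite."""

import numpy as np
from scipy.optimize import linprog


def cemd_flow_oracle(p, q):
    """Min-cost transport between unit-mass histograms on the K-bin circle,
    solved as a linear program over all couplings (ground distance:
    min(|i-j|, K-|i-j|))."""
    p = np.asarray(p, float) / np.sum(p)
    q = np.asarray(q, float) / np.sum(q)
    k = p.size
    cost = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            d = abs(i - j)
            cost[i, j] = min(d, k - d)
    a_eq = []
    for i in range(k):
        row = np.zeros((k, k))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(k):
        col = np.zeros((k, k))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost.ravel(), A_eq=np.array(a_eq),
                  b_eq=np.concatenate([p, q]), method="highs")
    assert res.success
    return res.fun
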