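"""Independent brute-force oracles shared across test modules."""

import numpy as np


def oracle_w(X):
    """Rank-definition Kendall's W: midranks from pairwise comparison
    counts, S and tie term from the textbook formula."""
    X = np.asarray(X, float)
    K, n = X.shape
    R = np.empty((K, n))
    T = 0.0
    for i in range(K):
        greater = (X[i][None, :] > X[i][:, None]).sum(axis=0)
        equal = (X[i][None, :] == X[i][:, None]).sum(axis=0)
        R[i] = greater + (equal + 1) / 2.0
        for v in np.unique(X[i]):
            t = np.sum(X[i] == v)
            T += t**3 - t
    Rj = R.sum(axis=0)
    S = np.sum((Rj - Rj.mean()) ** 2)
    return 12.0 * S / (K * K * (n**3 - n) - K * T)
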