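"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (brute force, recursion, dense algebra)
and shares no code with the implementation under test.
"""

import numpy as np


def brute_force_runs(genotype_row, chromosomes, min_snps):
    """All maximal homozygous runs by checking every (start, end) pair.

    Returns a set of (start, end) global index pairs.  A run qualifies when
    every call in it is 0 or 2, it does not cross a chromosome boundary, and
    it cannot be extended in either direction.
    """
    g = np.asarray(genotype_row)
    m = len(g)
    runs = set()
    for s in range(m):
        for e in range(s + min_snps - 1, m):
            if chromosomes[s] != chromosomes[e]:
                break
            window = g[s : e + 1]
            if np.all(window != 1):
                left_ok = s == 0 or chromosomes[s - 1] != chromosomes[s] or g[s - 1] == 1
                right_ok = e == m - 1 or chromosomes[e + 1] != chromosomes[e] or g[e + 1] == 1
                if left_ok and right_ok:
                    runs.add((s, e))
    return runs


def kinship(ped):
    """Recursive kinship coefficients phi(i, j); A = 2 * phi.

    ``ped`` is a rohscan Pedigree; indices follow its topological order.
    """
    n = len(ped)
    memo = {}

    def phi(i, j):
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            s, d = ped.sire[i], ped.dam[i]
            val = 0.5 * (1 + (phi(s, d) if s is not None and d is not None else 0.0))
        else:
            # j is the younger (later in topological order)
            s, d = ped.sire[j], ped.dam[j]
            val = 0.0
            if s is not None:
                val += 0.5 * phi(i, s)
            if d is not None:
                val += 0.5 * phi(i, d)
        memo[(i, j)] = val
        return val

    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = phi(i, j)
    return K


def gls_fit(y, X, Zs, Ks, variances, sigma2_e):
    """Dense GLS: fixed effects, their covariance, and BLUPs from V directly."""
    n = len(y)
    V = np.eye(n) * sigma2_e
    for Z, K, s2 in zip(Zs, Ks, variances):
        Kv = np.eye(Z.shape[1]) if K is None else K
        V += s2 * Z @ Kv @ Z.T
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    cov_b = np.linalg.inv(XtVX)
    b = cov_b @ X.T @ Vinv @ y
    resid_proj = Vinv @ (y - X @ b)
    blups = []
    for Z, K, s2 in zip(Zs, Ks, variances):
        Kv = np.eye(Z.shape[1]) if K is None else K
        blups.append(s2 * Kv @ Z.T @ resid_proj)
    return b, cov_b, blups


def h_dense(A, genotyped_pos, G):
    """H assembled from its closed-form block definition, then inverted later.

    genotyped_pos indexes the pedigree order; G is over the same order.
    """
    n = A.shape[0]
    g = np.asarray(genotyped_pos)
    ng = np.setdiff1d(np.arange(n), g)
    A22 = A[np.ix_(g, g)]
    A22inv = np.linalg.inv(A22)
    H = A.copy()
    A12 = A[np.ix_(ng, g)]
    T = A12 @ A22inv
    H[np.ix_(ng, ng)] = A[np.ix_(ng, ng)] + T @ (G - A22) @ T.T
    H[np.ix_(ng, g)] = T @ G
    H[np.ix_(g, ng)] = (T @ G).T
    H[np.ix_(g, g)] = G
    return H


def interval_union_length(intervals):
    """Union length of (start, end) intervals, counted as end - start."""
    points = []
    for s, e in intervals:
        points.append((s, 1))
        points.append((e, -1))
    points.sort()
    depth, total, last = 0, 0, None
    for x, d in points:
        if depth > 0:
            total += x - last
        depth += d
        last = x
    return total


def balanced_oneway_reml(y_matrix):
    """Closed-form REML for y_ij = mu + a_i + e_ij, balanced groups.

    y_matrix is groups x replicates.  Returns (sigma2_a, sigma2_e), with the
    group variance truncated at zero.
    """
    a, n0 = y_matrix.shape
    group_means = y_matrix.mean(axis=1)
    mse = ((y_matrix - group_means[:, None]) ** 2).sum() / (a * (n0 - 1))
    msb = n0 * ((group_means - group_means.mean()) ** 2).sum() / (a - 1)
    return max((msb - mse) / n0, 0.0), mse
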