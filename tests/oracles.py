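"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's code paths: REN by direct histogram
+ explicit summation, taxonomy by the O(n^2) neighbourhood definition, BH
by the textbook step-up, and the rank-sum p by exhaustive permutation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ren_bruteforce(x, y, n_bins: int = 10, eps: float = 1e-10) -> float:
    """REN by direct histogramming and an explicit per-bin KL sum."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    cx, _ = np.histogram(x, bins=edges)
    cy, _ = np.histogram(y, bins=edges)
    p = cx / cx.sum() + eps
    p = p / p.sum()
    q = cy / cy.sum() + eps
    q = q / q.sum()
    kl_pq = 0.0
    kl_qp = 0.0
    for pi, qi in zip(p, q):
        kl_pq += pi * np.log(pi / qi)
        kl_qp += qi * np.log(qi / pi)
    return max(kl_pq, kl_qp)


def taxonomy_bruteforce(onsets, offsets, threshold_h: float):
    """Labels by the quadratic definition: a seizure is isolated iff no
    other seizure lies within the cutoff before or after it (offset-to-onset
    gaps); clusters are connected components of the 'within cutoff' links.

    Returns a list of (category, is_cluster_first) tuples.
    """
    n = len(onsets)
    thr = threshold_h * 3600.0
    within = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = (i, j) if onsets[i] <= onsets[j] else (j, i)
            if onsets[b] - offsets[a] <= thr:
                within[i, j] = True
    # connected components over the symmetric relation
    comp = [-1] * n
    c = 0
    for i in range(n):
        if comp[i] != -1:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            k = stack.pop()
            for j in range(n):
                if within[k, j] and comp[j] == -1:
                    comp[j] = c
                    stack.append(j)
        c += 1
    out = []
    for i in range(n):
        members = [j for j in range(n) if comp[j] == comp[i]]
        if len(members) == 1:
            out.append(("isolated", False))
        else:
            last = max(members, key=lambda j: onsets[j])
            first = min(members, key=lambda j: onsets[j])
            cat = "cluster_last" if i == last else "cluster_non_last"
            out.append((cat, i == first))
    return out


def bh_stepup(p_values, q: float = 0.05):
    """Textbook Benjamini-Hochberg: adjusted p and rejections."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj, adj < q


def ranksum_exact_p(a, b) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # tie-free
    obs = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n_a):
        s = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total
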