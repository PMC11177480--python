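"""Independent oracles used across the suite.

Each function recomputes a quantity the package computes, by a different
route (enumeration, brute force, closed form), and is deliberately kept
free of labs_cfdna imports.
"""

import itertools

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided(m1, u1, m2, u2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n1, n2 = m1 + u1, m2 + u2
    K, N = m1 + m2, m1 + u1 + m2 + u2
    rv = hypergeom(N, K, n1)
    ks = np.arange(max(0, K - n2), min(K, n1) + 1)
    probs = rv.pmf(ks)
    p_obs = rv.pmf(m1)
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


def bh_qvalues(p):
    """Benjamini-Hochberg by the definition: q_(i) = min_{j>=i} p_(j) n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = np.inf
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        q[i] = min(running, 1.0)
    return q


def auc_pair_counting(y_true, scores):
    """AUC by counting concordant pairs (ties count 1/2)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    classes = np.unique(y)
    pos = s[y == classes[-1]]
    neg = s[y == classes[0]]
    wins = sum(float(p > q) + 0.5 * float(p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def simplex_grid_search(R, y, step=0.01, refine_rounds=2):
    """Constrained least squares by simplex grid search with local refinement.

    Enumerates the probability simplex at ``step`` resolution, then twice
    re-enumerates a shrinking box around the incumbent at 10x finer steps,
    reaching 1e-4 resolution from a 1e-2 start.
    """
    R = np.asarray(R, float)
    y = np.asarray(y, float)
    k = R.shape[1]

    def objective(w):
        r = R @ w - y
        return float(r @ r)

    def enumerate_box(center, half_width, step):
        best_w, best_obj = None, np.inf
        n_steps = int(round(2 * half_width / step))
        axes = []
        for c in center[:-1]:
            lo = max(0.0, c - half_width)
            vals = lo + step * np.arange(n_steps + 1)
            axes.append(vals[vals <= min(1.0, c + half_width) + 1e-12])
        for combo in itertools.product(*axes):
            last = 1.0 - sum(combo)
            if last < -1e-12:
                continue
            w = np.array(list(combo) + [max(last, 0.0)])
            obj = objective(w)
            if obj < best_obj:
                best_obj, best_w = obj, w
        return best_w, best_obj

    center = np.full(k, 1.0 / k)
    w, _ = enumerate_box(center, 1.0, step)
    width, s = 2 * step, step
    for _ in range(refine_rounds):
        s /= 10.0
        w, _ = enumerate_box(w, width, s)
        width = 4 * s
    return w


def summarize_regions_brute(calls, regions):
    """Per-region pooled counts by a direct double loop."""
    out = []
    for _, reg in regions.iterrows():
        m = u = ns = 0
        for _, site in calls.iterrows():
            if site["chrom"] == reg["chrom"] and reg["start0"] <= site["pos0"] < reg["end0"]:
                m += site["n_meth"]
                u += site["n_unmeth"]
                ns += 1
        out.append((m, u, ns, m / (m + u) if m + u else np.nan))
    return out
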