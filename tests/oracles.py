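"""Brute-force reference implementations used only as independent oracles.

Everything here works by direct enumeration over haplotype pairs or labelings,
with no shared code with the package's vectorized statistics.
"""

import itertools

import numpy as np


def pi_bruteforce(haps: np.ndarray, length: float) -> float:
    """Mean pairwise difference per site by looping over haplotype pairs."""
    n = haps.shape[0]
    tot = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += int(np.sum(haps[i] != haps[j]))
            pairs += 1
    return tot / pairs / length if pairs else 0.0


def theta_w_bruteforce(haps: np.ndarray, length: float) -> float:
    n = haps.shape[0]
    S = sum(1 for s in range(haps.shape[1]) if 0 < haps[:, s].sum() < n)
    a1 = sum(1.0 / i for i in range(1, n))
    return S / a1 / length


def he_bruteforce(haps: np.ndarray) -> float:
    n = haps.shape[0]
    vals = []
    for s in range(haps.shape[1]):
        d = int(haps[:, s].sum())
        if 0 < d < n:
            p = d / n
            vals.append(2 * p * (1 - p) * n / (n - 1))
    return float(np.mean(vals)) if vals else 0.0


def dxy_bruteforce(hapsA: np.ndarray, hapsB: np.ndarray, length: float) -> float:
    tot = 0
    pairs = 0
    for i in range(hapsA.shape[0]):
        for j in range(hapsB.shape[0]):
            tot += int(np.sum(hapsA[i] != hapsB[j]))
            pairs += 1
    return tot / pairs / length


def hudson_fst_bruteforce(hapsA: np.ndarray, hapsB: np.ndarray) -> float:
    """Hudson FST = 1 - Hw/Hb with the unbiased within estimator, written as
    the Bhatia ratio of per-site sums."""
    num = 0.0
    den = 0.0
    nA, nB = hapsA.shape[0], hapsB.shape[0]
    for s in range(hapsA.shape[1]):
        p1 = hapsA[:, s].sum() / nA
        p2 = hapsB[:, s].sum() / nB
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (nA - 1) - p2 * (1 - p2) / (nB - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den else float("nan")


def wc_fst_bruteforce(gtA: np.ndarray, gtB: np.ndarray) -> float:
    """Weir & Cockerham theta-hat for two diploid samples, written directly
    from the 1984 paper's a/b/c component formulas."""
    suma = sumall = 0.0
    r = 2
    for s in range(gtA.shape[1]):
        ns = [gtA.shape[0], gtB.shape[0]]
        ps = [gtA[:, s].sum() / (2 * ns[0]), gtB[:, s].sum() / (2 * ns[1])]
        hs = [np.mean(gtA[:, s] == 1), np.mean(gtB[:, s] == 1)]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        suma += a
        sumall += a + b + c
    return suma / sumall if sumall else float("nan")


def tajimas_d_bruteforce(haps: np.ndarray) -> float:
    """Tajima's D recomputed from first principles on a haplotype matrix."""
    n = haps.shape[0]
    S = 0
    pi_sum = 0.0
    for s in range(haps.shape[1]):
        d = int(haps[:, s].sum())
        if 0 < d < n:
            S += 1
            pi_sum += d * (n - d) / (n * (n - 1) / 2)
    if S == 0 or n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
    return (pi_sum - S / a1) / np.sqrt(var)


def fay_wu_h_bruteforce(haps_derived: np.ndarray) -> float:
    n = haps_derived.shape[0]
    xi = np.zeros(n + 1)
    for s in range(haps_derived.shape[1]):
        xi[int(haps_derived[:, s].sum())] += 1
    pi = sum(xi[i] * i * (n - i) for i in range(1, n)) / (n * (n - 1) / 2)
    th = sum(2 * xi[i] * i * i for i in range(1, n)) / (n * (n - 1))
    if xi[1:n].sum() == 0:
        return float("nan")
    return pi - th


def bh_stepup_bruteforce(pvals: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def mannwhitney_exact_bruteforce(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = np.array(x + y, dtype=float)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    m_obs = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        if min(u, n1 * n2 - u) <= m_obs + 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total


def chi2_2x2_bruteforce(a, b, c, d):
    """Pearson chi-square for a 2x2 table via the closed-form product formula."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den if den else 0.0
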