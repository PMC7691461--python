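"""Outlier-window detection, simulation-null significance and gene-level
selection tests (HKA + PBS).

Highly differentiated candidate windows combine an empirical top-FST cut with
negative Tajima's D (sweep-like); poorly differentiated windows use an
absolute FST ceiling (balancing-selection-like).  Null p-values come from
coalescent simulations under a fitted neutral demography, with
Benjamini-Hochberg FDR per tail and an add-one Monte-Carlo p-value convention.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coalescent_sim import _window_seed, _kernel_args
from . import _kernel
from .demography import DemographicModel, SampleConfig
from .genotype_io import GenotypeMatrix, PopulationMap
from .popgen_stats import fst_window

__all__ = [
    "flag_outlier_windows",
    "simulate_null_fst",
    "null_fst_pvalues",
    "rank_sum_compare",
    "hka_counts",
    "hka_test",
    "call_positive_genes",
]


def flag_outlier_windows(
    stats: pd.DataFrame,
    fst_col: str = "fst_N_S",
    tajd_cols: tuple[str, ...] = ("tajD_N", "tajD_S"),
    fst_top_fraction: float = 0.01,
    tajd_rule: str = "either",
    low_fst_threshold: float = 0.15,
) -> pd.DataFrame:
    """Flag sweep-like (high_diff) and balanced (low_diff) windows.

    high_diff: FST in the empirical top ``fst_top_fraction`` (ties at the
    boundary included) AND Tajima's D negative in either/both/the first of
    ``tajd_cols`` according to ``tajd_rule``.  low_diff: FST below
    ``low_fst_threshold``.  Windows with undefined FST are not scored.
    """
    if len(stats) == 0:
        raise ValueError("empty window table")
    if tajd_rule not in ("either", "both", "focal"):
        raise ValueError(f"unknown tajd_rule {tajd_rule!r}")
    fst = stats[fst_col].to_numpy(dtype=float)
    scored = np.isfinite(fst)
    m = int(scored.sum())
    if m == 0:
        raise ValueError("no scored windows (all FST undefined)")
    k = max(1, int(np.ceil(fst_top_fraction * m)))
    thresh = np.sort(fst[scored])[::-1][k - 1]
    top = scored & (fst >= thresh)
    d = np.column_stack([stats[c].to_numpy(dtype=float) for c in tajd_cols])
    if tajd_rule == "either":
        dneg = np.any(np.isfinite(d) & (d < 0), axis=1)
    elif tajd_rule == "both":
        dneg = np.all(np.where(np.isfinite(d), d < 0, False), axis=1)
    else:
        dneg = np.where(np.isfinite(d[:, 0]), d[:, 0] < 0, False)
    out = stats[["contig", "start", "end", fst_col]].copy()
    out["fst_rank_pct"] = np.where(
        scored, sps.rankdata(np.where(scored, fst, -np.inf)) / m * 100.0, np.nan
    )
    out["high_diff"] = top & dneg
    out["low_diff"] = scored & (fst < low_fst_threshold)
    return out


def simulate_null_fst(
    model: DemographicModel,
    config: SampleConfig,
    n_sims: int,
    pops: tuple[str, str],
    window_bp: int = 10_000,
    estimator: str = "WC",
    seed: int = 0,
) -> np.ndarray:
    """Window FST values simulated under the null demography.

    Windows are independent non-recombining loci; FST is computed exactly as
    for observed windows (diploids formed by haplotype pairing).  Windows with
    no polymorphism yield NaN and are dropped.
    """
    model.validate()
    config.validate(model)
    _, args = _kernel_args(model, config)
    pop_of_hap = [
        p for p in model.populations for _ in range(config.haplotypes.get(p, 0))
    ]
    mu = model.mu_per_gen
    ia = [i for i, p in enumerate(pop_of_hap) if p == pops[0]]
    ib = [i for i, p in enumerate(pop_of_hap) if p == pops[1]]
    vals = np.full(n_sims, np.nan)
    for w in range(n_sims):
        sw = _window_seed(seed, w)
        lengths, masks, _, ok = _kernel.tree_branch_masks(*args, sw)
        if ok != 1:
            raise RuntimeError("null model leaves isolated lineages")
        rng = np.random.default_rng(sw)
        total = lengths.sum()
        n_mut = rng.poisson(total * mu * window_bp)
        if n_mut == 0:
            continue
        branch = rng.choice(len(lengths), size=n_mut, p=lengths / total)
        nh = len(pop_of_hap)
        bits = (masks[branch][None, :] >> np.arange(nh, dtype=np.uint64)[:, None]) & np.uint64(1)
        haps = bits.astype(np.int8)
        gt = haps[0::2] + haps[1::2]
        pop_of_dip = pop_of_hap[0::2]
        ga = gt[[i for i, p in enumerate(pop_of_dip) if p == pops[0]]]
        gb = gt[[i for i, p in enumerate(pop_of_dip) if p == pops[1]]]
        vals[w] = fst_window(ga, gb, estimator=estimator)
    return vals[np.isfinite(vals)]


def null_fst_pvalues(
    obs_fst: np.ndarray,
    null_fst: np.ndarray,
    fdr_level: float = 0.01,
) -> pd.DataFrame:
    """Two-tailed Monte-Carlo p-values against a simulated null FST pool.

    p_upper = (#{null >= obs} + 1) / (n + 1) and analogously for the lower
    tail; Benjamini-Hochberg step-up is applied to each tail separately, and
    candidate flags mark q below ``fdr_level`` in the matching tail.
    """
    obs = np.asarray(obs_fst, dtype=float)
    null = np.sort(np.asarray(null_fst, dtype=float))
    n = len(null)
    if n < 100:
        raise ValueError("need at least 100 null simulations")
    ge = n - np.searchsorted(null, obs, side="left")
    le = np.searchsorted(null, obs, side="right")
    scored = np.isfinite(obs)
    p_up = np.where(scored, (ge + 1) / (n + 1), np.nan)
    p_lo = np.where(scored, (le + 1) / (n + 1), np.nan)
    q_up = np.full_like(p_up, np.nan)
    q_lo = np.full_like(p_lo, np.nan)
    if scored.any():
        q_up[scored] = multipletests(p_up[scored], method="fdr_bh")[1]
        q_lo[scored] = multipletests(p_lo[scored], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "fst": obs,
            "p_upper": p_up,
            "p_lower": p_lo,
            "q_upper": q_up,
            "q_lower": q_lo,
            "candidate_high": scored & (q_up < fdr_level),
            "candidate_low": scored & (q_lo < fdr_level),
        }
    )


def rank_sum_compare(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Mann-Whitney U between two groups (outliers vs background).

    Exact enumeration of labelings when both groups have at most 8 values
    (two-sided p = share of labelings at least as extreme in min(U, U'));
    otherwise the normal approximation with tie correction.  Returns
    (U, two-sided p, direction of shift of x relative to y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    direction = "greater" if np.median(x) > np.median(y) else (
        "less" if np.median(x) < np.median(y) else "equal"
    )
    n1, n2 = len(x), len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(n1 * n2 / 2.0), 1.0, "equal"
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
        m_obs = min(u_obs, n1 * n2 - u_obs)
        count = 0
        total = 0
        for comb in combinations(range(n1 + n2), n1):
            u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
            if min(u, n1 * n2 - u) <= m_obs + 1e-9:
                count += 1
            total += 1
        return u_obs, count / total, direction
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), direction


# ---------------------------------------------------------------------------
# HKA + PBS gene calls
# ---------------------------------------------------------------------------

def hka_counts(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    genes: list[tuple[str, int, int, str]],
    focal: str,
    others: tuple[str, ...],
    fst_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-gene polymorphism (A) and fixed-difference (B) counts.

    ``genes`` are BED-like (contig, start, end, gene_id) intervals.  A counts
    sites segregating within the focal population inside the gene; B counts
    sites whose per-site Hudson FST between the focal population and the
    pooled other populations exceeds ``fst_threshold``.
    """
    fidx = gm.sample_indices(pop_map.samples_for(focal))
    oidx = np.concatenate([gm.sample_indices(pop_map.samples_for(p)) for p in others])
    gF = gm.genotypes[fidx]
    gO = gm.genotypes[oidx]
    missF = gF == -1
    nF = 2 * (~missF).sum(axis=0)
    dF = np.where(missF, 0, gF).sum(axis=0)
    poly = (dF > 0) & (dF < nF)
    # vectorized per-site Hudson FST, focal vs pooled others
    missO = gO == -1
    nO = 2 * (~missO).sum(axis=0)
    dO = np.where(missO, 0, gO).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pF = dF / nF
        pO = dO / nO
        num = (pF - pO) ** 2 - pF * (1 - pF) / (nF - 1) - pO * (1 - pO) / (nO - 1)
        den = pF * (1 - pO) + pO * (1 - pF)
        site_fst = np.where((nF >= 2) & (nO >= 2) & (den > 0), num / den, np.nan)
    high = np.isfinite(site_fst) & (site_fst > fst_threshold)

    rows = []
    for c, s0, e0, gid in genes:
        inside = (gm.contigs == c) & (gm.positions - 1 >= s0) & (gm.positions - 1 < e0)
        rows.append(
            {
                "gene": gid,
                "contig": c,
                "start": s0,
                "end": e0,
                "A": int((inside & poly).sum()),
                "B": int((inside & high).sum()),
            }
        )
    tab = pd.DataFrame(rows)
    tab.attrs["A_tot"] = int(tab["A"].sum())
    tab.attrs["B_tot"] = int(tab["B"].sum())
    return tab


def hka_test(a_gene: int, b_gene: int, a_tot: int, b_tot: int) -> tuple[float, float]:
    """HKA-style Pearson chi-square of the gene's polymorphism/divergence
    ratio against the genome-wide ratio, on the 2x2 table
    [[A_gene, B_gene], [A_tot - A_gene, B_tot - B_gene]] with 1 df."""
    if a_gene > a_tot or b_gene > b_tot:
        raise ValueError("gene counts exceed genome totals")
    if a_tot + b_tot <= 0:
        raise ValueError("empty genome totals")
    table = np.array(
        [[a_gene, b_gene], [a_tot - a_gene, b_tot - b_gene]], dtype=float
    )
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        return 0.0, 1.0
    expect = np.outer(rows, cols) / total
    if np.any(expect < 5):
        warnings.warn("HKA 2x2 table has expected counts < 5", stacklevel=2)
    chi2 = float(((table - expect) ** 2 / expect).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def call_positive_genes(
    gene_table: pd.DataFrame,
    pbs_col: str = "pbs",
    hka_alpha: float = 0.01,
    pbs_percentile: float = 95.0,
) -> pd.DataFrame:
    """Positive-selection calls: HKA p below ``hka_alpha`` AND PBS at or above
    the nearest-rank ``pbs_percentile`` of all analyzed genes.

    ``gene_table`` needs columns A, B (with genome totals in ``attrs`` or
    computed as column sums) and a PBS column.
    """
    tab = gene_table.copy()
    if len(tab) < 20:
        warnings.warn("fewer than 20 genes: PBS percentile is unstable", stacklevel=2)
    a_tot = tab.attrs.get("A_tot", int(tab["A"].sum()))
    b_tot = tab.attrs.get("B_tot", int(tab["B"].sum()))
    chi2s, ps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, r in tab.iterrows():
            chi2, p = hka_test(int(r["A"]), int(r["B"]), a_tot, b_tot)
            chi2s.append(chi2)
            ps.append(p)
    tab["hka_chi2"] = chi2s
    tab["hka_p"] = ps
    pbs_vals = tab[pbs_col].to_numpy(dtype=float)
    finite = np.sort(pbs_vals[np.isfinite(pbs_vals)])
    if len(finite):
        k = int(np.ceil(pbs_percentile / 100.0 * len(finite)))  # nearest rank
        cutoff = finite[max(k - 1, 0)]
    else:
        cutoff = np.inf
    tab["pbs_percentile_cutoff"] = cutoff
    tab["positive_selection"] = (tab["hka_p"] < hka_alpha) & (pbs_vals >= cutoff)
    return tab
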