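"""Per-window and per-site population-genetic statistics.

Statistics operate on per-site allele counts (``n_avail`` = called haplotypes,
``dac`` = ALT or derived dosage sum) or on haplotype/genotype matrices, so
they can be checked against brute-force pairwise implementations.  The
:func:`window_scan` driver assembles the full per-window table.

Conventions: diversity is per callable site; window FST is the ratio of summed
variance components (never a mean of per-site ratios); undefined statistics
are NaN, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotype_io import MISSING, GenotypeMatrix, PolarizedSites, PopulationMap, WindowSet

__all__ = [
    "diversity_stats",
    "tajimas_d",
    "fay_wu_h",
    "fu_li_d",
    "neutrality_stats",
    "fst_window",
    "dxy_rnd_window",
    "classify_sites",
    "ld_stats",
    "estimate_rho",
    "pbs",
    "genotype_pca",
    "window_scan",
    "LDStats",
]


def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _a2(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


# ---------------------------------------------------------------------------
# Diversity and neutrality
# ---------------------------------------------------------------------------

def diversity_stats(
    n_avail: np.ndarray, dac: np.ndarray, callable_length: float
) -> tuple[float, float, float]:
    """(pi, Watterson's theta, HE) for one population over one window.

    pi and thetaW are per callable site; HE is the mean over segregating sites
    of 2p(1-p) with the n/(n-1) sample-size correction.  Sites with fewer than
    two called haplotypes are ignored; thetaW uses each site's own harmonic
    number so missingness is handled per site.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be > 0")
    n = np.asarray(n_avail, dtype=float)
    d = np.asarray(dac, dtype=float)
    ok = n >= 2
    n, d = n[ok], d[ok]
    if n.size == 0:
        return 0.0, 0.0, 0.0
    pi_sites = 2.0 * d * (n - d) / (n * (n - 1.0))
    pi = float(pi_sites.sum()) / callable_length
    seg = (d > 0) & (d < n)
    if seg.any():
        a1 = np.array([_a1(int(m)) for m in n[seg]])
        theta_w = float((1.0 / a1).sum()) / callable_length
        p = d[seg] / n[seg]
        he = float(np.mean(2.0 * p * (1.0 - p) * n[seg] / (n[seg] - 1.0)))
    else:
        theta_w = 0.0
        he = 0.0
    return pi, theta_w, he


def tajimas_d(n: int, dac: np.ndarray) -> float:
    """Tajima's D from the standard constants; NaN when undefined (S=0 or
    n<4, where the variance normalization degenerates)."""
    d = np.asarray(dac, dtype=float)
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0 or n < 4:
        return float("nan")
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = float((2.0 * d[seg] * (n - d[seg]) / (n * (n - 1.0))).sum())
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return (pi - S / a1) / np.sqrt(var)


def fay_wu_h(n: int, dac_derived: np.ndarray) -> float:
    """Fay & Wu's H = pi - theta_H from polarized derived counts.

    theta_H = sum_i 2 xi_i i^2 / (n (n-1)) over derived-count classes i; H is
    negative when high-frequency derived alleles are in excess.
    """
    d = np.asarray(dac_derived, dtype=float)
    seg = (d > 0) & (d < n)
    if not seg.any():
        return float("nan")
    d = d[seg]
    pi = float((2.0 * d * (n - d) / (n * (n - 1.0))).sum())
    theta_h = float((2.0 * d * d / (n * (n - 1.0))).sum())
    return pi - theta_h


def fu_li_d(n: int, dac_derived: np.ndarray) -> float:
    """Fu & Li's D (with outgroup): contrasts external (singleton derived)
    mutations with the total number of segregating mutations."""
    d = np.asarray(dac_derived, dtype=float)
    seg = (d > 0) & (d < n)
    S = int(seg.sum())
    if S == 0 or n < 3:
        return float("nan")
    eta_e = int((d[seg] == 1).sum())
    a1, a2 = _a1(n), _a2(n)
    c = 2.0 * (n * a1 - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    v = 1.0 + a1**2 / (a2 + a1**2) * (c - (n + 1.0) / (n - 1.0))
    u = a1 - 1.0 - v
    var = u * S + v * S * S
    if var <= 0:
        return float("nan")
    return (S - a1 * eta_e) / np.sqrt(var)


def neutrality_stats(
    n_avail: np.ndarray,
    dac: np.ndarray,
    pol: PolarizedSites | None = None,
    site_index: np.ndarray | None = None,
    ref_is_alt_dosage: bool = True,
) -> tuple[float, float, float]:
    """(Tajima's D, Fay & Wu's H, Fu & Li's D) for one population window.

    Only sites with complete data (n_avail equal to the maximum) enter, since
    the test constants require a single sample size.  H and Fu & Li's D use
    polarized derived counts and are NaN without polarization.
    """
    n_avail = np.asarray(n_avail)
    dac = np.asarray(dac)
    if n_avail.size == 0:
        return float("nan"), float("nan"), float("nan")
    n = int(n_avail.max())
    full = n_avail == n
    if n < 2 or not full.any():
        return float("nan"), float("nan"), float("nan")
    taj = tajimas_d(n, dac[full])
    if pol is None:
        return taj, float("nan"), float("nan")
    pol_mask = pol.polarizable if site_index is None else pol.polarizable[site_index]
    anc_ref = (
        pol.ancestral_is_ref if site_index is None else pol.ancestral_is_ref[site_index]
    )
    use = full & pol_mask
    if not use.any():
        return taj, float("nan"), float("nan")
    der = np.where(anc_ref[use], dac[use], n - dac[use]) if ref_is_alt_dosage else dac[use]
    return taj, fay_wu_h(n, der), fu_li_d(n, der)


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------

def _wc_components(gtA: np.ndarray, gtB: np.ndarray):
    """Weir & Cockerham (1984) per-site a, b, c for two diploid samples."""
    comps = []
    for g in (gtA, gtB):
        miss = g == MISSING
        n_i = (~miss).sum(axis=0).astype(float)
        alt = np.where(miss, 0, g).sum(axis=0).astype(float)
        het = ((g == 1) & ~miss).sum(axis=0).astype(float)
        comps.append((n_i, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    n1, n2 = n1[ok], n2[ok]
    p1 = alt1[ok] / (2 * n1)
    p2 = alt2[ok] / (2 * n2)
    h1 = het1[ok] / n1
    h2 = het2[ok] / n2
    r = 2.0
    n_bar = (n1 + n2) / r
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
    c = h_bar / 2.0
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[good], b[good], c[good]


def _hudson_components(gtA: np.ndarray, gtB: np.ndarray):
    """Hudson FST numerator/denominator per site (Bhatia et al. 2013 form),
    on haplotype counts derived from dosages."""
    out = []
    for g in (gtA, gtB):
        miss = g == MISSING
        n = 2.0 * (~miss).sum(axis=0)
        d = np.where(miss, 0, g).sum(axis=0).astype(float)
        out.append((n, d))
    (nA, dA), (nB, dB) = out
    ok = (nA >= 2) & (nB >= 2)
    nA, dA, nB, dB = nA[ok], dA[ok], nB[ok], dB[ok]
    p1, p2 = dA / nA, dB / nB
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (nA - 1) - p2 * (1 - p2) / (nB - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_window(gtA: np.ndarray, gtB: np.ndarray, estimator: str = "WC") -> float:
    """Window FST between two diploid genotype slices, ratio of summed
    per-site components; NaN when no site is polymorphic."""
    if estimator == "WC":
        a, b, c = _wc_components(gtA, gtB)
        den = (a + b + c).sum()
        return float(a.sum() / den) if den > 0 else float("nan")
    if estimator == "Hudson":
        num, den = _hudson_components(gtA, gtB)
        dsum = den.sum()
        return float(num.sum() / dsum) if dsum > 0 else float("nan")
    raise ValueError(f"unknown FST estimator {estimator!r}")


def dxy_rnd_window(
    nA: np.ndarray,
    dA: np.ndarray,
    nB: np.ndarray,
    dB: np.ndarray,
    nO: np.ndarray | None,
    dO: np.ndarray | None,
    callable_length: float,
) -> tuple[float, float, float]:
    """(dxy_AB, dxy_A_outgroup, RND) from per-site allele counts.

    dxy is the mean per-site difference over between-group haplotype pairs,
    normalized by the callable window length; RND = dxy_AB / dxy_A,out,
    NaN when the outgroup divergence is zero or unavailable.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be > 0")

    def _dxy(n1, d1, n2, d2):
        ok = (n1 >= 1) & (n2 >= 1)
        p1 = np.where(ok, d1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(ok, d2 / np.maximum(n2, 1), 0.0)
        per_site = np.where(ok, p1 * (1 - p2) + p2 * (1 - p1), 0.0)
        return float(per_site.sum()) / callable_length

    dxy_ab = _dxy(nA, dA, nB, dB)
    if nO is None:
        return dxy_ab, float("nan"), float("nan")
    dxy_ao = _dxy(nA, dA, nO, dO)
    rnd = dxy_ab / dxy_ao if dxy_ao > 0 else float("nan")
    return dxy_ab, dxy_ao, rnd


def classify_sites(
    nA: np.ndarray, derA: np.ndarray, nB: np.ndarray, derB: np.ndarray
) -> dict[str, int]:
    """Mutually-exclusive site classes between two populations from polarized
    derived counts: fixed differences (derived fixed in exactly one), shared
    and private polymorphisms, and monomorphic sites."""
    nA, derA = np.asarray(nA, float), np.asarray(derA, float)
    nB, derB = np.asarray(nB, float), np.asarray(derB, float)
    ok = (nA >= 1) & (nB >= 1)
    fA = derA[ok] / nA[ok]
    fB = derB[ok] / nB[ok]
    segA = (fA > 0) & (fA < 1)
    segB = (fB > 0) & (fB < 1)
    fixed = ((fA == 1) & (fB == 0)) | ((fA == 0) & (fB == 1))
    shared = segA & segB
    private_a = segA & ~segB
    private_b = segB & ~segA
    mono = ~(fixed | shared | private_a | private_b)
    return {
        "fixed_difference": int(fixed.sum()),
        "shared_polymorphism": int(shared.sum()),
        "private_A": int(private_a.sum()),
        "private_B": int(private_b.sum()),
        "monomorphic": int(mono.sum()),
    }


# ---------------------------------------------------------------------------
# Linkage disequilibrium and recombination
# ---------------------------------------------------------------------------

@dataclass
class LDStats:
    mean_r2: float
    profile: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    half_decay_bp: float


def _pair_r2(mat: np.ndarray, positions: np.ndarray, min_pair_dist: int):
    """(distances, r^2) over eligible column pairs of a 0/1 or dosage matrix."""
    keep = np.std(mat, axis=0) > 0
    mat = mat[:, keep].astype(float)
    pos = positions[keep]
    S = mat.shape[1]
    if S < 2:
        return np.empty(0), np.empty(0)
    r = np.corrcoef(mat, rowvar=False)
    iu, ju = np.triu_indices(S, k=1)
    dist = np.abs(pos[ju] - pos[iu])
    sel = dist > min_pair_dist
    return dist[sel], r[iu[sel], ju[sel]] ** 2


def ld_stats(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    min_pair_dist: int = 1_000,
    bin_width: int = 500,
    phased: bool = True,
    max_snps: int = 400,
) -> LDStats:
    """Pairwise r^2 within a window/region for one population.

    Phased input is a (haplotypes x sites) 0/1 matrix; unphased input is a
    (samples x sites) dosage matrix and r^2 is the squared genotype-dosage
    correlation.  Pairs closer than ``min_pair_dist`` are excluded.  The decay
    profile is binned by distance; the half-decay distance is the start of the
    smallest bin whose mean r^2 drops to half the profile maximum.  Windows
    with many SNPs are evenly thinned to ``max_snps`` columns.
    """
    mat = np.asarray(haplotypes)
    positions = np.asarray(positions)
    if mat.shape[1] > max_snps:
        pick = np.linspace(0, mat.shape[1] - 1, max_snps).astype(int)
        mat, positions = mat[:, pick], positions[pick]
    dist, r2 = _pair_r2(mat, positions, min_pair_dist)
    if dist.size == 0:
        return LDStats(
            float("nan"),
            pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"]),
            float("nan"),
        )
    edges = np.arange(min_pair_dist, dist.max() + bin_width + 1, bin_width)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            rows.append(
                {
                    "bin_start": int(edges[b]),
                    "bin_end": int(edges[b + 1]),
                    "mean_r2": float(r2[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    profile = pd.DataFrame(rows)
    half = float("nan")
    if len(profile):
        top = profile["mean_r2"].max()
        below = profile[profile["mean_r2"] <= top / 2.0]
        if len(below):
            half = float(below["bin_start"].iloc[0])
    return LDStats(float(r2.mean()), profile, half)


def _expected_r2(C: np.ndarray, n: int) -> np.ndarray:
    """Hill & Weir (1988) sample-size-adjusted E[r^2] at scaled distance C."""
    C = np.asarray(C, dtype=float)
    den = 22.0 + 13.0 * C + C * C
    return ((10.0 + C) / den) * (
        1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (n * den)
    )


def estimate_rho(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    window_bp: int,
    min_snps: int = 10,
    min_pair_dist: int = 0,
    bin_width: int = 500,
    max_snps: int = 400,
) -> float:
    """Per-window population-scaled recombination rate (rho = 4 Ne c per
    window) by least-squares fit of the binned r^2 decay to the Hill-Weir
    expected-r^2 curve.  This is a moment-style estimator meant for ordering
    and rank comparisons across windows, not absolute calibration.  NaN when
    fewer than ``min_snps`` segregating sites are available.
    """
    mat = np.asarray(haplotypes)
    n = mat.shape[0]
    seg = np.std(mat, axis=0) > 0
    if seg.sum() < min_snps:
        return float("nan")
    if mat.shape[1] > max_snps:
        pick = np.linspace(0, mat.shape[1] - 1, max_snps).astype(int)
        mat, positions = mat[:, pick], np.asarray(positions)[pick]
    dist, r2 = _pair_r2(mat, np.asarray(positions), min_pair_dist)
    if dist.size < 3:
        return float("nan")
    edges = np.arange(0, dist.max() + bin_width + 1, bin_width)
    which = np.digitize(dist, edges) - 1
    d_mid, r_mean, wts = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            d_mid.append(edges[b] + bin_width / 2.0)
            r_mean.append(r2[sel].mean())
            wts.append(sel.sum())
    d_mid = np.array(d_mid)
    r_mean = np.array(r_mean)
    wts = np.array(wts, dtype=float)

    def sse(log10_rho_bp):
        rho_bp = 10.0**log10_rho_bp
        pred = _expected_r2(rho_bp * d_mid, n)
        return float((wts * (r_mean - pred) ** 2).sum())

    res = minimize_scalar(sse, bounds=(-8.0, 0.0), method="bounded")
    rho_bp = 10.0**res.x
    if sse(-8.0) <= res.fun + 1e-12:  # flat decay: no detectable recombination
        rho_bp = 0.0
    return float(rho_bp * window_bp)


# ---------------------------------------------------------------------------
# PBS and PCA
# ---------------------------------------------------------------------------

def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic for population A.

    T_XY = -log(1 - FST_XY); PBS_A = (T_AB + T_AC - T_BC) / 2.  FST values at
    or above 1 are clamped to 1 - 1e-9 (with a warning); negative PBS is
    allowed.
    """
    vals = []
    for f in (fst_ab, fst_ac, fst_bc):
        if not np.isfinite(f):
            raise ValueError("non-finite FST")
        if f >= 1.0:
            warnings.warn("FST >= 1 clamped to 1 - 1e-9 in PBS", stacklevel=2)
            f = 1.0 - 1e-9
        vals.append(-np.log(1.0 - f))
    t_ab, t_ac, t_bc = vals
    return float((t_ab + t_ac - t_bc) / 2.0)


def genotype_pca(
    gm: GenotypeMatrix,
    samples: list[str] | None = None,
    standardize: bool = False,
    n_components: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered dosage matrix (optionally frequency-standardized).

    Missing calls are mean-imputed per site; monomorphic and all-missing sites
    are dropped.  Returns (sample coordinates, variance-explained fractions);
    the fractions sum to 1 over all computed components.
    """
    idx = (
        np.arange(gm.n_samples)
        if samples is None
        else gm.sample_indices(samples)
    )
    G = gm.genotypes[idx].astype(float)
    G[G == MISSING] = np.nan
    called = ~np.isnan(G)
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise ValueError("PCA needs at least 2 samples and 1 site")
    keep = called.any(axis=0)
    G, called = G[:, keep], called[:, keep]
    mean = np.nanmean(G, axis=0)
    G = np.where(called, G, mean[None, :])
    poly = G.std(axis=0) > 0
    G = G[:, poly]
    mean = mean[poly]
    X = G - mean[None, :]
    if standardize:
        p = mean / 2.0
        sd = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        X = X / sd[None, :]
    U, svals, _ = np.linalg.svd(X, full_matrices=False)
    var = svals**2
    frac = var / var.sum()
    coords = U * svals
    if n_components is not None:
        coords = coords[:, :n_components]
    return coords, frac


# ---------------------------------------------------------------------------
# Window-scan driver
# ---------------------------------------------------------------------------

def window_scan(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    windows: WindowSet,
    pol: PolarizedSites | None = None,
    pops: tuple[str, ...] = ("N", "C", "S"),
    outgroup: str | None = "OUTGROUP",
    focal_pair: tuple[str, str] = ("N", "S"),
    fst_estimator: str = "WC",
    compute_ld: bool = True,
    min_snps_rho: int = 10,
    min_pair_dist: int = 1_000,
) -> pd.DataFrame:
    """Compute the full per-window statistic table.

    One row per window: per-population diversity (pi, thetaW, HE), neutrality
    tests (Tajima's D, Fay & Wu's H, Fu & Li's D), mean r^2 and rho-hat;
    pairwise FST and dxy; outgroup dxy and RND plus site-class counts for the
    focal pair; and per-population PBS when three populations are scored.
    """
    pop_map.validate_against(gm)
    pops = tuple(pops)
    if outgroup is not None and outgroup not in pop_map.populations:
        outgroup = None
    idx = {p: gm.sample_indices(pop_map.samples_for(p)) for p in pops}
    out_idx = gm.sample_indices(pop_map.samples_for(outgroup)) if outgroup else None
    win_of_site = windows.site_window_index(gm)
    a_f, b_f = focal_pair
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]

    rows = []
    for w, (c, s0, e0) in enumerate(windows.windows):
        sites = np.nonzero(win_of_site == w)[0]
        L = float(e0 - s0)
        row: dict = {"contig": c, "start": s0, "end": e0, "n_sites": len(sites),
                     "callable_length": L}
        counts = {}
        for p in pops:
            n_av, dac = _counts(gm, idx[p], sites)
            counts[p] = (n_av, dac)
            pi, tw, he = diversity_stats(n_av, dac, L) if len(sites) else (0.0, 0.0, 0.0)
            taj, fwh, fld = neutrality_stats(n_av, dac, pol, site_index=sites)
            row.update({f"pi_{p}": pi, f"thetaW_{p}": tw, f"HE_{p}": he,
                        f"tajD_{p}": taj, f"fayH_{p}": fwh, f"fuliD_{p}": fld})
            if compute_ld:
                r2, rho = _window_ld(gm, idx[p], sites, s0, L, min_pair_dist, min_snps_rho)
                row[f"r2_{p}"] = r2
                row[f"rho_{p}"] = rho
                row[f"rho_over_theta_{p}"] = rho / (pi * L) if pi > 0 and np.isfinite(rho) else float("nan")
        if out_idx is not None:
            n_o, d_o = _counts(gm, out_idx, sites)
        else:
            n_o = d_o = None
        for a, b in pairs:
            gA = gm.genotypes[np.ix_(idx[a], sites)]
            gB = gm.genotypes[np.ix_(idx[b], sites)]
            row[f"fst_{a}_{b}"] = fst_window(gA, gB, estimator=fst_estimator) if len(sites) else float("nan")
            nA, dA = counts[a]
            nB, dB = counts[b]
            dxy_ab, dxy_ao, rnd = dxy_rnd_window(nA, dA, nB, dB, n_o, d_o, L)
            row[f"dxy_{a}_{b}"] = dxy_ab
            if (a, b) == (a_f, b_f) or (b, a) == (a_f, b_f):
                row[f"dxy_{a}_out"] = dxy_ao
                row[f"rnd_{a}_{b}"] = rnd
                if pol is not None and len(sites):
                    sub = pol.polarizable[sites] & (nA >= 1) & (nB >= 1)
                    derA = np.where(pol.ancestral_is_ref[sites], dA, nA - dA)
                    derB = np.where(pol.ancestral_is_ref[sites], dB, nB - dB)
                    cl = classify_sites(nA[sub], derA[sub], nB[sub], derB[sub])
                    row[f"fixed_{a}_{b}"] = cl["fixed_difference"]
                    row[f"shared_{a}_{b}"] = cl["shared_polymorphism"]
                    row[f"private_{a}"] = cl["private_A"]
                    row[f"private_{b}"] = cl["private_B"]
        if len(pops) == 3:
            p1, p2, p3 = pops
            f12 = row[f"fst_{p1}_{p2}"]
            f13 = row[f"fst_{p1}_{p3}"]
            f23 = row[f"fst_{p2}_{p3}"]
            if all(np.isfinite(v) and v < 1 for v in (f12, f13, f23)):
                neg = lambda v: max(v, 0.0)  # guard slightly negative estimates
                row[f"pbs_{p1}"] = pbs(neg(f12), neg(f13), neg(f23))
                row[f"pbs_{p2}"] = pbs(neg(f12), neg(f23), neg(f13))
                row[f"pbs_{p3}"] = pbs(neg(f13), neg(f23), neg(f12))
            else:
                row[f"pbs_{p1}"] = row[f"pbs_{p2}"] = row[f"pbs_{p3}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _counts(gm: GenotypeMatrix, sample_idx: np.ndarray, sites: np.ndarray):
    g = gm.genotypes[np.ix_(sample_idx, sites)]
    miss = g == MISSING
    return 2 * (~miss).sum(axis=0), np.where(miss, 0, g).sum(axis=0)


def _window_ld(gm, sample_idx, sites, win_start, L, min_pair_dist, min_snps_rho):
    if len(sites) < 2:
        return float("nan"), float("nan")
    pos = gm.positions[sites] - 1
    if gm.haplotypes is not None:
        hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in sample_idx])
        mat = gm.haplotypes[np.ix_(hap_rows, sites)]
        ok = ~np.any(mat == MISSING, axis=0)
    else:
        mat = gm.genotypes[np.ix_(sample_idx, sites)]
        ok = ~np.any(mat == MISSING, axis=0)
    mat, pos = mat[:, ok], pos[ok]
    if mat.shape[1] < 2:
        return float("nan"), float("nan")
    st = ld_stats(mat, pos, min_pair_dist=min_pair_dist)
    rho = estimate_rho(mat, pos, int(L), min_snps=min_snps_rho)
    return st.mean_r2, rho
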