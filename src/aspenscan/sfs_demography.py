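"""Joint-SFS construction and simulation-based composite-likelihood inference.

The observed joint SFS is tallied from called genotypes (optionally
down-projected over missing data); expected spectra come from Monte-Carlo
branch lengths (:func:`aspenscan.coalescent_sim.branch_sfs_tensor`).  Fitting
maximizes a multinomial composite log-likelihood over polymorphic classes.
Three-population data are scored as the composite of the three pairwise 2D
spectra (the full 3D tensor is available via ``pairs="full"``).

Monte-Carlo likelihoods are noisy; all optimizers here are derivative-free
(profile grids and conditional/coordinate maximization) and every parameter
evaluation reuses the same simulation seeds (common random numbers), which
makes the likelihood surface smooth in the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .coalescent_sim import branch_sfs_tensor, simulate_sfs_counts
from .demography import DemographicModel, SampleConfig
from .genotype_io import GenotypeMatrix, PolarizedSites, PopulationMap
from .sfs import JointSFS

__all__ = [
    "observed_joint_sfs",
    "composite_loglik",
    "composite_loglik_full",
    "pairwise_composite_loglik",
    "FitResult",
    "fit_parameters",
    "profile_parameter",
    "multi_stage_profile",
    "model_selection_table",
    "parametric_bootstrap",
    "years_from_generations",
    "generations_from_years",
]


def years_from_generations(t_gen: float, generation_years: float = 15.0) -> float:
    if t_gen < 0:
        raise ValueError("time must be >= 0")
    return t_gen * generation_years


def generations_from_years(t_years: float, generation_years: float = 15.0) -> float:
    if t_years < 0:
        raise ValueError("time must be >= 0")
    return t_years / generation_years


# ---------------------------------------------------------------------------
# Observed SFS
# ---------------------------------------------------------------------------

def observed_joint_sfs(
    gm: GenotypeMatrix,
    pop_map: PopulationMap,
    pops: tuple[str, ...],
    pol: PolarizedSites | None = None,
    fold: bool = False,
    project_to: dict[str, int] | None = None,
) -> JointSFS:
    """Tally the joint SFS of ``pops`` from called genotypes.

    Unfolded spectra (``fold=False``) require outgroup polarization (``pol``)
    and use only polarizable sites.  Sites with missing genotypes are
    hypergeometrically down-projected to a fixed per-population haplotype
    count (``project_to``; default: the smallest complete count observed for
    that population), the standard treatment for missing data in SFS work.
    """
    for p in pops:
        if not pop_map.samples_for(p):
            raise ValueError(f"population {p!r} has no samples in the map")
    idx = [np.array([gm.sample_ids.index(s) for s in pop_map.samples_for(p)]) for p in pops]
    G = gm.genotypes
    S = G.shape[1]
    miss = G < 0
    # per-pop per-site available haplotypes and alt-dosage sums
    n_avail = [2 * (~miss[i]).sum(axis=0) for i in idx]
    alt = [np.where(miss[i], 0, G[i]).sum(axis=0) for i in idx]

    if fold:
        keep = np.ones(S, dtype=bool)
        der = alt
    else:
        if pol is None:
            raise ValueError("unfolded SFS requires polarized sites")
        keep = pol.polarizable.copy()
        der = [np.where(pol.ancestral_is_ref, a, n - a) for a, n in zip(alt, n_avail)]

    if project_to is None:
        proj = []
        for k, p in enumerate(pops):
            avail = n_avail[k][keep]
            if avail.size == 0 or avail.max() == 0:
                raise ValueError(f"population {p!r} has no called genotypes")
            proj.append(int(avail[avail > 0].min()))
    else:
        proj = [int(project_to[p]) for p in pops]

    for k in range(len(pops)):
        keep &= n_avail[k] >= proj[k]

    dims = tuple(n + 1 for n in proj)
    data = np.zeros(dims)
    sites = np.nonzero(keep)[0]
    complete = np.ones(len(sites), dtype=bool)
    for k in range(len(pops)):
        complete &= n_avail[k][sites] == proj[k]

    # fast path: no projection needed
    full = sites[complete]
    if full.size:
        np.add.at(data, tuple(d[full].astype(int) for d in der), 1.0)
    # projection path: outer product of hypergeometric weights per population
    for s in sites[~complete]:
        weights = []
        for k in range(len(pops)):
            n, d, m = int(n_avail[k][s]), int(der[k][s]), proj[k]
            j = np.arange(m + 1)
            weights.append(hypergeom.pmf(j, n, d, m))
        w = weights[0]
        for wk in weights[1:]:
            w = np.multiply.outer(w, wk)
        data += w
    out = JointSFS(tuple(pops), tuple(proj), data, kind="counts")
    return out.fold() if fold else out


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------

def composite_loglik(obs: JointSFS, exp: JointSFS, floor: float | None = None) -> float:
    """Multinomial composite log-likelihood sum(n_c log p_c) over polymorphic
    classes.  Zero-count classes contribute 0; expected proportions are floored
    (Monte-Carlo zeros are sampling artifacts, not structural zeros)."""
    if obs.pops != exp.pops or obs.n_hap != exp.n_hap or obs.folded != exp.folded:
        raise ValueError("observed and expected SFS dimensions differ")
    if exp.kind != "proportions":
        exp = exp.normalized()
    mask = obs.polymorphic_mask()
    n = obs.data[mask]
    p = exp.data[mask]
    if floor is None:
        floor = 1e-12
    p = np.maximum(p, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(p), 0.0)
    return float(terms.sum())


def composite_loglik_full(
    obs: JointSFS,
    exp_branch: JointSFS,
    mu_per_gen: float,
    n_total_sites: float,
    floor: float | None = None,
) -> float:
    """Composite log-likelihood conditioned on total sequence length.

    Unlike :func:`composite_loglik`, the monomorphic class enters explicitly:
    with per-site per-generation mutation rate mu and expected branch
    generations L_c per polymorphic class c, each sequenced site falls in
    class c with probability ~ mu * L_c and is monomorphic otherwise.  This
    anchors the absolute diversity level (theta), which identifies effective
    sizes far more sharply than SFS shape alone — the conditioning used by
    standard SFS-based demographic-inference tools.
    """
    if obs.pops != exp_branch.pops or obs.n_hap != exp_branch.n_hap:
        raise ValueError("observed and expected SFS dimensions differ")
    mask = np.ones(obs.data.shape, dtype=bool)
    mask[(0,) * len(obs.n_hap)] = False
    n_c = obs.data[mask]
    if floor is None:
        floor = 1e-12
    p_c = np.maximum(mu_per_gen * exp_branch.data[mask], mu_per_gen * floor)
    p_mono = max(1.0 - p_c.sum(), 1e-300)
    n_mono = n_total_sites - n_c.sum()
    if n_mono < 0:
        raise ValueError("polymorphic counts exceed total sites")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_c > 0, n_c * np.log(p_c), 0.0)
    return float(terms.sum() + n_mono * np.log(p_mono))


def _pair_list(pops, pairs):
    if pairs == "full":
        return None
    if pairs is None:
        return list(combinations(pops, 2))
    return list(pairs)


def pairwise_composite_loglik(
    obs: JointSFS, exp_branch: JointSFS, pairs=None, floor: float | None = None
) -> float:
    """Composite log-likelihood over 2D pairwise marginals (default: all
    pairs).  ``exp_branch`` is a raw branch-length tensor; each pairwise
    marginal is renormalized over that pair's polymorphic classes."""
    plist = _pair_list(obs.pops, pairs)
    if plist is None:
        return composite_loglik(obs, exp_branch.normalized(), floor=floor)
    total = 0.0
    for a, b in plist:
        total += composite_loglik(
            obs.pairwise(a, b), exp_branch.pairwise(a, b).normalized(), floor=floor
        )
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    loglik: float
    n_free: int
    converged: bool
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "loglik": self.loglik,
            "n_free": self.n_free,
            "converged": self.converged,
            "trace": [[dict(p), ll] for p, ll in self.trace],
        }


def _objective(
    obs, template, config, n_reps, seed, pairs, floor,
    mu_per_gen=None, n_total_sites=None,
):
    """Build the theta -> composite-log-likelihood map.

    With ``mu_per_gen`` and ``n_total_sites`` both given, the likelihood is
    conditioned on total sequence length (:func:`composite_loglik_full`);
    otherwise it is the polymorphic-classes-only multinomial.
    """
    full = mu_per_gen is not None and n_total_sites is not None
    plist = _pair_list(obs.pops, pairs) if full else None

    def ll_of(model: DemographicModel) -> float:
        tensor = branch_sfs_tensor(model, config, n_reps, seed)
        f = floor if floor is not None else 1.0 / (10.0 * n_reps * tensor.data.size)
        if not full:
            return pairwise_composite_loglik(obs, tensor, pairs=pairs, floor=f)
        if plist is None:
            return composite_loglik_full(
                obs, tensor, mu_per_gen, n_total_sites, floor=1.0 / (10.0 * n_reps)
            )
        return sum(
            composite_loglik_full(
                obs.pairwise(a, b), tensor.pairwise(a, b), mu_per_gen,
                n_total_sites, floor=1.0 / (10.0 * n_reps),
            )
            for a, b in plist
        )

    return ll_of


def _geom_grid(lo, hi, k):
    return np.exp(np.linspace(math.log(lo), math.log(hi), k))


def _parabola_vertex(x, y):
    """Vertex of the parabola through three points; None unless concave."""
    A = np.polyfit(x, y, 2)
    if A[0] >= 0:
        return None
    return -A[1] / (2 * A[0])


def profile_parameter(
    obs: JointSFS,
    template: DemographicModel,
    config: SampleConfig,
    param: str,
    bounds: tuple[float, float],
    n_grid: int = 9,
    n_reps_per_eval: int = 20_000,
    seed: int = 0,
    pairs=None,
    refine: bool = True,
) -> FitResult:
    """One-parameter profile: geometric grid over ``bounds`` with all other
    parameters fixed at the template's values, with common random numbers
    across grid points and a quadratic refinement (in log parameter) around
    the best grid point."""
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    ll_of = _objective(obs, template, config, n_reps_per_eval, seed, pairs, None)
    grid = _geom_grid(lo, hi, n_grid)
    lls = np.array([ll_of(template.with_param(param, v)) for v in grid])
    best = int(np.argmax(lls))
    trace = [({param: float(v)}, float(l)) for v, l in zip(grid, lls)]
    est = float(grid[best])
    ll_best = float(lls[best])
    converged = 0 < best < n_grid - 1
    if refine and converged:
        xs = np.log(grid[best - 1 : best + 2])
        ys = lls[best - 1 : best + 2]
        vx = _parabola_vertex(xs, ys)
        if vx is not None and xs[0] < vx < xs[2]:
            cand = float(np.exp(vx))
            ll_cand = ll_of(template.with_param(param, cand))
            trace.append(({param: cand}, float(ll_cand)))
            # the vertex is the reported estimate; under common random numbers
            # its evaluated likelihood should not be materially worse
            est, ll_best = cand, float(max(ll_cand, ll_best))
    return FitResult(
        model_id=f"profile:{param}",
        params={param: est},
        loglik=ll_best,
        n_free=1,
        converged=converged,
        trace=trace,
    )


def multi_stage_profile(
    obs: JointSFS,
    template: DemographicModel,
    config: SampleConfig,
    param: str,
    bounds: tuple[float, float],
    stage_reps: tuple[int, ...] = (20_000, 200_000, 1_600_000),
    n_grid: int = 9,
    bracket_steps: tuple[int, ...] = (1, 2),
    seed: int = 0,
    pairs=None,
    mu_per_gen: float | None = None,
    n_total_sites: float | None = None,
) -> FitResult:
    """One-parameter profile with successive geometric grid refinement.

    Stage 1 scans ``n_grid`` points over ``bounds``; each later stage re-grids
    around the previous best with a bracket of ``bracket_steps`` previous grid
    steps and more Monte-Carlo replicates per evaluation (the noise-induced
    bias of the simulated likelihood shrinks with replicate count, so precision
    is spent where the surface is already localized).  All evaluations share
    simulation seeds (common random numbers).  Ends with a quadratic
    refinement in log parameter around the final best point.

    Passing ``mu_per_gen`` and ``n_total_sites`` switches the objective to the
    sequence-length-conditioned likelihood (:func:`composite_loglik_full`),
    which is what makes effective sizes sharply identifiable.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    trace = []
    grid = _geom_grid(lo, hi, n_grid)
    best = None
    lls = None
    for k, reps in enumerate(stage_reps):
        ll_of = _objective(obs, template, config, reps, seed, pairs, None,
                           mu_per_gen=mu_per_gen, n_total_sites=n_total_sites)
        if k > 0:
            step = math.log(grid[1]) - math.log(grid[0])
            width = bracket_steps[min(k - 1, len(bracket_steps) - 1)] * step
            g_lo = max(lo, best * math.exp(-width))
            g_hi = min(hi, best * math.exp(width))
            grid = _geom_grid(g_lo, g_hi, n_grid)
        lls = np.array([ll_of(template.with_param(param, v)) for v in grid])
        b = int(np.argmax(lls))
        best = float(grid[b])
        trace.extend(
            ({param: float(v), "stage": k}, float(l)) for v, l in zip(grid, lls)
        )
    b = int(np.argmax(lls))
    est = best
    converged = 0 < b < len(grid) - 1
    if converged:
        xs = np.log(grid[b - 1 : b + 2])
        vx = _parabola_vertex(xs, lls[b - 1 : b + 2])
        if vx is not None and xs[0] < vx < xs[2]:
            est = float(np.exp(vx))
    return FitResult(
        model_id=f"profile:{param}",
        params={param: est},
        loglik=float(lls[b]),
        n_free=1,
        converged=converged,
        trace=trace,
    )


def fit_parameters(
    obs: JointSFS,
    template: DemographicModel,
    config: SampleConfig,
    free: dict[str, tuple[float, float]],
    n_reps_per_eval: int = 20_000,
    optimizer: str = "coordinate",
    n_grid: int = 7,
    max_cycles: int = 15,
    tol: float = 0.05,
    seed: int = 0,
    pairs=None,
    model_id: str = "model",
) -> FitResult:
    """Maximize the composite likelihood over ``free`` parameters.

    ``optimizer="grid"`` requires exactly one free parameter and delegates to
    :func:`profile_parameter`.  ``optimizer="coordinate"`` runs conditional
    maximization: each cycle sweeps the free parameters, moving each to the
    best point of a local geometric grid that shrinks between cycles; stops
    when a full cycle improves the log-likelihood by less than ``tol`` or
    after ``max_cycles`` cycles.
    """
    for name, (lo, hi) in free.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"bad bounds for {name}")
        template.get_param(name)  # raises KeyError on unknown parameter
    if optimizer == "grid":
        if len(free) != 1:
            raise ValueError("grid optimizer handles exactly one free parameter")
        (name, bounds), = free.items()
        res = profile_parameter(
            obs, template, config, name, bounds,
            n_grid=n_grid, n_reps_per_eval=n_reps_per_eval, seed=seed, pairs=pairs,
        )
        res.model_id = model_id
        return res
    if optimizer != "coordinate":
        raise ValueError(f"unknown optimizer {optimizer!r}")

    ll_of = _objective(obs, template, config, n_reps_per_eval, seed, pairs, None)
    current = {n: float(np.clip(template.get_param(n), lo, hi)) for n, (lo, hi) in free.items()}

    def build(params):
        m = template
        for n, v in params.items():
            m = m.with_param(n, v)
        return m

    ll_cur = ll_of(build(current))
    trace = [(dict(current), float(ll_cur))]
    span = {n: math.sqrt(hi / lo) for n, (lo, hi) in free.items()}
    converged = False
    for cycle in range(max_cycles):
        ll_start = ll_cur
        for name, (lo, hi) in free.items():
            c = current[name]
            f = span[name]
            glo, ghi = max(lo, c / f), min(hi, c * f)
            grid = _geom_grid(glo, ghi, 5)
            lls = []
            for v in grid:
                trial = dict(current)
                trial[name] = float(v)
                lls.append(ll_of(build(trial)))
            b = int(np.argmax(lls))
            if lls[b] > ll_cur:
                current[name] = float(grid[b])
                ll_cur = float(lls[b])
        trace.append((dict(current), float(ll_cur)))
        for n in span:
            span[n] = max(span[n] ** 0.6, 1.02)
        if ll_cur - ll_start < tol:
            converged = True
            break
    return FitResult(
        model_id=model_id,
        params=current,
        loglik=float(ll_cur),
        n_free=len(free),
        converged=converged,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Model comparison and uncertainty
# ---------------------------------------------------------------------------

def model_selection_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC = 2k - 2 logL; Akaike weights normalized over the candidate set."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        rows.append({"model": f.model_id, "loglik": f.loglik, "k": f.n_free,
                     "AIC": 2 * f.n_free - 2 * f.loglik})
    tab = pd.DataFrame(rows)
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    w = np.exp(-tab["dAIC"] / 2.0)
    tab["weight"] = w / w.sum()
    return tab.sort_values("AIC", ignore_index=True)


def parametric_bootstrap(
    model: DemographicModel,
    config: SampleConfig,
    free: dict[str, tuple[float, float]],
    n_boot: int,
    n_windows: int,
    window_bp: int = 10_000,
    n_reps_per_eval: int = 5_000,
    optimizer: str = "grid",
    n_grid: int = 9,
    seed: int = 0,
    pairs=None,
) -> dict:
    """Percentile intervals from refits to datasets simulated at ``model``.

    Simulates ``n_boot`` windowed datasets at the (fitted) model, refits the
    same free parameters to each, and returns 2.5/97.5 percentile intervals.
    Non-converged refits are excluded and counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    estimates: dict[str, list[float]] = {n: [] for n in free}
    n_failed = 0
    for b in range(n_boot):
        sb = (seed * 7919 + 101 + b) % 2147483647
        obs = simulate_sfs_counts(model, config, n_windows, window_bp, seed=sb)
        fit = fit_parameters(
            obs, model, config, free,
            n_reps_per_eval=n_reps_per_eval, optimizer=optimizer, n_grid=n_grid,
            seed=(sb + 1) % 2147483647, pairs=pairs, model_id=f"boot{b}",
        )
        if not fit.converged:
            n_failed += 1
            continue
        for n in free:
            estimates[n].append(fit.params[n])
    intervals = {}
    for n, vals in estimates.items():
        if len(vals) >= 2:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            intervals[n] = (float(lo), float(hi))
        else:
            intervals[n] = (float("nan"), float("nan"))
    return {"intervals": intervals, "estimates": estimates, "n_failed": n_failed}
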