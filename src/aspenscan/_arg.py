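"""Ancestral-recombination simulation along a window (opt-in).

Hudson-style backward simulation in which each lineage carries ancestral
material over a grid of discrete segments; recombination picks a breakpoint
inside the lineage's ancestral span and splits it, coalescence merges material
and advances every overlapping segment's marginal tree.  This discretized
variant (breakpoints between segments rather than between base pairs) is used
only for LD/recombination-rate validation, where ordering across rho values is
what matters.

The per-window scaled rate ``rho = 4 Ne c`` is converted to a per-generation,
per-bp crossover probability using the current diploid size of the first
sampled population.
"""

from __future__ import annotations

import numpy as np

N_SEGMENTS = 50


def window_haplotypes_recomb(cm, args, mu_per_gen, window_bp, rho_window, seed,
                             n_segments: int = N_SEGMENTS):
    """Simulate one recombining window.

    Returns (positions, haplotypes, mean marginal TMRCA, mean marginal total
    branch length) matching the non-recombining window interface.
    """
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to = args
    rng = np.random.default_rng(seed)
    n = len(samp_pop)
    P = ne.shape[1]
    K = n_segments
    seg_bp = window_bp / K
    ne_ref = ne[0, samp_pop[0]]
    c_bp = rho_window / (4.0 * ne_ref * window_bp)

    # per-segment marginal trees
    nn = 2 * n - 1
    parent = np.full((K, nn), -1, dtype=np.int64)
    ntime = np.zeros((K, nn))
    next_node = np.full(K, n, dtype=np.int64)
    active_ct = np.full(K, n, dtype=np.int64)

    # lineages: population label + per-segment current node (-1 = no material)
    lin_pop: list[int] = list(samp_pop)
    lin_nodes: list[np.ndarray] = [np.full(K, i, dtype=np.int64) for i in range(n)]

    def span(nodes) -> tuple[int, int]:
        anc = np.nonzero(nodes >= 0)[0]
        if anc.size == 0:
            return (0, -1)
        return (int(anc[0]), int(anc[-1]))

    t = 0.0
    mi = 0
    E = len(t_bounds)
    for e in range(E):
        while mi < len(merge_epoch) and merge_epoch[mi] == e:
            f, to = merge_from[mi], merge_to[mi]
            lin_pop = [to if p == f else p for p in lin_pop]
            mi += 1
        t = max(t, t_bounds[e])
        t_next = t_bounds[e + 1] if e + 1 < E else np.inf
        while any(active_ct > 1):
            k = np.zeros(P, dtype=np.int64)
            for p in lin_pop:
                k[p] += 1
            if len(lin_pop) <= 1:
                break
            coal = np.array([k[p] * (k[p] - 1) / (4.0 * ne[e, p]) for p in range(P)])
            mig_out = np.array([mig[e, p, :].sum() for p in range(P)])
            rec_rates = np.array(
                [
                    max(0, span(nodes)[1] - span(nodes)[0]) * seg_bp * c_bp
                    for nodes in lin_nodes
                ]
            )
            R = coal.sum() + (k * mig_out).sum() + rec_rates.sum()
            if R <= 0:
                if e + 1 >= E:
                    raise RuntimeError("stuck lineages in recombining simulation")
                t = t_next
                break
            dt = rng.exponential(1.0 / R)
            if t + dt >= t_next:
                t = t_next
                break
            t += dt
            u = rng.random() * R
            if u < coal.sum():
                p = int(np.searchsorted(np.cumsum(coal), u, side="right"))
                members = [i for i, pp in enumerate(lin_pop) if pp == p]
                ia, ib = rng.choice(len(members), size=2, replace=False)
                ia, ib = members[ia], members[ib]
                na, nb = lin_nodes[ia], lin_nodes[ib]
                merged = np.full(K, -1, dtype=np.int64)
                for s in range(K):
                    if na[s] >= 0 and nb[s] >= 0:
                        v = next_node[s]
                        ntime[s, v] = t
                        parent[s, na[s]] = v
                        parent[s, nb[s]] = v
                        next_node[s] += 1
                        active_ct[s] -= 1
                        merged[s] = v if active_ct[s] > 1 else -1
                    elif na[s] >= 0:
                        merged[s] = na[s] if active_ct[s] > 1 else -1
                    elif nb[s] >= 0:
                        merged[s] = nb[s] if active_ct[s] > 1 else -1
                for i in sorted((ia, ib), reverse=True):
                    lin_pop.pop(i)
                    lin_nodes.pop(i)
                if np.any(merged >= 0):
                    lin_pop.append(p)
                    lin_nodes.append(merged)
            elif u < coal.sum() + (k * mig_out).sum():
                u2 = u - coal.sum()
                acc = 0.0
                moved = False
                for p in range(P):
                    for q in range(P):
                        acc += k[p] * mig[e, p, q]
                        if u2 < acc and not moved:
                            members = [i for i, pp in enumerate(lin_pop) if pp == p]
                            lin_pop[members[rng.integers(len(members))]] = q
                            moved = True
                    if moved:
                        break
            else:
                u3 = u - coal.sum() - (k * mig_out).sum()
                j = int(np.searchsorted(np.cumsum(rec_rates), u3, side="right"))
                lo, hi = span(lin_nodes[j])
                bp = int(rng.integers(lo + 1, hi + 1))  # breakpoint before segment bp
                left = lin_nodes[j].copy()
                right = lin_nodes[j].copy()
                left[bp:] = -1
                right[:bp] = -1
                lin_nodes[j] = left
                lin_nodes.append(right)
                lin_pop.append(lin_pop[j])
        if not any(active_ct > 1):
            break

    if any(active_ct > 1):
        raise RuntimeError("recombining window failed to coalesce")

    # mutations per segment
    all_pos = []
    all_cols = []
    tmrcas = np.zeros(K)
    totlens = np.zeros(K)
    for s in range(K):
        par = parent[s]
        tt = ntime[s]
        lens = tt[par[: nn - 1]] - tt[: nn - 1]
        desc = np.zeros((nn, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for v in range(nn - 1):
            desc[par[v]] |= desc[v]
        tmrcas[s] = tt[nn - 1]
        totlens[s] = lens.sum()
        n_mut = rng.poisson(lens.sum() * mu_per_gen * seg_bp)
        if n_mut == 0:
            continue
        n_mut = min(n_mut, int(seg_bp))
        branch = rng.choice(nn - 1, size=n_mut, p=lens / lens.sum())
        offs = rng.choice(int(seg_bp), size=n_mut, replace=False)
        for b, o in zip(branch, offs):
            all_pos.append(int(s * seg_bp) + int(o))
            all_cols.append(desc[b].astype(np.uint8))
    if not all_pos:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((n, 0), dtype=np.uint8),
            float(tmrcas.mean()),
            float(totlens.mean()),
        )
    order = np.argsort(all_pos)
    positions = np.array(all_pos, dtype=np.int64)[order]
    haps = np.stack(all_cols, axis=1)[:, order]
    return positions, haps, float(tmrcas.mean()), float(totlens.mean())
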