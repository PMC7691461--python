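"""Numba kernels for the structured-coalescent simulator.

Gillespie simulation of the multi-population coalescent with migration under a
piecewise-constant demography compiled to flat epoch arrays (see
``demography.CompiledModel``).  Node ids: leaves ``0..n-1``, internal nodes
``n..2n-2`` in coalescence-time order, so a parent id always exceeds its
children's ids; the root is ``2n-2``.

Diploid convention: a population of size ``Ne`` has pairwise coalescence rate
``1/(2 Ne)`` per generation.  ``mig[e, i, j]`` is the backward per-generation
probability a lineage in ``i`` moves to ``j`` during epoch ``e``.

Reproducibility: every replicate reseeds numba's RNG from a counter-derived
seed, so replicate ``k`` of a run is reproducible in isolation and common
random numbers across parameter evaluations reuse the same seeds.
"""

import numpy as np
from numba import njit

_MIX = 2654435761  # Knuth multiplicative-hash constant for per-rep substreams
_MOD = 2147483647


@njit(cache=True)
def _rep_seed(seed, rep):
    return (seed + _MIX * (rep + 1)) % _MOD


@njit(cache=True)
def _simulate_tree(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
    node_time, node_parent, lin_node, lin_pop, k,
):
    """One coalescent genealogy; fills node_time/node_parent. Returns 1 if fully
    coalesced, 0 if lineages remained un-coalescible (invalid model)."""
    n = samp_pop.shape[0]
    P = ne.shape[1]
    E = t_bounds.shape[0]
    for i in range(n):
        lin_node[i] = i
        lin_pop[i] = samp_pop[i]
        node_time[i] = 0.0
        node_parent[i] = -1
    for p in range(P):
        k[p] = 0
    for i in range(n):
        k[samp_pop[i]] += 1
    n_act = n
    next_node = n
    t = 0.0
    mi = 0
    for e in range(E):
        while mi < merge_epoch.shape[0] and merge_epoch[mi] == e:
            f = merge_from[mi]
            to = merge_to[mi]
            if k[f] > 0:
                for i in range(n_act):
                    if lin_pop[i] == f:
                        lin_pop[i] = to
                k[to] += k[f]
                k[f] = 0
            mi += 1
        if t < t_bounds[e]:
            t = t_bounds[e]
        t_next = t_bounds[e + 1] if e + 1 < E else np.inf
        while n_act > 1:
            R = 0.0
            for p in range(P):
                if k[p] > 1:
                    R += k[p] * (k[p] - 1) / (4.0 * ne[e, p])
                if k[p] > 0:
                    for q in range(P):
                        R += k[p] * mig[e, p, q]
            if R <= 0.0:
                if e + 1 >= E:
                    return 0  # stuck: isolated lineages in the final epoch
                t = t_next
                break
            dt = np.random.exponential(1.0 / R)
            if t + dt >= t_next:
                t = t_next
                break
            t += dt
            u = np.random.random() * R
            acc = 0.0
            done = False
            for p in range(P):
                if k[p] > 1:
                    acc += k[p] * (k[p] - 1) / (4.0 * ne[e, p])
                    if u < acc:
                        a = np.random.randint(k[p])
                        b = np.random.randint(k[p] - 1)
                        if b >= a:
                            b += 1
                        ia = -1
                        ib = -1
                        c = 0
                        for i in range(n_act):
                            if lin_pop[i] == p:
                                if c == a:
                                    ia = i
                                if c == b:
                                    ib = i
                                c += 1
                        node_time[next_node] = t
                        node_parent[next_node] = -1
                        node_parent[lin_node[ia]] = next_node
                        node_parent[lin_node[ib]] = next_node
                        lin_node[ia] = next_node
                        lin_node[ib] = lin_node[n_act - 1]
                        lin_pop[ib] = lin_pop[n_act - 1]
                        n_act -= 1
                        k[p] -= 1
                        next_node += 1
                        done = True
                        break
            if not done:
                for p in range(P):
                    if done:
                        break
                    if k[p] > 0:
                        for q in range(P):
                            m = mig[e, p, q]
                            if m > 0.0:
                                acc += k[p] * m
                                if u < acc:
                                    a = np.random.randint(k[p])
                                    c = 0
                                    for i in range(n_act):
                                        if lin_pop[i] == p:
                                            if c == a:
                                                lin_pop[i] = q
                                                break
                                            c += 1
                                    k[p] -= 1
                                    k[q] += 1
                                    done = True
                                    break
        if n_act <= 1:
            break
    return 1 if n_act == 1 else 0


@njit(cache=True)
def simulate_tree_arrays(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to, seed
):
    """Single seeded genealogy: returns (node_time, node_parent, ok)."""
    n = samp_pop.shape[0]
    P = ne.shape[1]
    nn = 2 * n - 1
    node_time = np.zeros(nn)
    node_parent = np.full(nn, -1, np.int64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int64)
    k = np.zeros(P, np.int64)
    np.random.seed(_rep_seed(seed, 0))
    ok = _simulate_tree(
        samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
        node_time, node_parent, lin_node, lin_pop, k,
    )
    return node_time, node_parent, ok


@njit(cache=True)
def accumulate_branch_sfs(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
    axis_of_pop, dims, n_reps, seed, out,
):
    """Accumulate branch lengths into a flattened joint-SFS tensor.

    ``out`` is a flat float64 array of size prod(dims); a branch whose
    descendant counts in the sampled populations are (d0, d1, ...) adds its
    length (generations) to cell (d0, d1, ...).  Returns the number of
    replicates that failed to coalesce (0 for any valid model).
    """
    n = samp_pop.shape[0]
    P = ne.shape[1]
    naxes = dims.shape[0]
    nn = 2 * n - 1
    node_time = np.zeros(nn)
    node_parent = np.full(nn, -1, np.int64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int64)
    k = np.zeros(P, np.int64)
    desc = np.zeros((nn, naxes), np.int64)
    strides = np.zeros(naxes, np.int64)
    s = 1
    for a in range(naxes - 1, -1, -1):
        strides[a] = s
        s *= dims[a]
    failed = 0
    for rep in range(n_reps):
        np.random.seed(_rep_seed(seed, rep))
        ok = _simulate_tree(
            samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
            node_time, node_parent, lin_node, lin_pop, k,
        )
        if ok == 0:
            failed += 1
            continue
        for v in range(nn):
            for a in range(naxes):
                desc[v, a] = 0
        for i in range(n):
            a = axis_of_pop[samp_pop[i]]
            if a >= 0:
                desc[i, a] = 1
        for v in range(nn - 1):
            par = node_parent[v]
            blen = node_time[par] - node_time[v]
            cell = 0
            for a in range(naxes):
                cell += desc[v, a] * strides[a]
                desc[par, a] += desc[v, a]
            out[cell] += blen
    return failed


@njit(cache=True)
def accumulate_mutation_sfs(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
    axis_of_pop, dims, n_windows, mu_times_bp, seed, out,
):
    """Tally infinite-sites mutation counts from independent window genealogies
    into a flattened joint-SFS count tensor (int64).

    ``mu_times_bp`` is per-generation mutation rate per site times window
    length, i.e. the per-generation mutation rate of the whole window.
    """
    n = samp_pop.shape[0]
    P = ne.shape[1]
    naxes = dims.shape[0]
    nn = 2 * n - 1
    node_time = np.zeros(nn)
    node_parent = np.full(nn, -1, np.int64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int64)
    k = np.zeros(P, np.int64)
    desc = np.zeros((nn, naxes), np.int64)
    strides = np.zeros(naxes, np.int64)
    s = 1
    for a in range(naxes - 1, -1, -1):
        strides[a] = s
        s *= dims[a]
    failed = 0
    for w in range(n_windows):
        np.random.seed(_rep_seed(seed, w))
        ok = _simulate_tree(
            samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
            node_time, node_parent, lin_node, lin_pop, k,
        )
        if ok == 0:
            failed += 1
            continue
        for v in range(nn):
            for a in range(naxes):
                desc[v, a] = 0
        for i in range(n):
            a = axis_of_pop[samp_pop[i]]
            if a >= 0:
                desc[i, a] = 1
        for v in range(nn - 1):
            par = node_parent[v]
            blen = node_time[par] - node_time[v]
            nm = np.random.poisson(blen * mu_times_bp)
            cell = 0
            for a in range(naxes):
                cell += desc[v, a] * strides[a]
                desc[par, a] += desc[v, a]
            out[cell] += nm
    return failed


@njit(cache=True)
def tree_branch_masks(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to, seed
):
    """One genealogy as (branch_lengths, descendant bitmasks, ok) for n <= 64.

    Entry ``v`` (v = 0..2n-3) is the branch above node v; bit ``i`` of
    ``masks[v]`` is set iff leaf ``i`` descends from node ``v``.
    """
    n = samp_pop.shape[0]
    P = ne.shape[1]
    nn = 2 * n - 1
    node_time = np.zeros(nn)
    node_parent = np.full(nn, -1, np.int64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int64)
    k = np.zeros(P, np.int64)
    np.random.seed(_rep_seed(seed, 0))
    ok = _simulate_tree(
        samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
        node_time, node_parent, lin_node, lin_pop, k,
    )
    lengths = np.zeros(nn - 1)
    masks = np.zeros(nn, np.uint64)
    if ok == 1:
        for i in range(n):
            masks[i] = np.uint64(1) << np.uint64(i)
        for v in range(nn - 1):
            par = node_parent[v]
            lengths[v] = node_time[par] - node_time[v]
            masks[par] |= masks[v]
    return lengths, masks[: nn - 1], node_time, ok


@njit(cache=True)
def tmrca_and_length_reps(
    samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to, n_reps, seed
):
    """Per-replicate (TMRCA, total branch length) for Monte-Carlo checks."""
    n = samp_pop.shape[0]
    P = ne.shape[1]
    nn = 2 * n - 1
    node_time = np.zeros(nn)
    node_parent = np.full(nn, -1, np.int64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int64)
    k = np.zeros(P, np.int64)
    tmrca = np.zeros(n_reps)
    tlen = np.zeros(n_reps)
    for rep in range(n_reps):
        np.random.seed(_rep_seed(seed, rep))
        ok = _simulate_tree(
            samp_pop, t_bounds, ne, mig, merge_epoch, merge_from, merge_to,
            node_time, node_parent, lin_node, lin_pop, k,
        )
        if ok == 0:
            tmrca[rep] = np.nan
            tlen[rep] = np.nan
            continue
        tmrca[rep] = node_time[nn - 1]
        tot = 0.0
        for v in range(nn - 1):
            tot += node_time[node_parent[v]] - node_time[v]
        tlen[rep] = tot
    return tmrca, tlen
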