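"""Structured-coalescent simulation: genealogies, mutations, datasets, SFS.

This is both the synthetic-data generator and the null-model engine of the
pipeline.  Windows are independent non-recombining loci by default (the
standard SFS-block setup); intra-window recombination is opt-in via
``recombination_rho`` in :func:`simulate_dataset` and is used for LD/rho
validation only (see :mod:`aspenscan._arg`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .demography import CompiledModel, DemographicModel, SampleConfig
from .sfs import JointSFS

__all__ = [
    "Genealogy",
    "SimTruth",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "simulate_sfs_counts",
    "branch_sfs_tensor",
    "expected_joint_sfs",
]

_SEED_MOD = 2147483647


def _window_seed(seed: int, w: int) -> int:
    return (seed * 1000003 + 17 + w) % _SEED_MOD


def _kernel_args(model: DemographicModel, config: SampleConfig):
    config.validate(model)
    cm = CompiledModel(model)
    samp_pop = cm.sample_pops_array(config)
    return cm, (
        samp_pop,
        cm.t_bounds,
        cm.ne,
        cm.mig,
        cm.merge_epoch,
        cm.merge_from,
        cm.merge_to,
    )


def _axes(cm: CompiledModel, config: SampleConfig):
    pops = [p for p in cm.model.populations if config.haplotypes.get(p, 0) > 0]
    axis_of_pop = np.full(len(cm.model.populations), -1, dtype=np.int64)
    for a, p in enumerate(pops):
        axis_of_pop[cm.pop_index[p]] = a
    dims = np.array([config.haplotypes[p] + 1 for p in pops], dtype=np.int64)
    return pops, axis_of_pop, dims


@dataclass
class Genealogy:
    """Labelled binary coalescent tree; times in generations before present.

    Leaves ``0..n-1`` carry ``leaf_pops`` labels; internal node ids follow in
    coalescence order, the root last.
    """

    node_time: np.ndarray
    node_parent: np.ndarray
    leaf_pops: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_pops)

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    def branch_lengths(self) -> np.ndarray:
        v = np.arange(len(self.node_time) - 1)
        return self.node_time[self.node_parent[v]] - self.node_time[v]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def descendant_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves): leaf j descends from node i."""
        nn = len(self.node_time)
        n = self.n_leaves
        desc = np.zeros((nn, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for v in range(nn - 1):
            desc[self.node_parent[v]] |= desc[v]
        return desc

    def newick(self) -> str:
        nn = len(self.node_time)
        children: list[list[int]] = [[] for _ in range(nn)]
        for v in range(nn - 1):
            children[self.node_parent[v]].append(v)
        labels = [f"{p}_{i}" for i, p in enumerate(self.leaf_pops)]

        def rec(v: int) -> str:
            t = self.node_time
            if not children[v]:
                return labels[v]
            parts = [f"{rec(c)}:{t[v] - t[c]:.6f}" for c in children[v]]
            return "(" + ",".join(parts) + ")"

        return rec(nn - 1) + ";"


def simulate_genealogy(
    model: DemographicModel, config: SampleConfig, seed: int
) -> Genealogy:
    """Simulate one multi-population coalescent genealogy."""
    cm, args = _kernel_args(model, config)
    node_time, node_parent, ok = _kernel.simulate_tree_arrays(*args, seed % _SEED_MOD)
    if ok != 1:
        raise RuntimeError("lineages failed to coalesce; model leaves isolated demes")
    leaf_pops = [
        p for p in model.populations for _ in range(config.haplotypes.get(p, 0))
    ]
    return Genealogy(node_time, node_parent, leaf_pops)


def drop_mutations(
    gen: Genealogy, mu_per_gen: float, length_bp: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations on a genealogy.

    Returns ``(positions, haplotypes)`` with ``positions`` strictly increasing
    0-based offsets in ``[0, length_bp)`` and ``haplotypes`` a
    ``(n_leaves, S)`` 0/1 matrix (1 = derived).
    """
    if mu_per_gen < 0:
        raise ValueError("mutation rate must be >= 0")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    rng = np.random.default_rng(seed)
    blens = gen.branch_lengths()
    total = blens.sum()
    n_mut = rng.poisson(total * mu_per_gen * length_bp)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty((gen.n_leaves, 0), dtype=np.uint8)
    if n_mut > length_bp:
        raise RuntimeError(
            f"infinite-sites saturation: {n_mut} mutations on {length_bp} bp"
        )
    branch = rng.choice(len(blens), size=n_mut, p=blens / total)
    positions = np.sort(rng.choice(length_bp, size=n_mut, replace=False))
    desc = gen.descendant_matrix()
    haps = desc[branch].T.astype(np.uint8)  # (n_leaves, S)
    return positions.astype(np.int64), haps


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    model: dict
    haplotypes: dict[str, int]
    seed: int
    window_bp: int
    contig: str
    n_windows: int
    ancestral_is_ref: bool
    recombination_rho: float
    windows: list[dict] = field(default_factory=list)  # tmrca, total_length, n_sites

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _window_haplotypes_norec(args, mu_per_gen, window_bp, seed_w):
    lengths, masks, node_time, ok = _kernel.tree_branch_masks(*args, seed_w)
    if ok != 1:
        raise RuntimeError("lineages failed to coalesce")
    rng = np.random.default_rng(seed_w)
    total = lengths.sum()
    n_mut = rng.poisson(total * mu_per_gen * window_bp)
    n = args[0].shape[0]
    if n_mut == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((n, 0), dtype=np.uint8),
            float(node_time[-1]),
            float(total),
        )
    if n_mut > window_bp:
        raise RuntimeError("infinite-sites saturation in window")
    branch = rng.choice(len(lengths), size=n_mut, p=lengths / total)
    positions = np.sort(rng.choice(window_bp, size=n_mut, replace=False))
    bits = (masks[branch][None, :] >> np.arange(n, dtype=np.uint64)[:, None]) & np.uint64(1)
    haps = bits.astype(np.uint8)  # (n, S)
    return positions.astype(np.int64), haps, float(node_time[-1]), float(total)


def simulate_dataset(
    model: DemographicModel,
    config: SampleConfig,
    n_windows: int,
    out_prefix,
    window_bp: int = 10_000,
    recombination_rho: float = 0.0,
    seed: int = 0,
    contig: str = "chr_sim",
) -> SimTruth:
    """Simulate a windowed diploid dataset and write VCF + truth + BED.

    Each window is an independent locus on one synthetic contig; diploid
    samples are formed by pairing consecutive haplotypes within each
    population, so every sampled population needs an even haplotype count.
    Writes ``<out_prefix>.vcf``, ``<out_prefix>.truth.json``,
    ``<out_prefix>.windows.bed`` and ``<out_prefix>.popmap.tsv``; REF is the
    ancestral allele by construction.  Deterministic given (model, config,
    seed).
    """
    cm, args = _kernel_args(model, config)
    n_hap = args[0].shape[0]
    if n_hap > 64:
        raise ValueError("simulate_dataset supports at most 64 haplotypes")
    for p, h in config.haplotypes.items():
        if h % 2 != 0:
            raise ValueError(f"odd haplotype count for {p!r}: cannot form diploids")
    sampled = [p for p in model.populations if config.haplotypes.get(p, 0) > 0]
    sample_names = []
    sample_pops = []
    for p in sampled:
        for d in range(config.haplotypes[p] // 2):
            sample_names.append(f"{p}{d + 1:02d}")
            sample_pops.append(p)
    mu = model.mu_per_gen

    if recombination_rho > 0:
        from ._arg import window_haplotypes_recomb

    truth = SimTruth(
        model=model.to_dict(),
        haplotypes=dict(config.haplotypes),
        seed=int(seed),
        window_bp=int(window_bp),
        contig=contig,
        n_windows=int(n_windows),
        ancestral_is_ref=True,
        recombination_rho=float(recombination_rho),
    )

    vcf_path = f"{out_prefix}.vcf"
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write(f"##contig=<ID={contig},length={n_windows * window_bp}>\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        vcf.write("##source=aspenscan-simulate\n")
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for w in range(n_windows):
            sw = _window_seed(seed, w)
            if recombination_rho > 0:
                pos, haps, tm, tl = window_haplotypes_recomb(
                    cm, args, mu, window_bp, recombination_rho, sw
                )
            else:
                pos, haps, tm, tl = _window_haplotypes_norec(args, mu, window_bp, sw)
            truth.windows.append(
                {"tmrca": tm, "total_length": tl, "n_sites": int(pos.shape[0])}
            )
            base = w * window_bp
            for s in range(pos.shape[0]):
                gts = "\t".join(
                    f"{haps[2 * i, s]}|{haps[2 * i + 1, s]}:99"
                    for i in range(len(sample_names))
                )
                vcf.write(f"{contig}\t{base + pos[s] + 1}\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t{gts}\n")

    with open(f"{out_prefix}.windows.bed", "w") as bed:
        for w in range(n_windows):
            bed.write(f"{contig}\t{w * window_bp}\t{(w + 1) * window_bp}\n")
    with open(f"{out_prefix}.popmap.tsv", "w") as pm:
        for name, p in zip(sample_names, sample_pops):
            pm.write(f"{name}\t{'OUTGROUP' if p == 'OUT' else p}\n")
    truth.to_json(f"{out_prefix}.truth.json")
    return truth


def simulate_sfs_counts(
    model: DemographicModel,
    config: SampleConfig,
    n_windows: int,
    window_bp: int = 10_000,
    seed: int = 0,
) -> JointSFS:
    """Joint SFS of a simulated windowed dataset, tallied without materializing
    genotypes (equivalent to :func:`simulate_dataset` + a count pass)."""
    cm, args = _kernel_args(model, config)
    pops, axis_of_pop, dims = _axes(cm, config)
    out = np.zeros(int(np.prod(dims)), dtype=np.int64)
    failed = _kernel.accumulate_mutation_sfs(
        *args,
        axis_of_pop,
        dims,
        int(n_windows),
        model.mu_per_gen * window_bp,
        seed % _SEED_MOD,
        out,
    )
    if failed:
        raise RuntimeError(f"{failed} windows failed to coalesce")
    data = out.reshape(tuple(dims)).astype(float)
    return JointSFS(tuple(pops), tuple(d - 1 for d in dims), data, kind="counts")


def branch_sfs_tensor(
    model: DemographicModel, config: SampleConfig, n_reps: int, seed: int
) -> JointSFS:
    """Monte-Carlo expected branch lengths per joint derived-count class.

    The expected SFS is proportional to these branch lengths (each branch
    contributes its length to the class of its descendant set); normalize with
    :meth:`JointSFS.normalized` for expected proportions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cm, args = _kernel_args(model, config)
    pops, axis_of_pop, dims = _axes(cm, config)
    out = np.zeros(int(np.prod(dims)), dtype=np.float64)
    failed = _kernel.accumulate_branch_sfs(
        *args, axis_of_pop, dims, int(n_reps), seed % _SEED_MOD, out
    )
    if failed:
        raise RuntimeError(f"{failed}/{n_reps} replicates failed to coalesce")
    data = out.reshape(tuple(dims)) / n_reps
    return JointSFS(tuple(pops), tuple(d - 1 for d in dims), data, kind="counts")


def expected_joint_sfs(
    model: DemographicModel, config: SampleConfig, n_reps: int, seed: int
) -> JointSFS:
    """Monte-Carlo expected joint-SFS proportions over polymorphic classes."""
    return branch_sfs_tensor(model, config, n_reps, seed).normalized()
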