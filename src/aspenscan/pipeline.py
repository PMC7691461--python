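"""Stage orchestration: simulate, SFS, fit, scan, outliers, genes, report.

Each stage is a plain function over files so it can be driven from the CLI,
from the numbered analysis scripts, or from tests.  Every run directory gets a
manifest (config hash, seeds, versions, row counts, wall time) written
atomically at stage end; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .demography import DemographicModel, SampleConfig, table1_model
from .genotype_io import (
    PopulationMap,
    WindowSet,
    make_windows,
    polarize_sites,
    read_vcf,
)
from .popgen_stats import window_scan, pbs
from .selection_scan import (
    call_positive_genes,
    flag_outlier_windows,
    hka_counts,
    null_fst_pvalues,
    simulate_null_fst,
)
from .sfs import JointSFS
from .sfs_demography import fit_parameters, model_selection_table, observed_joint_sfs
from .coalescent_sim import simulate_dataset
from .popgen_stats import fst_window

__all__ = [
    "write_manifest",
    "run_simulate",
    "run_sfs",
    "run_fit",
    "run_scan",
    "run_outliers",
    "run_genes",
    "run_report",
]


def write_manifest(out_dir, stage: str, config: dict, seeds, row_counts: dict,
                   t_start: float) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "stage": stage,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seeds": seeds,
        "versions": {
            "aspenscan": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": row_counts,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    path = os.path.join(out_dir, f"manifest_{stage}.json")
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
    return manifest


def _load_model(model: str | DemographicModel) -> DemographicModel:
    if isinstance(model, DemographicModel):
        return model
    if model in ("table1", "table1_outgroup"):
        return table1_model(include_outgroup=model.endswith("outgroup"))
    return DemographicModel.from_json(model)


def run_simulate(out_dir, model="table1_outgroup", samples=None, n_windows=200,
                 window_bp=10_000, recombination_rho=0.0, seed=1,
                 scale=1.0) -> dict:
    """Simulate a windowed dataset into ``out_dir/sim.*``.

    ``scale`` > 1 applies a structure-preserving diffusion rescaling
    (sizes/times divided, migration multiplied) that lowers per-site mutation
    density; useful because fitted parameters with very large ancestral sizes
    can saturate a discrete infinite-sites window.
    """
    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    m = _load_model(model)
    if scale != 1.0:
        from .demography import scaled_model

        m = scaled_model(m, scale)
    samples = samples or {p: (2 if p == "OUT" else 8) for p in m.populations}
    cfg = SampleConfig(samples)
    truth = simulate_dataset(
        m, cfg, n_windows, os.path.join(out_dir, "sim"),
        window_bp=window_bp, recombination_rho=recombination_rho, seed=seed,
    )
    n_sites = sum(w["n_sites"] for w in truth.windows)
    config = {"model": m.to_dict(), "samples": samples, "n_windows": n_windows,
              "window_bp": window_bp, "recombination_rho": recombination_rho}
    write_manifest(out_dir, "simulate", config, [seed],
                   {"windows": n_windows, "sites": n_sites}, t0)
    return {"vcf": os.path.join(out_dir, "sim.vcf"),
            "popmap": os.path.join(out_dir, "sim.popmap.tsv"),
            "truth": os.path.join(out_dir, "sim.truth.json"),
            "bed": os.path.join(out_dir, "sim.windows.bed")}


def run_sfs(out_dir, vcf, popmap, pops=("N", "C", "S"), outgroup="OUTGROUP",
            fold=False) -> dict:
    """Observed joint SFS (full tensor + the three pairwise marginals)."""
    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    pm = PopulationMap.read_tsv(popmap)
    gm = read_vcf(vcf, pm)
    pol = None
    if not fold:
        pol = polarize_sites(gm, pm.samples_for(outgroup))
    sfs = observed_joint_sfs(gm, pm, tuple(pops), pol=pol, fold=fold)
    sfs.save(os.path.join(out_dir, "sfs_joint.txt"))
    outputs = {"joint": os.path.join(out_dir, "sfs_joint.txt")}
    if not fold and len(pops) >= 2:
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                a, b = pops[i], pops[j]
                p = os.path.join(out_dir, f"sfs_{a}_{b}.txt")
                sfs.pairwise(a, b).save(p)
                outputs[f"{a}_{b}"] = p
    config = {"vcf": vcf, "popmap": popmap, "pops": list(pops), "fold": fold}
    write_manifest(out_dir, "sfs", config, [], {"sites": sfs.n_sites}, t0)
    return outputs


def run_fit(out_dir, sfs_path, models: dict, free: dict, samples: dict,
            n_reps_per_eval=10_000, optimizer="coordinate", seed=1) -> dict:
    """Fit one or more model templates to an observed joint SFS and write the
    per-model fits plus the AIC model-selection table."""
    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    obs = JointSFS.load(sfs_path)
    cfg = SampleConfig(samples)
    fits = []
    for mid, model in models.items():
        fit = fit_parameters(
            obs, _load_model(model), cfg, free,
            n_reps_per_eval=n_reps_per_eval, optimizer=optimizer,
            seed=seed, model_id=mid,
        )
        fits.append(fit)
        with open(os.path.join(out_dir, f"fit_{mid}.json"), "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
            fh.write("\n")
    tab = model_selection_table(fits)
    tab.to_csv(os.path.join(out_dir, "model_table.tsv"), sep="\t", index=False)
    config = {"sfs": sfs_path, "models": list(models), "free": {k: list(v) for k, v in free.items()},
              "samples": samples, "n_reps_per_eval": n_reps_per_eval}
    write_manifest(out_dir, "fit", config, [seed], {"models": len(fits)}, t0)
    return {"model_table": os.path.join(out_dir, "model_table.tsv")}


def run_scan(out_dir, vcf, popmap, window_bp=10_000, pops=("N", "C", "S"),
             outgroup="OUTGROUP", focal_pair=("N", "S"), compute_ld=True,
             gq_min=10, max_missing=2) -> dict:
    """Windowed statistic scan over site-filtered genotypes.

    Applies the standard site filters first (biallelic only, GQ masking,
    missingness cap) and writes the per-rule removal report, then the
    per-window statistic table plus genome-wide (ratio-of-sums) FST and dxy
    per pair."""
    from .genotype_io import apply_site_filters

    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    pm = PopulationMap.read_tsv(popmap)
    gm = read_vcf(vcf, pm)
    gm, filter_report = apply_site_filters(gm, gq_min=gq_min, max_missing=max_missing)
    filter_report.to_csv(os.path.join(out_dir, "filter_report.tsv"), sep="\t",
                         index=False)
    pol = None
    if outgroup in pm.populations:
        pol = polarize_sites(gm, pm.samples_for(outgroup))
    lengths = {}
    for c in dict.fromkeys(gm.contigs.tolist()):
        lengths[c] = int(np.ceil(gm.positions[gm.contigs == c].max() / window_bp) * window_bp)
    windows = make_windows(lengths, window_bp)
    tab = window_scan(gm, pm, windows, pol=pol, pops=tuple(pops),
                      outgroup=outgroup, focal_pair=tuple(focal_pair),
                      compute_ld=compute_ld)
    scan_path = os.path.join(out_dir, "scan.tsv")
    tab.to_csv(scan_path, sep="\t", index=False)

    gw = []
    all_sites = np.arange(gm.n_sites)
    idx = {p: gm.sample_indices(pm.samples_for(p)) for p in pops}
    total_bp = float(sum(lengths.values()))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            gA, gB = gm.genotypes[idx[a]], gm.genotypes[idx[b]]
            fst = fst_window(gA, gB)
            from .popgen_stats import dxy_rnd_window, _counts
            nA, dA = _counts(gm, idx[a], all_sites)
            nB, dB = _counts(gm, idx[b], all_sites)
            dxy, _, _ = dxy_rnd_window(nA, dA, nB, dB, None, None, total_bp)
            gw.append({"pop_a": a, "pop_b": b, "fst": fst, "dxy": dxy})
    gw_path = os.path.join(out_dir, "genomewide.tsv")
    pd.DataFrame(gw).to_csv(gw_path, sep="\t", index=False)

    config = {"vcf": vcf, "popmap": popmap, "window_bp": window_bp,
              "pops": list(pops), "focal_pair": list(focal_pair)}
    write_manifest(out_dir, "scan", config, [], {"windows": len(tab)}, t0)
    return {"scan": scan_path, "genomewide": gw_path}


def run_outliers(out_dir, scan_path, model, samples, fst_col="fst_N_S",
                 pops=("N", "S"), n_sims=1_000, fdr=0.01, top=0.01,
                 low_fst=0.15, window_bp=10_000, seed=1, scale=1.0) -> dict:
    """Outlier flags + simulation-null p/q values for the focal-pair FST."""
    t0 = time.time()
    if not os.path.exists(scan_path):
        raise FileNotFoundError(
            f"missing scan output {scan_path!r}: run the 'scan' stage first"
        )
    os.makedirs(out_dir, exist_ok=True)
    tab = pd.read_csv(scan_path, sep="\t")
    m = _load_model(model)
    if scale != 1.0:
        from .demography import scaled_model

        m = scaled_model(m, scale)
    cfg = SampleConfig(samples)
    flags = flag_outlier_windows(
        tab, fst_col=fst_col,
        tajd_cols=(f"tajD_{pops[0]}", f"tajD_{pops[1]}"),
        fst_top_fraction=top, low_fst_threshold=low_fst,
    )
    null = simulate_null_fst(m, cfg, n_sims, tuple(pops), window_bp=window_bp, seed=seed)
    np.savetxt(os.path.join(out_dir, "null_fst.txt"), null, fmt="%.6f")
    pq = null_fst_pvalues(tab[fst_col].to_numpy(float), null, fdr_level=fdr)
    out = pd.concat([flags.reset_index(drop=True),
                     pq.drop(columns=["fst"]).reset_index(drop=True)], axis=1)
    out_path = os.path.join(out_dir, "outliers.tsv")
    out.to_csv(out_path, sep="\t", index=False)
    config = {"scan": scan_path, "n_sims": n_sims, "fdr": fdr, "top": top,
              "low_fst": low_fst, "pops": list(pops)}
    write_manifest(out_dir, "outliers", config, [seed],
                   {"windows": len(out), "null_windows": len(null),
                    "candidate_high": int(out["candidate_high"].sum()),
                    "candidate_low": int(out["candidate_low"].sum())}, t0)
    return {"outliers": out_path, "null": os.path.join(out_dir, "null_fst.txt")}


def _read_bed_genes(path):
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            name = parts[3] if len(parts) > 3 else f"gene{i + 1}"
            genes.append((parts[0], int(parts[1]), int(parts[2]), name))
    return genes


def run_genes(out_dir, vcf, popmap, genes_bed, focal="N",
              pops=("N", "C", "S"), hka_alpha=0.01, pbs_percentile=95.0) -> dict:
    """HKA + PBS positive-selection calls over BED gene intervals."""
    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    pm = PopulationMap.read_tsv(popmap)
    gm = read_vcf(vcf, pm)
    genes = _read_bed_genes(genes_bed)
    others = tuple(p for p in pops if p != focal)
    tab = hka_counts(gm, pm, genes, focal, others)
    idx = {p: gm.sample_indices(pm.samples_for(p)) for p in pops}
    pbs_vals = []
    for c, s0, e0, _ in genes:
        sites = np.nonzero((gm.contigs == c) & (gm.positions - 1 >= s0)
                           & (gm.positions - 1 < e0))[0]
        if len(sites) == 0:
            pbs_vals.append(float("nan"))
            continue
        f = {}
        ps = list(pops)
        for i in range(3):
            for j in range(i + 1, 3):
                g1 = gm.genotypes[np.ix_(idx[ps[i]], sites)]
                g2 = gm.genotypes[np.ix_(idx[ps[j]], sites)]
                f[(ps[i], ps[j])] = fst_window(g1, g2)
        o1, o2 = others
        vals = [f.get((focal, o1), f.get((o1, focal))),
                f.get((focal, o2), f.get((o2, focal))),
                f.get((o1, o2), f.get((o2, o1)))]
        if all(v is not None and np.isfinite(v) and v < 1 for v in vals):
            pbs_vals.append(pbs(max(vals[0], 0), max(vals[1], 0), max(vals[2], 0)))
        else:
            pbs_vals.append(float("nan"))
    tab["pbs"] = pbs_vals
    calls = call_positive_genes(tab, hka_alpha=hka_alpha, pbs_percentile=pbs_percentile)
    path = os.path.join(out_dir, "gene_calls.tsv")
    calls.to_csv(path, sep="\t", index=False)
    config = {"vcf": vcf, "genes_bed": genes_bed, "focal": focal,
              "hka_alpha": hka_alpha, "pbs_percentile": pbs_percentile}
    write_manifest(out_dir, "genes", config, [],
                   {"genes": len(calls),
                    "positive": int(calls["positive_selection"].sum())}, t0)
    return {"gene_calls": path}


def run_report(out_dir) -> dict:
    """Plain-text summary + deterministic figures from existing stage outputs."""
    t0 = time.time()
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = ["aspenscan run summary", "====================="]
    gw_path = os.path.join(out_dir, "genomewide.tsv")
    if os.path.exists(gw_path):
        gw = pd.read_csv(gw_path, sep="\t")
        lines.append("genome-wide differentiation (ratio of sums):")
        for _, r in gw.iterrows():
            lines.append(
                f"  FST({r.pop_a},{r.pop_b}) = {r.fst:.4f}   "
                f"dxy({r.pop_a},{r.pop_b}) = {r.dxy:.5f}"
            )
    scan_path = os.path.join(out_dir, "scan.tsv")
    figures = []
    if os.path.exists(scan_path):
        tab = pd.read_csv(scan_path, sep="\t")
        lines.append(f"windows scored: {len(tab)}")
        fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
        mid = (tab["start"] + tab["end"]) / 2
        for ax, col, lab in zip(
            axes,
            [c for c in ("fst_N_S", "dxy_N_S", "pi_N") if c in tab.columns],
            ["FST (N,S)", "dxy (N,S)", "pi (N)"],
        ):
            ax.plot(mid, tab[col], ".", ms=2)
            ax.set_ylabel(lab)
        axes[-1].set_xlabel("window midpoint (bp)")
        fig.tight_layout()
        p = os.path.join(out_dir, "fig_windows.png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        figures.append(p)
    out_tab = os.path.join(out_dir, "outliers.tsv")
    if os.path.exists(out_tab):
        ot = pd.read_csv(out_tab, sep="\t")
        n_hi = int(ot["candidate_high"].sum())
        n_lo = int(ot["candidate_low"].sum())
        if n_hi + n_lo == 0:
            lines.append("outlier testing: zero candidate windows")
        else:
            lines.append(f"outlier candidates: {n_hi} high-FST, {n_lo} low-FST (q < 0.01)")
        lines.append(f"flagged high_diff windows: {int(ot['high_diff'].sum())}")
        lines.append(f"flagged low_diff windows: {int(ot['low_diff'].sum())}")
    genes_tab = os.path.join(out_dir, "gene_calls.tsv")
    if os.path.exists(genes_tab):
        gt = pd.read_csv(genes_tab, sep="\t")
        lines.append(
            f"genes analyzed: {len(gt)}; positively selected: "
            f"{int(gt['positive_selection'].sum())}"
        )
    mt = os.path.join(out_dir, "model_table.tsv")
    if os.path.exists(mt):
        lines.append("model selection table:")
        lines.extend("  " + ln for ln in open(mt).read().rstrip().split("\n"))
    summary = "\n".join(lines) + "\n"
    spath = os.path.join(out_dir, "summary.txt")
    with open(spath, "w") as fh:
        fh.write(summary)
    write_manifest(out_dir, "report", {"dir": str(out_dir)}, [],
                   {"figures": len(figures)}, t0)
    return {"summary": spath, "figures": figures}
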