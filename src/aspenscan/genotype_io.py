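"""Genotype I/O, site filtering, window tiling and outgroup polarization.

Coordinate conventions: VCF POS is 1-based; windows are 0-based half-open
(BED); a site at POS falls in the window containing POS-1.

The site filters mirror a strict short-read genotyping protocol: drop sites
with more than two alleles, mask individual calls with low genotype quality,
drop SNPs flanking indels, then drop sites with too many missing genotypes —
in that order, with a per-rule removal report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "WindowSet",
    "PolarizedSites",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "make_windows",
    "polarize_sites",
]


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid allele dosages with per-call genotype quality.

    ``genotypes[i, s]`` is the ALT-dosage of sample i at site s (0/1/2, or
    :data:`MISSING`).  ``n_alleles`` keeps the original allele count of each
    record so the biallelic filter can act after reading.  ``haplotypes`` is
    the (2*n_samples, n_sites) phased allele matrix when every call in the
    source VCF was phased, else None.
    """

    sample_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    n_alleles: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    ploidy: int = 2

    def __post_init__(self):
        if self.n_alleles is None:
            self.n_alleles = np.full(self.n_sites, 2, dtype=np.int16)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_samples, len(self.positions)):
            raise ValueError("genotype matrix shape mismatch")
        for c in np.unique(self.contigs):
            pos = self.positions[self.contigs == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        g = self.genotypes
        if not np.all((g == MISSING) | ((g >= 0) & (g <= 2))):
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            contigs=self.contigs[index],
            positions=self.positions[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            genotypes=self.genotypes[:, index],
            gq=None if self.gq is None else self.gq[:, index],
            n_alleles=self.n_alleles[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
        )

    def sample_indices(self, samples: list[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([self.sample_ids.index(s) for s in samples], dtype=np.int64)

    def alt_counts(self, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(available haplotypes, ALT dosage sum) per site for a sample set."""
        g = self.genotypes[sample_idx]
        miss = g == MISSING
        return 2 * (~miss).sum(axis=0), np.where(miss, 0, g).sum(axis=0)


@dataclass
class PopulationMap:
    """sample_id -> population label."""

    mapping: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen = []
        for p in self.mapping.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples_for(self, pop: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == pop]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        absent = [s for s in self.mapping if s not in gm.sample_ids]
        if absent:
            raise ValueError(f"mapped samples absent from matrix: {absent}")
        for p in self.populations:
            if not self.samples_for(p):
                raise ValueError(f"population {p!r} has no samples")

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{ln}: expected sample<TAB>population")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class WindowSet:
    """Non-overlapping tiled genomic windows, 0-based half-open."""

    windows: list[tuple[str, int, int]]
    window_size: int

    def __len__(self) -> int:
        return len(self.windows)

    def validate(self) -> None:
        last: dict[str, int] = {}
        for c, s, e in self.windows:
            if not (0 <= s < e and e - s <= self.window_size):
                raise ValueError(f"bad window {(c, s, e)}")
            if c in last and s != last[c]:
                raise ValueError(f"windows not tiled on {c}")
            last[c] = e

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.windows:
                fh.write(f"{c}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path, window_size: int | None = None) -> "WindowSet":
        wins = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                c, s, e = line.split()[:3]
                wins.append((c, int(s), int(e)))
        size = window_size or max(e - s for _, s, e in wins)
        return cls(wins, size)

    def site_window_index(self, gm: GenotypeMatrix) -> np.ndarray:
        """Window index per site (-1 if a site falls outside every window)."""
        out = np.full(gm.n_sites, -1, dtype=np.int64)
        by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for w, (c, s, e) in enumerate(self.windows):
            by_contig.setdefault(c, []).append((s, e, w))
        for c, entries in by_contig.items():
            entries.sort()
            starts = np.array([s for s, _, _ in entries])
            ends = np.array([e for _, e, _ in entries])
            wid = np.array([w for _, _, w in entries])
            on = np.nonzero(gm.contigs == c)[0]
            pos0 = gm.positions[on] - 1  # POS is 1-based
            j = np.searchsorted(starts, pos0, side="right") - 1
            ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
            out[on[ok]] = wid[j[ok]]
        return out


@dataclass
class PolarizedSites:
    """Per-site ancestral state inferred from outgroup consensus."""

    ancestral_is_ref: np.ndarray  # bool; meaningful only where polarizable
    polarizable: np.ndarray  # bool

    def ancestral_allele(self, gm: GenotypeMatrix) -> np.ndarray:
        out = np.where(self.ancestral_is_ref, gm.ref_allele, gm.alt_allele)
        return np.where(self.polarizable, out, "N")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, pop_map: PopulationMap | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    If ``pop_map`` is given the matrix is restricted to the mapped samples (a
    mapped sample absent from the header is an error).  Multi-allelic records
    are kept and annotated via ``n_alleles``; their dosage counts the first
    ALT allele only, pending removal by :func:`apply_site_filters`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if pop_map is not None:
        wanted = [s for s in pop_map.mapping if s in header_samples]
        absent = [s for s in pop_map.mapping if s not in header_samples]
        if absent:
            raise ValueError(f"samples in population map absent from VCF header: {absent}")
        vcf.set_samples(wanted)
    samples = list(vcf.samples)
    ns = len(samples)

    contigs, positions, refs, alts, nall = [], [], [], [], []
    gts, gqs, haps = [], [], []
    all_phased = True
    rec_no = 0
    try:
        for v in vcf:
            rec_no += 1
            contigs.append(v.CHROM)
            positions.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0] if v.ALT else ".")
            nall.append(1 + len(v.ALT))
            row = np.full(ns, MISSING, dtype=np.int8)
            hrow = np.full(2 * ns, MISSING, dtype=np.int8)
            for i, g in enumerate(v.genotypes):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    continue
                row[i] = (a == 1) + (b == 1)
                hrow[2 * i] = 1 if a == 1 else 0
                hrow[2 * i + 1] = 1 if b == 1 else 0
                if not g[2]:
                    all_phased = False
            gts.append(row)
            haps.append(hrow)
            q = v.format("GQ")
            if q is None:
                gqs.append(np.full(ns, -1, dtype=np.int16))
            else:
                q = q.astype(float).reshape(ns, -1)[:, 0]
                q = np.where(np.isfinite(q), q, -1)
                gqs.append(q.astype(np.int16))
    except Exception as err:  # cyvcf2 raises on malformed records
        raise ValueError(f"{path}: malformed VCF near record {rec_no + 1}: {err}") from err

    n_sites = len(positions)
    gm = GenotypeMatrix(
        sample_ids=samples,
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        genotypes=(
            np.array(gts, dtype=np.int8).T if n_sites else np.empty((ns, 0), np.int8)
        ),
        gq=np.array(gqs, dtype=np.int16).T if n_sites else np.empty((ns, 0), np.int16),
        n_alleles=np.array(nall, dtype=np.int16),
        haplotypes=(
            np.array(haps, dtype=np.int8).T if (n_sites and all_phased) else None
        ),
    )
    gm.validate()
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT:GQ, deterministic ordering."""
    sep = "|" if gm.haplotypes is not None else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(gm.contigs.tolist()):
            on = gm.contigs == c
            length = int(gm.positions[on].max()) if on.any() else 0
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for s in range(gm.n_sites):
            cols = []
            for i in range(gm.n_samples):
                d = gm.genotypes[i, s]
                if d == MISSING:
                    gt = f".{sep}."
                elif gm.haplotypes is not None:
                    gt = f"{gm.haplotypes[2 * i, s]}{sep}{gm.haplotypes[2 * i + 1, s]}"
                else:
                    gt = ("0/0", "0/1", "1/1")[d]
                q = -1 if gm.gq is None else gm.gq[i, s]
                cols.append(f"{gt}:{q}" if q >= 0 else f"{gt}:.")
            fh.write(
                f"{gm.contigs[s]}\t{gm.positions[s]}\t.\t{gm.ref_allele[s]}\t"
                f"{gm.alt_allele[s]}\t.\tPASS\t.\tGT:GQ\t" + "\t".join(cols) + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering, windows, polarization
# ---------------------------------------------------------------------------

def apply_site_filters(
    gm: GenotypeMatrix,
    gq_min: int = 10,
    max_missing: int = 2,
    indel_positions: list[tuple[str, int]] | None = None,
    indel_flank_bp: int = 5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the four-rule site filter, in order.

    (i) drop sites with more than two alleles; (ii) set calls with GQ below
    ``gq_min`` to missing; (iii) drop SNPs within ``indel_flank_bp`` of a
    supplied indel position; (iv) drop sites with more than ``max_missing``
    missing genotypes (counted after GQ masking).  Returns the filtered matrix
    and a per-rule report (rule, sites_removed; the GQ rule reports masked
    calls instead of sites).
    """
    if gq_min < 0 or max_missing < 0 or indel_flank_bp < 0:
        raise ValueError("filter thresholds must be >= 0")
    report = []
    # (i) biallelic only
    keep = gm.n_alleles == 2
    report.append(("multiallelic", int((~keep).sum())))
    gm = gm.take_sites(np.nonzero(keep)[0])
    # (ii) GQ masking
    masked = 0
    if gm.gq is not None:
        low = (gm.gq >= 0) & (gm.gq < gq_min) & (gm.genotypes != MISSING)
        masked = int(low.sum())
        if masked:
            gm = GenotypeMatrix(
                sample_ids=gm.sample_ids,
                contigs=gm.contigs,
                positions=gm.positions,
                ref_allele=gm.ref_allele,
                alt_allele=gm.alt_allele,
                genotypes=np.where(low, MISSING, gm.genotypes).astype(np.int8),
                gq=gm.gq,
                n_alleles=gm.n_alleles,
                haplotypes=(
                    None
                    if gm.haplotypes is None
                    else np.where(np.repeat(low, 2, axis=0), MISSING, gm.haplotypes).astype(np.int8)
                ),
            )
    report.append(("low_gq_calls_masked", masked))
    # (iii) indel flanks
    if indel_positions:
        drop = np.zeros(gm.n_sites, dtype=bool)
        for c, p in indel_positions:
            drop |= (gm.contigs == c) & (np.abs(gm.positions - p) <= indel_flank_bp)
        report.append(("near_indel", int(drop.sum())))
        gm = gm.take_sites(np.nonzero(~drop)[0])
    else:
        report.append(("near_indel", 0))
    # (iv) missingness
    n_miss = (gm.genotypes == MISSING).sum(axis=0)
    keep = n_miss <= max_missing
    report.append(("excess_missing", int((~keep).sum())))
    gm = gm.take_sites(np.nonzero(keep)[0])
    return gm, pd.DataFrame(report, columns=["rule", "sites_removed"])


def make_windows(contig_lengths: dict[str, int], size: int = 10_000) -> WindowSet:
    """Tile each contig with non-overlapping windows of ``size`` bp; the final
    partial window keeps its true length."""
    if size <= 0:
        raise ValueError("window size must be > 0")
    wins = []
    for c, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {c!r} has non-positive length")
        start = 0
        while start < length:
            wins.append((c, start, min(start + size, length)))
            start += size
    ws = WindowSet(wins, size)
    ws.validate()
    return ws


def polarize_sites(gm: GenotypeMatrix, outgroup_samples: list[str]) -> PolarizedSites:
    """Infer ancestral alleles from outgroup consensus.

    A site is polarizable iff every non-missing outgroup call carries the same
    allele (strict consensus, no majority rule); heterozygous or fully missing
    outgroups leave the site unpolarized.
    """
    if not outgroup_samples:
        raise ValueError("outgroup sample list is empty")
    idx = gm.sample_indices(outgroup_samples)
    g = gm.genotypes[idx]
    miss = g == MISSING
    any_called = (~miss).sum(axis=0) > 0
    all_ref = np.all(miss | (g == 0), axis=0) & any_called
    all_alt = np.all(miss | (g == 2), axis=0) & any_called
    polarizable = all_ref | all_alt
    return PolarizedSites(ancestral_is_ref=all_ref, polarizable=polarizable)
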