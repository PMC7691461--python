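"""Joint site-frequency-spectrum container.

A :class:`JointSFS` holds a k-dimensional array indexed by derived (or minor,
if folded) allele counts per population.  Observed spectra carry integer site
counts; expected spectra carry proportions normalized over polymorphic classes.
The two monomorphic corners (derived count 0 everywhere / n everywhere) are
kept in the array but excluded by :meth:`polymorphic_mask` from totals,
normalization and likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = ["JointSFS"]


@dataclass
class JointSFS:
    pops: tuple[str, ...]
    n_hap: tuple[int, ...]
    data: np.ndarray
    kind: str = "counts"  # "counts" | "proportions"
    folded: bool = False

    def __post_init__(self):
        self.pops = tuple(self.pops)
        self.n_hap = tuple(int(n) for n in self.n_hap)
        expect = tuple(n + 1 for n in self.n_hap)
        if self.data.shape != expect:
            raise ValueError(f"data shape {self.data.shape} != {expect}")
        if self.kind not in ("counts", "proportions"):
            raise ValueError(f"bad kind {self.kind!r}")
        if np.any(self.data < 0):
            raise ValueError("negative SFS entries")

    def polymorphic_mask(self) -> np.ndarray:
        mask = np.ones(self.data.shape, dtype=bool)
        mask[(0,) * len(self.n_hap)] = False
        if not self.folded:
            mask[tuple(self.n_hap)] = False
        return mask

    @property
    def n_sites(self) -> float:
        return float(self.data[self.polymorphic_mask()].sum())

    def normalized(self) -> "JointSFS":
        """Expected proportions over polymorphic classes (corners zeroed)."""
        mask = self.polymorphic_mask()
        tot = self.data[mask].sum()
        if tot <= 0:
            raise ValueError("no mass on polymorphic classes")
        out = np.where(mask, self.data / tot, 0.0)
        return JointSFS(self.pops, self.n_hap, out, kind="proportions", folded=self.folded)

    def marginal(self, pops) -> "JointSFS":
        """Marginal spectrum over a subset of populations (axis sum)."""
        if self.folded:
            raise ValueError("marginalize before folding")
        keep = [self.pops.index(p) for p in pops]
        drop = tuple(a for a in range(len(self.pops)) if a not in keep)
        data = self.data.sum(axis=drop) if drop else self.data.copy()
        data = np.moveaxis(data, [sorted(keep).index(a) for a in keep], range(len(keep)))
        return JointSFS(
            tuple(pops), tuple(self.n_hap[a] for a in keep), data, kind=self.kind
        )

    def pairwise(self, pop_a: str, pop_b: str) -> "JointSFS":
        return self.marginal((pop_a, pop_b))

    def fold(self) -> "JointSFS":
        """Fold onto minor-allele classes.

        Cell c and its complement n-c are merged onto the lexicographically
        smaller of the two count vectors (standard joint folding); the
        monomorphic corners merge onto the zero cell.
        """
        if self.folded:
            return self
        out = np.zeros_like(self.data, dtype=float)
        n = np.array(self.n_hap)
        for cell in product(*(range(k + 1) for k in n)):
            partner = tuple(n - np.array(cell))
            out[min(cell, partner)] += self.data[cell]
        return JointSFS(self.pops, self.n_hap, out, kind=self.kind, folded=True)

    # --- plain-text I/O -----------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#aspenscan-sfs v1\n")
            fh.write("pops\t" + "\t".join(self.pops) + "\n")
            fh.write("n_hap\t" + "\t".join(str(n) for n in self.n_hap) + "\n")
            fh.write(f"kind\t{self.kind}\n")
            fh.write(f"folded\t{int(self.folded)}\n")
            flat = self.data.reshape(self.data.shape[0], -1)
            for row in flat:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "JointSFS":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines or not lines[0].startswith("#aspenscan-sfs"):
            raise ValueError(f"{path}: not an aspenscan SFS file")
        header = {}
        body_start = 1
        for i, ln in enumerate(lines[1:], start=1):
            key = ln.split("\t", 1)[0]
            if key in ("pops", "n_hap", "kind", "folded"):
                header[key] = ln.split("\t")[1:]
                body_start = i + 1
            else:
                break
        pops = tuple(header["pops"])
        n_hap = tuple(int(v) for v in header["n_hap"])
        kind = header["kind"][0]
        folded = bool(int(header["folded"][0]))
        rows = [
            [float(v) for v in ln.split("\t")]
            for ln in lines[body_start:]
            if ln.strip()
        ]
        data = np.array(rows).reshape(tuple(n + 1 for n in n_hap))
        return cls(pops, n_hap, data, kind=kind, folded=folded)
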