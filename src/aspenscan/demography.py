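"""Demographic models for multi-population isolation-with-migration histories.

A :class:`DemographicModel` describes an arbitrary number of populations with
piecewise-constant diploid sizes, ordered split (merge, looking backward) events,
an optional bottleneck per population, and a constant backward migration matrix.
Time is measured in generations before present throughout; years appear only at
I/O boundaries (:func:`years_from_generations` and friends live in
:mod:`aspenscan.sfs_demography`).

Migration convention
--------------------
``migration[(i, j)]`` is the backward-in-time per-generation probability that a
lineage currently in population ``i`` traces its ancestry to population ``j``.
A forward-time migration rate "from X to Y" therefore enters the matrix as
``migration[(Y, X)]``.  Rates apply only while both populations exist.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographicModel",
    "SampleConfig",
    "CompiledModel",
    "table1_model",
    "scaled_model",
    "model_families",
    "MU_PER_YEAR",
    "GENERATION_YEARS",
]

#: Annual per-site mutation rate assumed for Populus.
MU_PER_YEAR = 2.5e-9
#: Years per generation assumed for Populus.
GENERATION_YEARS = 15.0


@dataclass
class DemographicModel:
    """Piecewise-constant multi-population IM demography.

    Parameters
    ----------
    populations
        Ordered population labels (e.g. ``["N", "C", "S"]``).
    Ne
        Present-day diploid effective size per population.
    splits
        ``(time_gen, derived, ancestral)`` events: looking backward, at
        ``time_gen`` all lineages of ``derived`` merge into ``ancestral``.
        Must be consistent with a tree topology (each population is derived in
        at most one split).
    migration
        Backward migration rates ``{(i, j): rate}``; see module docstring.
    size_changes
        Optional ``{pop: [(time_gen, Ne_from_then_backward), ...]}`` steps.
    bottlenecks
        Optional ``[(pop, start_gen, end_gen, Ne_during)]`` intervals.
    mu_per_year, generation_years
        Mutation clock; per-generation per-site rate is their product.
    """

    populations: list[str]
    Ne: dict[str, float]
    splits: list[tuple[float, str, str]] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    size_changes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    bottlenecks: list[tuple[str, float, float, float]] = field(default_factory=list)
    mu_per_year: float = MU_PER_YEAR
    generation_years: float = GENERATION_YEARS

    @property
    def mu_per_gen(self) -> float:
        return self.mu_per_year * self.generation_years

    def validate(self) -> None:
        pops = set(self.populations)
        if len(pops) != len(self.populations):
            raise ValueError("duplicate population labels")
        for p, ne in self.Ne.items():
            if p not in pops:
                raise ValueError(f"Ne given for unknown population {p!r}")
            if not (np.isfinite(ne) and ne > 0):
                raise ValueError(f"Ne[{p!r}] must be finite and > 0")
        for p in self.populations:
            if p not in self.Ne:
                raise ValueError(f"missing Ne for population {p!r}")
        derived_seen = set()
        for t, d, a in self.splits:
            if not (np.isfinite(t) and t > 0):
                raise ValueError("split times must be finite and > 0")
            if d not in pops or a not in pops:
                raise ValueError(f"split references unknown population ({d}, {a})")
            if d in derived_seen:
                raise ValueError(f"population {d!r} is derived in two splits")
            derived_seen.add(d)
        # topology consistency: walking backward, a merge target must still exist
        alive = set(self.populations)
        for t, d, a in sorted(self.splits):
            if d not in alive:
                raise ValueError(f"split at {t}: {d!r} already merged away")
            if a not in alive:
                raise ValueError(f"split at {t}: target {a!r} already merged away")
            alive.remove(d)
        if len(alive) != 1 and len(self.populations) > 1:
            raise ValueError("splits do not merge all populations into one")
        for (i, j), m in self.migration.items():
            if i not in pops or j not in pops:
                raise ValueError(f"migration references unknown population ({i}, {j})")
            if i == j:
                raise ValueError("migration diagonal entries are not allowed")
            if not (np.isfinite(m) and m >= 0):
                raise ValueError("migration rates must be finite and >= 0")
        for p, steps in self.size_changes.items():
            if p not in pops:
                raise ValueError(f"size change for unknown population {p!r}")
            for t, ne in steps:
                if not (np.isfinite(t) and t > 0 and np.isfinite(ne) and ne > 0):
                    raise ValueError("size-change entries must be positive and finite")
        for p, t0, t1, ne in self.bottlenecks:
            if p not in pops:
                raise ValueError(f"bottleneck for unknown population {p!r}")
            if not (0 <= t0 < t1 and ne > 0):
                raise ValueError("bottleneck needs 0 <= start < end and Ne > 0")
        if not (np.isfinite(self.mu_per_year) and self.mu_per_year >= 0):
            raise ValueError("mu_per_year must be finite and >= 0")
        if not (np.isfinite(self.generation_years) and self.generation_years > 0):
            raise ValueError("generation_years must be finite and > 0")

    # --- parameter access by dotted name (used by the fitting code) ---------

    def get_param(self, name: str) -> float:
        kind, _, rest = name.partition(":")
        if kind == "Ne":
            return self.Ne[rest]
        if kind == "Ne_past":
            pop, _, idx = rest.partition("@")
            return self.size_changes[pop][int(idx)][1]
        if kind == "Tsplit":
            for t, d, a in self.splits:
                if d == rest:
                    return t
            raise KeyError(name)
        if kind == "mig":
            i, _, j = rest.partition(">")
            return self.migration[(i, j)]
        raise KeyError(name)

    def with_param(self, name: str, value: float) -> "DemographicModel":
        """Return a copy with one named parameter replaced.

        Names: ``Ne:P``, ``Ne_past:P@k``, ``Tsplit:P`` (split where P is the
        derived population; tied size changes at the same time move with it),
        ``mig:I>J`` (backward rate i→j).
        """
        m = self.copy()
        kind, _, rest = name.partition(":")
        if kind == "Ne":
            m.Ne[rest] = value
        elif kind == "Ne_past":
            pop, _, idx = rest.partition("@")
            t, _ = m.size_changes[pop][int(idx)]
            m.size_changes[pop][int(idx)] = (t, value)
        elif kind == "Tsplit":
            done = False
            for k, (t, d, a) in enumerate(m.splits):
                if d == rest:
                    m.splits[k] = (value, d, a)
                    # size changes scheduled exactly at the old split time follow it
                    for p, steps in m.size_changes.items():
                        m.size_changes[p] = [
                            (value, ne) if math.isclose(ts, t) else (ts, ne)
                            for ts, ne in steps
                        ]
                    done = True
            if not done:
                raise KeyError(name)
        elif kind == "mig":
            i, _, j = rest.partition(">")
            m.migration[(i, j)] = value
        else:
            raise KeyError(name)
        return m

    def copy(self) -> "DemographicModel":
        return DemographicModel(
            populations=list(self.populations),
            Ne=dict(self.Ne),
            splits=list(self.splits),
            migration=dict(self.migration),
            size_changes={p: list(v) for p, v in self.size_changes.items()},
            bottlenecks=list(self.bottlenecks),
            mu_per_year=self.mu_per_year,
            generation_years=self.generation_years,
        )

    # --- JSON config ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "Ne": dict(self.Ne),
            "splits": [list(s) for s in self.splits],
            "migration": {f"{i}>{j}": m for (i, j), m in self.migration.items()},
            "size_changes": {p: [list(s) for s in v] for p, v in self.size_changes.items()},
            "bottlenecks": [list(b) for b in self.bottlenecks],
            "mu_per_year": self.mu_per_year,
            "generation_years": self.generation_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        mig = {}
        for key, m in d.get("migration", {}).items():
            i, _, j = key.partition(">")
            mig[(i, j)] = float(m)
        model = cls(
            populations=list(d["populations"]),
            Ne={p: float(v) for p, v in d["Ne"].items()},
            splits=[(float(t), str(a), str(b)) for t, a, b in d.get("splits", [])],
            migration=mig,
            size_changes={
                p: [(float(t), float(ne)) for t, ne in v]
                for p, v in d.get("size_changes", {}).items()
            },
            bottlenecks=[
                (str(p), float(a), float(b), float(ne))
                for p, a, b, ne in d.get("bottlenecks", [])
            ],
            mu_per_year=float(d.get("mu_per_year", MU_PER_YEAR)),
            generation_years=float(d.get("generation_years", GENERATION_YEARS)),
        )
        model.validate()
        return model

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SampleConfig:
    """Haplotype sampling design: ``{population: n_haplotypes}``."""

    haplotypes: dict[str, int]

    def validate(self, model: DemographicModel) -> None:
        if not self.haplotypes or sum(self.haplotypes.values()) < 1:
            raise ValueError("need at least one sampled haplotype")
        for p, n in self.haplotypes.items():
            if p not in model.populations:
                raise ValueError(f"sampled population {p!r} not in model")
            if n < 0:
                raise ValueError("negative haplotype count")

    @property
    def sampled_pops(self) -> list[str]:
        return [p for p, n in self.haplotypes.items() if n > 0]

    @property
    def n_total(self) -> int:
        return sum(self.haplotypes.values())


class CompiledModel:
    """Flat epoch/event arrays consumed by the simulation kernel.

    Epoch boundaries are the union of t=0, size-change times, bottleneck
    boundaries and split times.  Within an epoch all rates are constant;
    merges fire at epoch starts.
    """

    def __init__(self, model: DemographicModel):
        model.validate()
        self.model = model
        pops = model.populations
        self.pop_index = {p: k for k, p in enumerate(pops)}
        P = len(pops)

        bounds = {0.0}
        for t, _, _ in model.splits:
            bounds.add(float(t))
        for steps in model.size_changes.values():
            for t, _ in steps:
                bounds.add(float(t))
        for _, t0, t1, _ in model.bottlenecks:
            bounds.add(float(t0))
            bounds.add(float(t1))
        tb = np.array(sorted(bounds), dtype=np.float64)
        E = len(tb)

        ne = np.zeros((E, P))
        for k, p in enumerate(pops):
            cur = model.Ne[p]
            steps = sorted(model.size_changes.get(p, []))
            for e in range(E):
                t = tb[e]
                val = cur
                for ts, n_ in steps:
                    if t >= ts - 1e-9:
                        val = n_
                for bp, b0, b1, bn in model.bottlenecks:
                    if bp == p and b0 - 1e-9 <= t < b1 - 1e-9:
                        val = bn
                ne[e, k] = val

        alive = np.ones(P, dtype=bool)
        mig = np.zeros((E, P, P))
        merge_epoch: list[int] = []
        merge_from: list[int] = []
        merge_to: list[int] = []
        splits = sorted(model.splits)
        for e in range(E):
            t = tb[e]
            for ts, d, a in splits:
                if abs(ts - t) < 1e-9:
                    merge_epoch.append(e)
                    merge_from.append(self.pop_index[d])
                    merge_to.append(self.pop_index[a])
                    alive[self.pop_index[d]] = False
            for (i, j), m in model.migration.items():
                ii, jj = self.pop_index[i], self.pop_index[j]
                if alive[ii] and alive[jj]:
                    mig[e, ii, jj] = m

        self.t_bounds = tb
        self.ne = ne
        self.mig = mig
        self.merge_epoch = np.array(merge_epoch, dtype=np.int64)
        self.merge_from = np.array(merge_from, dtype=np.int64)
        self.merge_to = np.array(merge_to, dtype=np.int64)

    def sample_pops_array(self, config: SampleConfig) -> np.ndarray:
        """Per-haplotype population index, grouped by population order."""
        out = []
        for p in self.model.populations:
            n = config.haplotypes.get(p, 0)
            out.extend([self.pop_index[p]] * n)
        return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Fixture models
# ---------------------------------------------------------------------------

#: Fitted point estimates of the three-population aspen IM model (years / sizes
#: / forward migration rates as published), used by :func:`table1_model`.
TABLE1_POINT = {
    "Ne_ANC": 2_573_682.0,
    "Ne_N": 45_278.0,
    "Ne_C": 63_365.0,
    "Ne_S": 12_666.0,
    "m_N_to_C": 1.81e-5,
    "m_C_to_N": 4.02e-6,
    "m_N_to_S": 1.74e-7,
    "m_S_to_N": 2.46e-7,
    "m_C_to_S": 1.13e-6,
    "m_S_to_C": 1.53e-5,
    "TDIV_North_South_years": 792_548.0,
    "TDIV_N_C_years": 78_933.0,
}

#: Published 95% parametric-bootstrap ranges for the same parameters.
TABLE1_BOOTSTRAP_RANGE = {
    "Ne_ANC": (2_480_215.0, 2_600_225.0),
    "Ne_N": (43_688.0, 46_671.0),
    "Ne_C": (62_321.0, 65_105.0),
    "Ne_S": (11_123.0, 13_105.0),
    "TDIV_North_South_years": (780_000.0, 800_000.0),
    "TDIV_N_C_years": (77_865.0, 79_025.0),
}

#: Default stand-in outgroup (P. tremula-like): split time and size.
OUTGROUP_SPLIT_YEARS = 5.0e6
OUTGROUP_NE = 100_000.0


def scaled_model(model: DemographicModel, factor: float) -> DemographicModel:
    """Diffusion rescaling: sizes and times divided by ``factor``, migration
    rates multiplied by it.

    The rescaled model has the same coalescent genealogy distribution up to a
    global time contraction, so FST, SFS shape, Tajima's D and all relative
    statistics are unchanged, while per-site diversity (theta = 4 Ne mu)
    shrinks by ``factor``.  Useful for genotype-level simulation when fitted
    parameters imply near-saturating infinite-sites mutation densities.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    m = model.copy()
    m.Ne = {p: v / factor for p, v in m.Ne.items()}
    m.splits = [(t / factor, d, a) for t, d, a in m.splits]
    m.migration = {k: v * factor for k, v in m.migration.items()}
    m.size_changes = {
        p: [(t / factor, ne / factor) for t, ne in steps]
        for p, steps in m.size_changes.items()
    }
    m.bottlenecks = [
        (p, t0 / factor, t1 / factor, ne / factor) for p, t0, t1, ne in m.bottlenecks
    ]
    m.validate()
    return m


def table1_model(include_outgroup: bool = False) -> DemographicModel:
    """Three-population aspen IM model at the published point estimates.

    Populations N (Northeast), C (Central), S (South).  Backward in time, C
    merges into N at the shallow split, then N merges into S at the deep
    North/South split where the size becomes the ancestral Ne.  The merged
    Northern ancestor keeps Ne-N between the two splits, and exchanges
    migrants with S at the N<->S rates (the published table prints no
    parameters for that interval).  With ``include_outgroup`` an ``OUT``
    population joins at a deep interspecific split for polarization.
    """
    g = GENERATION_YEARS
    t_ns = TABLE1_POINT["TDIV_North_South_years"] / g
    t_nc = TABLE1_POINT["TDIV_N_C_years"] / g
    pops = ["N", "C", "S"]
    ne = {
        "N": TABLE1_POINT["Ne_N"],
        "C": TABLE1_POINT["Ne_C"],
        "S": TABLE1_POINT["Ne_S"],
    }
    splits = [(t_nc, "C", "N"), (t_ns, "N", "S")]
    size_changes = {"S": [(t_ns, TABLE1_POINT["Ne_ANC"])]}
    mig = {
        # backward[i][j]: lineage in i came from j == forward rate j -> i
        ("C", "N"): TABLE1_POINT["m_N_to_C"],
        ("N", "C"): TABLE1_POINT["m_C_to_N"],
        ("S", "N"): TABLE1_POINT["m_N_to_S"],
        ("N", "S"): TABLE1_POINT["m_S_to_N"],
        ("S", "C"): TABLE1_POINT["m_C_to_S"],
        ("C", "S"): TABLE1_POINT["m_S_to_C"],
    }
    if include_outgroup:
        pops = pops + ["OUT"]
        ne["OUT"] = OUTGROUP_NE
        splits = splits + [(OUTGROUP_SPLIT_YEARS / g, "OUT", "S")]
    model = DemographicModel(
        populations=pops, Ne=ne, splits=splits, migration=mig, size_changes=size_changes
    )
    model.validate()
    return model


def model_families(include_outgroup: bool = False) -> dict[str, DemographicModel]:
    """Five IM model families for three populations, as fit templates.

    The published study screened twenty parameterizations drawn from five
    families; only the families are recoverable, so each is represented by one
    template initialized near the fitted values:

    - ``asym_migration``: asymmetric migration, constant sizes (the Table 1
      topology; this is the fixture model).
    - ``no_migration``: same topology and sizes, all migration zero.
    - ``asym_migration_expansion``: asymmetric migration with a recent
      step expansion in every current population.
    - ``bottleneck_N``: asymmetric migration plus a bottleneck in N.
    - ``bottleneck_S``: asymmetric migration plus a bottleneck in S.
    """
    base = table1_model(include_outgroup=include_outgroup)
    fams: dict[str, DemographicModel] = {"asym_migration": base}

    nom = base.copy()
    nom.migration = {}
    fams["no_migration"] = nom

    exp_t = 5_000.0 / base.generation_years  # expansion after the last glacial maximum
    expm = base.copy()
    for p in ("N", "C", "S"):
        expm.size_changes.setdefault(p, [])
        expm.size_changes[p] = [(exp_t, base.Ne[p] / 5.0)] + expm.size_changes.get(p, [])
    fams["asym_migration_expansion"] = expm

    t_nc = base.get_param("Tsplit:C")
    bn = base.copy()
    bn.bottlenecks = [("N", 0.4 * t_nc, 0.8 * t_nc, base.Ne["N"] / 10.0)]
    fams["bottleneck_N"] = bn

    bs = base.copy()
    bs.bottlenecks = [("S", 0.4 * t_nc, 0.8 * t_nc, base.Ne["S"] / 10.0)]
    fams["bottleneck_S"] = bs

    for m in fams.values():
        m.validate()
    return fams
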