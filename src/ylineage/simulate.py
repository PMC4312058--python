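"""Synthetic Y-chromosome datasets with known truth.

Generates the statistical structure the analysis assumes: a genealogy per
lineage (star or constant-size Kingman coalescent rescaled so the realized
root age equals the requested founder age), stepwise single-repeat STR
mutation at per-locus rates (Poisson number of mutations per branch, each
+-1 repeat with equal probability), SNP states consistent with the
haplogroup tree, and region-level mixtures of lineages (European vs Inuit
source pools). Identical scenario + seed reproduces byte-identical output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .haplogroups import HaplogroupTree, default_tree
from .types import (
    ANCESTRAL,
    DERIVED,
    Dataset,
    LocusPanel,
    Sample,
    SNPGenotype,
    STRHaplotype,
    yfiler_panel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Genealogy",
    "LineageSpec",
    "SimScenario",
    "SimTruth",
    "simulate_genealogy",
    "mutate_str",
    "place_snps",
    "simulate_dataset",
    "table1_like_scenario",
    "DEFAULT_FOUNDERS",
]


@dataclass(frozen=True)
class Genealogy:
    """Rooted genealogy: leaves 0..n-1; parent[i] = -1 for the root;
    node_time in generations before present (leaves at 0)."""

    n_leaves: int
    parent: np.ndarray
    node_time: np.ndarray
    model: str

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def root_age_generations(self) -> float:
        return float(self.node_time[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.node_time[p] - self.node_time[node])


def simulate_genealogy(
    n: int,
    model: str = "star",
    age_years: float = 7000.0,
    gen_years: float = 25.0,
    seed: int | np.random.Generator | None = None,
) -> Genealogy:
    """Simulate a genealogy of ``n`` lineages rooted at the founder.

    ``star``: n branches of equal length age/gen_years generations.
    ``coalescent``: a constant-size Kingman coalescent whose node times are
    rescaled so the root sits exactly at the founder age (the founder is the
    MRCA by construction).
    """
    if n < 2:
        raise ValueError("need at least two lineages")
    return _genealogy(n, model, age_years, gen_years, np.random.default_rng(seed))


def _genealogy(n, model, age_years, gen_years, rng) -> Genealogy:
    age_gens = age_years / gen_years
    if model == "star":
        parent = np.full(n + 1, n, dtype=np.int64)
        parent[n] = -1
        times = np.zeros(n + 1)
        times[n] = age_gens
        return Genealogy(n, parent, times, "star")
    if model != "coalescent":
        raise ValueError(f"unknown genealogy model: {model!r}")
    if n == 1:
        parent = np.array([1, -1], dtype=np.int64)
        times = np.array([0.0, age_gens])
        return Genealogy(1, parent, times, "coalescent")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))  # coalescent units
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        times[nxt] = t
        active[i] = nxt
        del active[j]
        nxt += 1
    times *= age_gens / times[n_nodes - 1]
    return Genealogy(n, parent, times, "coalescent")


def mutate_str(
    genealogy: Genealogy,
    rates: Mapping[str, float],
    founder: STRHaplotype,
    seed: int | np.random.Generator | None = None,
) -> list[STRHaplotype]:
    """Evolve the founder haplotype down the genealogy under the stepwise
    mutation model and return the leaf haplotypes (leaf order).

    Per branch and locus the mutation count is Poisson(rate x length in
    generations); each mutation is +-1 repeat with equal probability. Repeat
    counts are floored at 1 (a lost locus cannot be observed as an allele).
    """
    rng = np.random.default_rng(seed)
    loci = list(rates)
    rate_vec = np.array([rates[l] for l in loci], dtype=float)
    if (rate_vec < 0).any():
        raise ValueError("mutation rates must be non-negative")
    base = np.array([int(founder.get(l)) for l in loci], dtype=np.int64)

    n_nodes = len(genealogy.parent)
    values = np.zeros((n_nodes, len(loci)), dtype=np.int64)
    order = np.argsort(genealogy.node_time)[::-1]  # root first
    values[genealogy.root] = base
    for node in order:
        p = genealogy.parent[node]
        if p == -1:
            continue
        length = genealogy.branch_length(node)
        muts = rng.poisson(rate_vec * length)
        ups = rng.binomial(muts, 0.5)
        values[node] = values[p] + 2 * ups - muts
    values = np.maximum(values, 1)
    return [
        STRHaplotype(dict(zip(loci, map(int, values[i]))))
        for i in range(genealogy.n_leaves)
    ]


def place_snps(
    tree: HaplogroupTree, lineage: str, markers: Sequence[str] | None = None
) -> SNPGenotype:
    """SNP states consistent with membership of ``lineage``: derived at every
    marker on its root path, ancestral at the other typed markers.

    ``lineage`` may be a node name ("Q-NWT01") or a formatted label
    ("Q-NWT01 (xM265)"). By default every tree marker is typed, so
    assignment recovers the lineage (as its paragroup label) exactly.
    """
    name = lineage.split(" (")[0]
    if name not in tree.node_names:
        raise ValueError(f"unknown lineage: {lineage!r}")
    markers = list(markers) if markers is not None else tree.markers
    path = set(tree.root_path(name))
    states = {}
    for m in markers:
        states[m] = DERIVED if tree.marker_node(m) in path else ANCESTRAL
    return SNPGenotype(states)


#: Plausible modal Yfiler haplotypes (15 analysis loci) used as lineage
#: founders by the default scenarios. Values are in the ordinary allele
#: ranges of the respective haplogroups; they are synthetic, not published
#: founder haplotypes.
DEFAULT_FOUNDERS: dict[str, dict[str, int]] = {
    "Q-NWT01": dict(DYS456=14, DYS389I=13, DYS390=23, DYS389b=16, DYS458=16,
                    DYS19=13, DYS393=13, DYS391=10, DYS439=12, DYS635=22,
                    DYS392=15, GATA_H4=11, DYS437=14, DYS438=11, DYS448=19),
    "Q-M3": dict(DYS456=15, DYS389I=13, DYS390=24, DYS389b=16, DYS458=17,
                 DYS19=13, DYS393=13, DYS391=10, DYS439=11, DYS635=22,
                 DYS392=14, GATA_H4=11, DYS437=14, DYS438=10, DYS448=19),
    "I-M170": dict(DYS456=15, DYS389I=12, DYS390=22, DYS389b=16, DYS458=15,
                   DYS19=16, DYS393=13, DYS391=10, DYS439=11, DYS635=21,
                   DYS392=11, GATA_H4=10, DYS437=16, DYS438=10, DYS448=20),
    "R1a-M513": dict(DYS456=15, DYS389I=13, DYS390=25, DYS389b=17, DYS458=16,
                     DYS19=16, DYS393=13, DYS391=11, DYS439=10, DYS635=23,
                     DYS392=11, GATA_H4=12, DYS437=14, DYS438=11, DYS448=20),
    "R1b-M343": dict(DYS456=16, DYS389I=13, DYS390=24, DYS389b=16, DYS458=17,
                     DYS19=14, DYS393=13, DYS391=11, DYS439=12, DYS635=23,
                     DYS392=13, GATA_H4=11, DYS437=15, DYS438=12, DYS448=19),
    "Q-M120": dict(DYS456=15, DYS389I=13, DYS390=24, DYS389b=17, DYS458=18,
                   DYS19=13, DYS393=12, DYS391=10, DYS439=12, DYS635=21,
                   DYS392=13, GATA_H4=12, DYS437=14, DYS438=11, DYS448=20),
}


@dataclass(frozen=True)
class LineageSpec:
    """One simulated lineage: tree node, founder haplotype, founder age and
    its share of each region's sample."""

    name: str
    age_years: float
    shares: Mapping[str, float]
    founder: STRHaplotype | None = None

    def founder_haplotype(self) -> STRHaplotype:
        if self.founder is not None:
            return self.founder
        if self.name not in DEFAULT_FOUNDERS:
            raise ValueError(f"no default founder haplotype for {self.name}")
        return STRHaplotype(DEFAULT_FOUNDERS[self.name])


@dataclass(frozen=True)
class SimScenario:
    """Demographic and mutational parameters driving the generator."""

    region_sizes: Mapping[str, int]
    lineages: tuple[LineageSpec, ...]
    mutation_rate: float = 6.9e-4  # per locus per generation (evolutionary rate)
    per_locus_rates: Mapping[str, float] | None = None
    gen_years: float = 25.0
    model: str = "star"
    seed: int = 0
    population: str = "Simulated"

    def __post_init__(self):
        for region in self.region_sizes:
            total = sum(l.shares.get(region, 0.0) for l in self.lineages)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"lineage shares for region {region!r} sum to {total}, not 1")

    def rates(self, loci: Sequence[str]) -> dict[str, float]:
        if self.per_locus_rates is not None:
            return {l: float(self.per_locus_rates[l]) for l in loci}
        return {l: self.mutation_rate for l in loci}


@dataclass
class SimTruth:
    """Latent values behind a simulated dataset."""

    lineage_of: dict[str, str]
    founders: dict[str, STRHaplotype]
    genealogies: dict[str, Genealogy]
    root_age_years: dict[str, float]
    scenario: SimScenario

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": list(self.lineage_of),
                "lineage": list(self.lineage_of.values()),
                "root_age_years": [
                    self.root_age_years[l] for l in self.lineage_of.values()
                ],
            }
        )


def simulate_dataset(
    sc: SimScenario,
    tree: HaplogroupTree | None = None,
    panel: LocusPanel | None = None,
) -> tuple[Dataset, SimTruth]:
    """Draw a full dataset from a scenario.

    Region counts per lineage are multinomial in the region shares; each
    lineage is simulated as a single genealogy spanning all its samples, so
    within-lineage relatedness crosses region borders (as it does for real
    lineages). The emitted dataset carries the 17-locus Yfiler layout:
    DYS389II = DYS389I + DYS389b and constant DYS385a/b (not analysis loci).
    """
    tree = tree or default_tree()
    panel = panel or yfiler_panel()
    rng = np.random.default_rng(sc.seed)
    loci = list(panel.analysis_loci)
    rates = sc.rates(loci)

    regions = list(sc.region_sizes)
    shares = np.array(
        [[l.shares.get(r, 0.0) for l in sc.lineages] for r in regions]
    )
    counts = np.zeros((len(regions), len(sc.lineages)), dtype=int)
    for i, r in enumerate(regions):
        n = int(sc.region_sizes[r])
        if n == 0:
            logger.info("region %s has no samples", r)
            continue
        counts[i] = rng.multinomial(n, shares[i])

    samples: list[Sample] = []
    truth = SimTruth({}, {}, {}, {}, sc)
    sample_no = 1
    for j, lin in enumerate(sc.lineages):
        n_lin = int(counts[:, j].sum())
        if n_lin == 0:
            continue
        founder = lin.founder_haplotype()
        genealogy = _genealogy(n_lin, sc.model, lin.age_years, sc.gen_years, rng)
        leaves = mutate_str(genealogy, rates, founder, seed=rng)
        snp = place_snps(tree, lin.name)
        truth.founders[lin.name] = founder
        truth.genealogies[lin.name] = genealogy
        truth.root_age_years[lin.name] = genealogy.root_age_generations * sc.gen_years
        k = 0
        for i, r in enumerate(regions):
            for _ in range(counts[i, j]):
                h = leaves[k]
                k += 1
                sid = f"SIM{sample_no:04d}"
                sample_no += 1
                full = h.alleles
                full["DYS389II"] = full["DYS389I"] + full["DYS389b"]
                full.setdefault("DYS385a", 11)
                full.setdefault("DYS385b", 14)
                samples.append(
                    Sample(id=sid, population=sc.population, region=r,
                           snp=snp, str_haplotype=STRHaplotype(full))
                )
                truth.lineage_of[sid] = lin.name
    ds = Dataset(samples=samples, panel=panel, regions=tuple(regions))
    return ds, truth


def scenario_from_yaml(path) -> SimScenario:
    """Load a scenario from YAML.

    Layout::

        regions: {East Sermersooq: 68, ...}
        lineages:
          - {name: Q-NWT01, age_years: 7038, shares: {East Sermersooq: 0.54, ...},
             founder: {DYS456: 14, ...}}   # founder optional
        mutation_rate: 6.9e-4
        gen_years: 25
        model: star
        seed: 0
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    lineages = tuple(
        LineageSpec(
            name=l["name"],
            age_years=float(l["age_years"]),
            shares={k: float(v) for k, v in l["shares"].items()},
            founder=STRHaplotype(l["founder"]) if "founder" in l else None,
        )
        for l in cfg["lineages"]
    )
    return SimScenario(
        region_sizes={k: int(v) for k, v in cfg["regions"].items()},
        lineages=lineages,
        mutation_rate=float(cfg.get("mutation_rate", 6.9e-4)),
        per_locus_rates=cfg.get("per_locus_rates"),
        gen_years=float(cfg.get("gen_years", 25.0)),
        model=cfg.get("model", "star"),
        seed=int(cfg.get("seed", 0)),
    )


def table1_like_scenario(seed: int = 0, model: str = "star") -> SimScenario:
    """A scenario mirroring the regional haplogroup mixture of the Greenlandic
    cohort: five regions, two Inuit Q lineages, three European lineages and a
    rare 'other' lineage, with region shares equal to the observed relative
    frequencies. Founder ages of the Inuit lineages are their published
    rho-based TMRCA point estimates; European/other ages are round values in
    the range typical for those haplogroups."""
    region_counts = {
        "East Sermersooq": dict(N=68, nwt=37, m3=19, i=2, r1a=0, r1b=7, other=3),
        "Kujalleq": dict(N=24, nwt=4, m3=10, i=2, r1a=2, r1b=6, other=0),
        "West Sermersooq": dict(N=64, nwt=10, m3=11, i=14, r1a=8, r1b=19, other=2),
        "Qeqqata": dict(N=27, nwt=5, m3=3, i=3, r1a=4, r1b=9, other=3),
        "Qaasuitsup": dict(N=44, nwt=14, m3=9, i=11, r1a=3, r1b=4, other=3),
    }
    keys = dict(nwt="Q-NWT01", m3="Q-M3", i="I-M170", r1a="R1a-M513",
                r1b="R1b-M343", other="Q-M120")
    ages = {"Q-NWT01": 7038.0, "Q-M3": 4366.0, "I-M170": 15000.0,
            "R1a-M513": 12000.0, "R1b-M343": 13000.0, "Q-M120": 20000.0}
    lineages = []
    for key, name in keys.items():
        shares = {r: c[key] / c["N"] for r, c in region_counts.items()}
        lineages.append(LineageSpec(name=name, age_years=ages[name], shares=shares))
    return SimScenario(
        region_sizes={r: c["N"] for r, c in region_counts.items()},
        lineages=tuple(lineages),
        model=model,
        seed=seed,
    )
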