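"""End-to-end analysis pipeline: read -> assign -> group -> summarise ->
distances -> MDS -> networks -> TMRCA -> report bundle.

Every stage writes plain-text outputs (TSV / GraphML / YAML manifest) into
the configured output directory; a stage failure aborts with a message
naming the stage. Runs are deterministic for a fixed config and seed.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import (
    count_distinct_haplotypes,
    haplotype_diversity,
    intra_population_variance,
    mean_pairwise_difference,
)
from .distances import classical_mds, fst_haplogroup, rst
from .disclap import disclap_distance_matrix
from .haplogroups import (
    assign_haplogroup,
    default_grouping,
    default_tree,
    haplogroup_frequencies,
    lineage_group,
    load_grouping,
    load_tree,
)
from .io import apply_exclusions, read_samples
from .network import (
    EVOLUTIONARY_RATE,
    build_mj_network,
    locus_weights,
    rho_statistic,
    select_founder,
    tmrca_from_rho,
    write_graphml,
)
from .types import Dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | Path
    output_dir: str | Path
    tree_path: str | Path | None = None
    grouping_path: str | Path | None = None
    n_permutations: int = 10_000
    mds_dimensions: int = 2
    network_epsilon: float = 0.0
    rate: float = EVOLUTIONARY_RATE
    gen_years: float = 25.0
    seed: int = 0
    #: haplogroup labels to build networks / date; default: the "Inuit"
    #: group of the grouping config.
    network_labels: tuple[str, ...] | None = None
    disclap_clusters: int = 1

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(f"input table not found: {self.input_path}")
        for p, what in ((self.tree_path, "tree config"), (self.grouping_path, "grouping config")):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{what} not found: {p}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("read")
def _read(cfg: RunConfig) -> Dataset:
    return apply_exclusions(read_samples(cfg.input_path))


@_stage("assign")
def _assign(ds: Dataset, tree):
    return {s.id: assign_haplogroup(s, tree) for s in ds.snp_samples()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and return a dict of results and output paths."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = load_tree(cfg.tree_path) if cfg.tree_path else default_tree()
    grouping = load_grouping(cfg.grouping_path) if cfg.grouping_path else default_grouping()

    t_start = time.perf_counter()
    ds = _read(cfg)
    loci = ds.panel.analysis_loci

    # exclusion log
    excl = pd.DataFrame(
        [
            (s.id, "excluded" if s.excluded else "str-excluded",
             s.exclusion_reason or s.str_exclusion_reason)
            for s in ds.samples
            if s.excluded or s.str_excluded
        ],
        columns=["id", "scope", "reason"],
    )
    excl.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)

    calls = _assign(ds, tree)

    freq = haplogroup_frequencies(ds, calls)
    freq.to_tsv(outdir / "haplogroup_frequencies.tsv")

    # continental-origin groups per region
    group_rows = []
    for s in ds.snp_samples():
        group_rows.append((s.region, lineage_group(calls[s.id], grouping)))
    gdf = pd.DataFrame(group_rows, columns=["region", "group"])
    gtab = gdf.pivot_table(index="group", columns="region", aggfunc="size", fill_value=0)
    gtab = gtab.reindex(columns=list(ds.regions), fill_value=0)
    gtab.to_csv(outdir / "group_frequencies.tsv", sep="\t")

    # per-haplogroup haplotype summaries (diversity, MPD, Vp)
    by_label: dict[str, list] = {}
    for s in ds.str_samples():
        by_label.setdefault(calls[s.id].label, []).append(s.str_haplotype)
    summary_rows = []
    for label in sorted(by_label):
        haps = by_label[label]
        if len(haps) < 2:
            continue
        vecs = [h.vector(loci) for h in haps]
        div = haplotype_diversity(vecs)
        mpd = mean_pairwise_difference(haps, loci)
        vp = intra_population_variance(haps, loci)
        summary_rows.append(
            dict(haplogroup=label, N=len(haps),
                 h=count_distinct_haplotypes(haps, loci),
                 diversity=round(div.value, 3), diversity_se=round(div.se, 3),
                 MPD=round(mpd.mean, 2), MPD_sd=round(mpd.sd, 2),
                 Vp=round(vp.value, 2))
        )
    pd.DataFrame(summary_rows).to_csv(outdir / "haplotype_summary.tsv", sep="\t", index=False)

    # pairwise distances between regions
    regions = [r for r in ds.regions if sum(1 for s in ds.snp_samples() if s.region == r) >= 2]
    label_pops = [
        [calls[s.id].label for s in ds.snp_samples() if s.region == r] for r in regions
    ]
    fst = fst_haplogroup(label_pops, n_perm=cfg.n_permutations, labels=regions, seed=cfg.seed)
    fst.to_dataframe().to_csv(outdir / "fst_haplogroups.tsv", sep="\t")

    str_regions = [r for r in ds.regions if sum(1 for s in ds.str_samples() if s.region == r) >= 2]
    hap_pops = [
        [s.str_haplotype for s in ds.str_samples() if s.region == r] for r in str_regions
    ]
    rst_m = rst(hap_pops, loci, n_perm=cfg.n_permutations, labels=str_regions, seed=cfg.seed + 1)
    rst_m.to_dataframe().to_csv(outdir / "rst_haplotypes.tsv", sep="\t")

    dl = disclap_distance_matrix(
        hap_pops, loci, n_clusters=cfg.disclap_clusters, labels=str_regions, seed=cfg.seed + 2
    )
    dl.to_dataframe().to_csv(outdir / "disclap_distances.tsv", sep="\t")

    mds_out = {}
    for name, mat in (("rst", rst_m), ("disclap", dl)):
        emb = classical_mds(mat, k=cfg.mds_dimensions)
        df = pd.DataFrame(
            emb.coordinates, index=mat.labels,
            columns=[f"MDS{i+1}" for i in range(cfg.mds_dimensions)],
        )
        df.to_csv(outdir / f"mds_{name}.tsv", sep="\t", index_label="population")
        mds_out[name] = emb

    # median-joining networks and rho-TMRCA for the dated lineages
    labels_to_date = (
        list(cfg.network_labels)
        if cfg.network_labels is not None
        else list(grouping.get("Inuit", []))
    )
    dating_rows = []
    networks = {}
    for label in labels_to_date:
        haps = by_label.get(label, [])
        if len(haps) < 2:
            logger.warning("skipping network for %s: fewer than two haplotypes", label)
            continue
        w = locus_weights(haps, loci)
        net = build_mj_network(haps, w, loci, epsilon=cfg.network_epsilon)
        safe = label.split(" ")[0].replace("*", "star")
        write_graphml(net, outdir / f"network_{safe}.graphml")
        founder = select_founder(haps, net, loci)
        rho = rho_statistic(haps, founder, net, loci)
        tm = tmrca_from_rho(rho, rate=cfg.rate, gen_years=cfg.gen_years, n_loci=len(loci))
        networks[label] = net
        dating_rows.append(
            dict(haplogroup=label, N=rho.n, rho=round(rho.rho, 2), sigma=round(rho.sigma, 2),
                 tmrca_years=round(tm.years), tmrca_se_years=round(tm.se_years))
        )
    pd.DataFrame(dating_rows).to_csv(outdir / "tmrca.tsv", sep="\t", index=False)

    manifest = dict(
        package="ylineage", version=__version__, seed=cfg.seed,
        n_permutations=cfg.n_permutations, rate=cfg.rate, gen_years=cfg.gen_years,
        epsilon=cfg.network_epsilon, mds_dimensions=cfg.mds_dimensions,
        n_samples=len(ds), n_snp_samples=len(ds.snp_samples()),
        n_str_samples=len(ds.str_samples()),
        runtime_s=round(time.perf_counter() - t_start, 2),
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return dict(
        dataset=ds, calls=calls, frequencies=freq, summary=pd.DataFrame(summary_rows),
        fst=fst, rst=rst_m, disclap=dl, mds=mds_out, networks=networks,
        dating=pd.DataFrame(dating_rows), manifest=manifest, output_dir=outdir,
    )
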