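"""Reading and writing sample tables; Yfiler pre-processing rules.

File dialect
------------
Tab-separated UTF-8 with a header row. Required columns ``id``,
``population``, ``region``. Y-SNP columns are prefixed ``snp_`` (e.g.
``snp_M242``) with cell values ``der``, ``anc`` or empty (missing). Every
remaining column must be a panel STR locus; allele cells hold repeat counts
(decimal microvariants like ``17.2`` allowed), empty for missing, and two
values separated by ``,`` for a locus duplication. Unparseable allele cells
become missing.
"""
from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .types import (
    ANCESTRAL,
    DERIVED,
    MISSING,
    Dataset,
    LocusPanel,
    Sample,
    SNPGenotype,
    STRHaplotype,
    yfiler_panel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_samples",
    "write_samples",
    "derive_dys389b",
    "apply_exclusions",
]

_SNP_CODES = {"der": DERIVED, "anc": ANCESTRAL, "": MISSING}
_SNP_CODES_INV = {DERIVED: "der", ANCESTRAL: "anc", MISSING: ""}


def _parse_allele(cell: str) -> Fraction | None:
    try:
        return Fraction(str(cell).strip())
    except (ValueError, ZeroDivisionError):
        return None


def read_samples(path: str | Path, panel: LocusPanel | None = None) -> Dataset:
    """Read a sample table into a :class:`Dataset`.

    One sample per row; row count is preserved. Duplicate ids raise;
    an STR column not in the panel raises naming the column.
    """
    panel = panel or yfiler_panel()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "population", "region"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")
    snp_cols = [c for c in df.columns if c.startswith("snp_")]
    str_cols = [c for c in df.columns if c not in required and not c.startswith("snp_")]
    known = set(panel.loci) | {"DYS389b"}
    for c in str_cols:
        if c not in known:
            raise ValueError(f"unknown locus column: {c!r}")

    samples = []
    for _, row in df.iterrows():
        states = {}
        for c in snp_cols:
            code = str(row[c]).strip().lower()
            if code not in _SNP_CODES:
                logger.warning("sample %s: unrecognised SNP state %r at %s -> missing",
                               row["id"], row[c], c)
            states[c[4:]] = _SNP_CODES.get(code, MISSING)
        alleles = {}
        duplicated = []
        for c in str_cols:
            cell = str(row[c]).strip()
            if not cell:
                continue
            if "," in cell:
                duplicated.append(c)
                continue
            v = _parse_allele(cell)
            if v is None:
                logger.warning("sample %s: unparseable allele %r at %s -> missing",
                               row["id"], cell, c)
                continue
            alleles[c] = v
        samples.append(
            Sample(
                id=str(row["id"]),
                population=str(row["population"]),
                region=str(row["region"]),
                snp=SNPGenotype(states),
                str_haplotype=STRHaplotype(alleles),
                duplicated_loci=tuple(duplicated),
            )
        )
    ds = Dataset(samples=samples, panel=panel)
    logger.info("read %d samples from %s", len(ds), path)
    return ds


def write_samples(ds: Dataset, path: str | Path) -> None:
    """Write a dataset back to the TSV dialect read by :func:`read_samples`."""
    snp_markers: list[str] = []
    for s in ds.samples:
        for m in s.snp.states:
            if m not in snp_markers:
                snp_markers.append(m)
    str_cols = [l for l in ds.panel.loci] + (
        ["DYS389b"] if any("DYS389b" in s.str_haplotype for s in ds.samples) else []
    )
    rows = []
    for s in ds.samples:
        row = {"id": s.id, "population": s.population, "region": s.region}
        for m in snp_markers:
            row[f"snp_{m}"] = _SNP_CODES_INV[s.snp.state(m)]
        for l in str_cols:
            v = s.str_haplotype.get(l)
            if v is None:
                row[l] = ",".join(["?"] * 2) if l in s.duplicated_loci else ""
            else:
                row[l] = str(v) if v.denominator == 1 else f"{float(v):g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def derive_dys389b(h: STRHaplotype) -> STRHaplotype:
    """Add DYS389b = DYS389II - DYS389I, retaining DYS389I.

    DYS389II's amplicon contains the DYS389I repeat stretch; the subtraction
    isolates the second stretch so the two analysis loci are independent.
    Either parent locus missing leaves DYS389b missing; DYS389II < DYS389I is
    an impossible allele pair and raises.
    """
    a, b = h.get("DYS389I"), h.get("DYS389II")
    if a is None or b is None:
        return h.without("DYS389b") if "DYS389b" in h else h
    if b < a:
        raise ValueError(f"impossible allele pair: DYS389II={b} < DYS389I={a}")
    diff = b - a
    if diff == 0:
        logger.warning("DYS389b = 0 (DYS389I == DYS389II == %s): suspicious", a)
    return h.with_allele("DYS389b", diff)


def apply_exclusions(ds: Dataset) -> Dataset:
    """Apply the analysis-panel exclusion rules, returning a new Dataset.

    * DYS389b is derived for every sample first.
    * A duplicated (two-valued) allele at any analysis locus excludes the
      sample entirely (reason "locus duplication").
    * A missing allele at any analysis locus excludes the sample from
      haplotype-level statistics only; it is retained for haplogroup counts.
    """
    analysis = ds.panel.analysis_loci
    out = []
    n_dup = n_inc = 0
    for s in ds.samples:
        h = derive_dys389b(s.str_haplotype)
        s = s.clone(str_haplotype=h)
        dup_analysis = [l for l in s.duplicated_loci if l in analysis]
        if dup_analysis:
            s = s.clone(excluded=True,
                        exclusion_reason=f"locus duplication ({', '.join(dup_analysis)})")
            n_dup += 1
        elif not h.is_complete_on(analysis):
            miss = [l for l in analysis if l not in h]
            s = s.clone(str_excluded=True,
                        str_exclusion_reason=f"incomplete haplotype (missing {', '.join(miss)})")
            n_inc += 1
        out.append(s)
    new = Dataset(samples=out, panel=ds.panel, regions=ds.regions)
    logger.info(
        "exclusions: %d duplicated-locus sample(s) excluded, %d incomplete "
        "haplotype(s) excluded from STR statistics; %d of %d retained for STR analysis",
        n_dup, n_inc, len(new.str_samples()), len(new),
    )
    return new
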