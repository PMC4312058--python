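"""Core domain types: STR haplotypes, SNP genotypes, samples, datasets, locus panels.

Alleles are repeat counts stored as :class:`fractions.Fraction` so that
microvariant alleles such as 17.2 (17 full repeats plus a 2-bp partial
repeat) are represented exactly. Stepwise mutational distances between two
alleles are ``|x - y|`` rounded to the nearest integer; a non-integer
difference (e.g. 17.2 vs 17) signals alleles that are not connected by
whole-repeat steps and triggers a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STRHaplotype",
    "SNPGenotype",
    "Sample",
    "Dataset",
    "LocusPanel",
    "ANCESTRAL",
    "DERIVED",
    "MISSING",
    "YFILER_LOCI",
    "yfiler_panel",
]

ANCESTRAL = "ancestral"
DERIVED = "derived"
MISSING = "missing"
_SNP_STATES = frozenset({ANCESTRAL, DERIVED, MISSING})

#: The 17 AmpFlSTR Yfiler loci in kit order.
YFILER_LOCI: tuple[str, ...] = (
    "DYS456", "DYS389I", "DYS390", "DYS389II", "DYS458", "DYS19",
    "DYS385a", "DYS385b", "DYS393", "DYS391", "DYS439", "DYS635",
    "DYS392", "GATA_H4", "DYS437", "DYS438", "DYS448",
)


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret allele value {value!r}")


@dataclass(frozen=True)
class LocusPanel:
    """An ordered Y-STR locus panel and the subset used for statistics.

    ``analysis_loci`` is the panel on which haplotype-level statistics are
    computed. For the Yfiler kit this is 15 loci: the multi-copy locus
    DYS385a/b is dropped (the physical order of its two alleles cannot be
    determined) and DYS389II is replaced by DYS389b = DYS389II - DYS389I,
    removing the overlap between the two DYS389 fragments.
    """

    loci: tuple[str, ...]
    analysis_loci: tuple[str, ...]

    def __post_init__(self):
        if "DYS385a" in self.analysis_loci or "DYS385b" in self.analysis_loci:
            raise ValueError("analysis panel must exclude DYS385a/b")
        if "DYS389II" in self.analysis_loci:
            raise ValueError("analysis panel carries DYS389b in place of DYS389II")
        unknown = [l for l in self.analysis_loci if l not in self.loci and l != "DYS389b"]
        if unknown:
            raise ValueError(f"analysis loci not in panel: {unknown}")

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_loci)


def yfiler_panel() -> LocusPanel:
    """The default 17-locus Yfiler panel with its 15-locus analysis subset."""
    analysis = tuple(
        ("DYS389b" if l == "DYS389II" else l)
        for l in YFILER_LOCI
        if l not in ("DYS385a", "DYS385b")
    )
    return LocusPanel(loci=YFILER_LOCI, analysis_loci=analysis)


class STRHaplotype:
    """An ordered map locus name -> repeat count (Fraction).

    A locus absent from the mapping is missing. Instances are immutable and
    hashable on their (locus, allele) pairs.
    """

    __slots__ = ("_alleles",)

    def __init__(self, alleles: Mapping[str, object]):
        items = []
        for locus, value in alleles.items():
            v = _as_fraction(value)
            # DYS389b is a derived difference; zero is suspicious but storable
            if v < 0 or (v == 0 and locus != "DYS389b"):
                raise ValueError(f"repeat count at {locus} must be positive, got {v}")
            items.append((locus, v))
        object.__setattr__(self, "_alleles", tuple(items))
        d = dict(items)
        if "DYS389b" in d and "DYS389I" in d and "DYS389II" in d:
            if d["DYS389b"] != d["DYS389II"] - d["DYS389I"]:
                raise ValueError("DYS389b must equal DYS389II - DYS389I")

    @property
    def alleles(self) -> dict[str, Fraction]:
        return dict(self._alleles)

    def get(self, locus: str) -> Fraction | None:
        for l, v in self._alleles:
            if l == locus:
                return v
        return None

    def __contains__(self, locus: str) -> bool:
        return any(l == locus for l, _ in self._alleles)

    def with_allele(self, locus: str, value) -> "STRHaplotype":
        d = self.alleles
        d[locus] = value
        return STRHaplotype(d)

    def without(self, locus: str) -> "STRHaplotype":
        return STRHaplotype({l: v for l, v in self._alleles if l != locus})

    def is_complete_on(self, loci: Iterable[str]) -> bool:
        have = {l for l, _ in self._alleles}
        return all(l in have for l in loci)

    def vector(self, loci: Sequence[str]) -> tuple[Fraction, ...]:
        """Allele vector over ``loci``; raises if any locus is missing."""
        d = dict(self._alleles)
        try:
            return tuple(d[l] for l in loci)
        except KeyError as e:
            raise ValueError(f"haplotype is missing locus {e.args[0]}") from None

    def __eq__(self, other):
        # content equality: locus order is presentation, not identity
        return isinstance(other, STRHaplotype) and sorted(self._alleles) == sorted(other._alleles)

    def __hash__(self):
        return hash(tuple(sorted(self._alleles)))

    def __repr__(self):
        inner = ", ".join(f"{l}={float(v):g}" for l, v in self._alleles)
        return f"STRHaplotype({inner})"


def step_distance(x: Fraction, y: Fraction) -> int:
    """Mutational steps between two repeat counts: |x-y| rounded to integer.

    Non-integer differences (microvariant vs full repeat) cannot arise from
    whole-repeat stepwise mutation; they are rounded with a warning.
    """
    diff = abs(x - y)
    if diff.denominator != 1:
        warnings.warn(
            f"non-integer repeat difference {float(diff):g}; rounding to nearest step",
            stacklevel=2,
        )
    return int(round(float(diff)))


@dataclass(frozen=True)
class SNPGenotype:
    """Binary marker states: marker name -> ancestral / derived / missing."""

    states: Mapping[str, str]

    def __post_init__(self):
        bad = {s for s in self.states.values()} - _SNP_STATES
        if bad:
            raise ValueError(f"invalid SNP states: {sorted(bad)}")
        object.__setattr__(self, "states", dict(self.states))

    def state(self, marker: str) -> str:
        return self.states.get(marker, MISSING)

    def typed(self) -> dict[str, str]:
        return {m: s for m, s in self.states.items() if s != MISSING}


@dataclass
class Sample:
    """One male individual: identifiers, SNP genotype and STR haplotype."""

    id: str
    population: str
    region: str
    snp: SNPGenotype = field(default_factory=lambda: SNPGenotype({}))
    str_haplotype: STRHaplotype = field(default_factory=lambda: STRHaplotype({}))
    #: loci where two alleles were observed (duplication); stored as missing
    #: in the haplotype and grounds for exclusion.
    duplicated_loci: tuple[str, ...] = ()
    excluded: bool = False
    exclusion_reason: str = ""
    #: excluded from haplotype-level statistics only (kept for SNP counts)
    str_excluded: bool = False
    str_exclusion_reason: str = ""

    def clone(self, **changes) -> "Sample":
        return replace(self, **changes)


@dataclass
class Dataset:
    """A collection of samples typed on a common locus panel."""

    samples: list[Sample]
    panel: LocusPanel
    regions: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        if not self.regions:
            seen: list[str] = []
            for s in self.samples:
                if s.region not in seen:
                    seen.append(s.region)
            self.regions = tuple(seen)
        else:
            self.regions = tuple(self.regions)
            for s in self.samples:
                if s.region not in self.regions:
                    raise ValueError(f"sample {s.id} has unknown region {s.region!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def snp_samples(self) -> list[Sample]:
        """Samples usable for haplogroup (SNP-based) statistics."""
        return [s for s in self.samples if not s.excluded]

    def str_samples(self) -> list[Sample]:
        """Samples usable for haplotype (STR-based) statistics."""
        return [s for s in self.samples if not s.excluded and not s.str_excluded]

    def by_region(self, region: str) -> list[Sample]:
        return [s for s in self.samples if s.region == region]
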