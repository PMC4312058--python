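"""Haplogroup assignment against a rooted Y-SNP marker tree.

A Y chromosome is assigned to the deepest tree node whose defining marker is
in the derived state, provided no marker on the path back to the root is
typed ancestral. Markers that were never typed are treated as unknown, not
ancestral — hierarchical typing strategies leave most of the tree untyped
for most samples. Paragroup nomenclature follows the field convention:
``Q-NWT01 (xM265)`` is derived at NWT01 and ancestral at the typed
downstream marker M265; ``Q*-M242`` is derived at M242 and ancestral at all
typed downstream markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .types import ANCESTRAL, DERIVED, Dataset, Sample, SNPGenotype

__all__ = [
    "HaplogroupTree",
    "HaplogroupCall",
    "HaplogroupFrequencyTable",
    "InconsistentGenotypeError",
    "UNASSIGNED",
    "assign_haplogroup",
    "nomenclature",
    "lineage_group",
    "haplogroup_frequencies",
    "load_tree",
    "load_grouping",
    "default_tree",
    "default_grouping",
]

UNASSIGNED = "unassigned"


class InconsistentGenotypeError(ValueError):
    """Derived states observed on disjoint root-paths (or within one node)."""


@dataclass(frozen=True)
class _Node:
    name: str
    parent: str | None
    markers: tuple[str, ...]
    star_form: bool = False


class HaplogroupTree:
    """Rooted marker tree; each marker defines exactly one node."""

    def __init__(self, nodes: dict[str, dict], root: str):
        self._nodes: dict[str, _Node] = {}
        self._children: dict[str, list[str]] = {}
        self._marker_node: dict[str, str] = {}
        for name, spec in nodes.items():
            node = _Node(
                name=name,
                parent=spec.get("parent"),
                markers=tuple(spec.get("markers", ())),
                star_form=bool(spec.get("star_form", False)),
            )
            self._nodes[name] = node
            self._children.setdefault(name, [])
            for m in node.markers:
                if m in self._marker_node:
                    raise ValueError(f"marker {m} defined at two nodes")
                self._marker_node[m] = name
        for name, node in self._nodes.items():
            if node.parent is None:
                continue
            if node.parent not in self._nodes:
                raise ValueError(f"node {name} has unknown parent {node.parent}")
            self._children[node.parent].append(name)
        self.root = root
        if root not in self._nodes or self._nodes[root].parent is not None:
            raise ValueError("root must be a parentless node of the tree")
        # depth cache
        self._depth: dict[str, int] = {}
        for name in self._nodes:
            d, cur = 0, name
            while self._nodes[cur].parent is not None:
                cur = self._nodes[cur].parent
                d += 1
            self._depth[name] = d

    @property
    def node_names(self) -> list[str]:
        return list(self._nodes)

    @property
    def markers(self) -> list[str]:
        return list(self._marker_node)

    def node(self, name: str) -> _Node:
        return self._nodes[name]

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def marker_node(self, marker: str) -> str:
        return self._marker_node[marker]

    def depth(self, name: str) -> int:
        return self._depth[name]

    def root_path(self, name: str) -> list[str]:
        """Nodes from the root down to (and including) ``name``."""
        path = [name]
        while self._nodes[path[-1]].parent is not None:
            path.append(self._nodes[path[-1]].parent)
        return path[::-1]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` lies on the root path of ``b`` (a == b counts)."""
        return a in self.root_path(b)


def load_tree(path: str | Path) -> HaplogroupTree:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return HaplogroupTree(cfg["nodes"], cfg["root"])


def default_tree() -> HaplogroupTree:
    """The bundled tree: I-M170, R-M207 branches and the Q-M242 lineage."""
    with resources.files("ylineage.data").joinpath("haplogroup_tree.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return HaplogroupTree(cfg["nodes"], cfg["root"])


def load_grouping(path: str | Path) -> dict[str, list[str]]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_grouping() -> dict[str, list[str]]:
    with resources.files("ylineage.data").joinpath("lineage_groups.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class HaplogroupCall:
    """The deepest supported haplogroup plus the typed-ancestral children."""

    node: str | None
    tested_ancestral_children: tuple[str, ...] = ()
    star: bool = False
    primary_marker: str = ""
    label: str = field(default="", compare=False)

    @property
    def assigned(self) -> bool:
        return self.node is not None


def _node_state(tree: HaplogroupTree, name: str, typed: dict[str, str]) -> str | None:
    states = {typed[m] for m in tree.node(name).markers if m in typed}
    if DERIVED in states and ANCESTRAL in states:
        raise InconsistentGenotypeError(
            f"node {name}: markers {tree.node(name).markers} both derived and ancestral"
        )
    if DERIVED in states:
        return DERIVED
    if ANCESTRAL in states:
        return ANCESTRAL
    return None


def assign_haplogroup(sample: Sample | SNPGenotype, tree: HaplogroupTree) -> HaplogroupCall:
    """Assign the deepest haplogroup supported by the typed markers.

    Raises :class:`InconsistentGenotypeError` when derived states occur on
    disjoint root-paths; returns the ``unassigned`` sentinel when every typed
    marker is ancestral.
    """
    geno = sample.snp if isinstance(sample, Sample) else sample
    typed = geno.typed()
    if not typed:
        raise ValueError("no typed markers: cannot assign a haplogroup")

    state = {name: _node_state(tree, name, typed) for name in tree.node_names}
    derived_nodes = [n for n, s in state.items() if s == DERIVED]
    if not derived_nodes:
        return HaplogroupCall(node=None, label=UNASSIGNED)

    derived_nodes.sort(key=tree.depth)
    deepest = derived_nodes[-1]
    for n in derived_nodes:
        if not tree.is_ancestor(n, deepest):
            m1 = next(m for m in tree.node(n).markers if typed.get(m) == DERIVED)
            m2 = next(m for m in tree.node(deepest).markers if typed.get(m) == DERIVED)
            raise InconsistentGenotypeError(
                f"derived markers {m1} ({n}) and {m2} ({deepest}) lie on disjoint root-paths"
            )
    for n in tree.root_path(deepest):
        if state[n] == ANCESTRAL:
            m = next(m for m in tree.node(n).markers if typed.get(m) == ANCESTRAL)
            raise InconsistentGenotypeError(
                f"marker {m} ({n}) typed ancestral on the root-path of {deepest}"
            )

    exclusions = []
    any_child_typed_derived = False
    for child in tree.children(deepest):
        s = state[child]
        if s == ANCESTRAL:
            exclusions.extend(m for m in tree.node(child).markers if typed.get(m) == ANCESTRAL)
        elif s == DERIVED:  # cannot happen: child would be deeper
            any_child_typed_derived = True
    node = tree.node(deepest)
    star = bool(node.star_form and exclusions and not any_child_typed_derived)
    call = HaplogroupCall(
        node=deepest,
        tested_ancestral_children=tuple(exclusions),
        star=star,
        primary_marker=node.markers[0] if node.markers else "",
    )
    return HaplogroupCall(
        node=call.node,
        tested_ancestral_children=call.tested_ancestral_children,
        star=call.star,
        primary_marker=call.primary_marker,
        label=nomenclature(call),
    )


def nomenclature(call: HaplogroupCall) -> str:
    """Format a call as the conventional (para)group label.

    ``NAME`` with no typed-ancestral children; ``NAME (xA, B and C)``
    otherwise; ``PREFIX*-MARKER`` for star-form nodes whose typed children
    are all ancestral.
    """
    if call.node is None:
        return UNASSIGNED
    if not call.tested_ancestral_children:
        return call.node
    if call.star:
        prefix = call.node.split("-", 1)[0]
        return f"{prefix}*-{call.primary_marker}"
    ex = list(call.tested_ancestral_children)
    if len(ex) == 1:
        inner = ex[0]
    else:
        inner = ", ".join(ex[:-1]) + " and " + ex[-1]
    return f"{call.node} (x{inner})"


def lineage_group(call: HaplogroupCall | str, grouping: dict[str, list[str]] | None = None) -> str:
    """Map a haplogroup label to its continental-origin group (default config:
    Inuit / European / Other)."""
    grouping = grouping or default_grouping()
    label = call if isinstance(call, str) else call.label
    for group, labels in grouping.items():
        if label in labels:
            return group
    return "Other"


class HaplogroupFrequencyTable:
    """Haplogroup x region counts with recomputable percentages."""

    def __init__(self, counts: pd.DataFrame):
        self.counts = counts  # index: labels, columns: regions (+ "Total")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def percentages(self, decimals: int | None = 0) -> pd.DataFrame:
        pct = 100 * self.counts / self.counts.sum(axis=0)
        return pct if decimals is None else pct.round(decimals)

    def formatted(self) -> pd.DataFrame:
        """Cells as ``count (pct%)``, matching the conventional report layout."""
        pct = self.percentages()
        out = self.counts.astype(str)
        for c in self.counts.columns:
            out[c] = [f"{n} ({int(p)}%)" for n, p in zip(self.counts[c], pct[c])]
        return out

    def to_tsv(self, path) -> None:
        self.formatted().to_csv(path, sep="\t", index_label="haplogroup")


def haplogroup_frequencies(
    ds: Dataset, calls: dict[str, HaplogroupCall]
) -> HaplogroupFrequencyTable:
    """Count haplogroup labels per region (plus a Total column).

    ``calls`` maps sample id -> call; only SNP-eligible samples are counted.
    """
    samples = ds.snp_samples()
    rows = []
    for s in samples:
        if s.id not in calls:
            raise ValueError(f"sample {s.id} has no haplogroup call")
        rows.append((calls[s.id].label, s.region))
    df = pd.DataFrame(rows, columns=["label", "region"])
    counts = (
        df.pivot_table(index="label", columns="region", aggfunc="size", fill_value=0)
        .reindex(columns=list(ds.regions), fill_value=0)
    )
    counts["Total"] = counts.sum(axis=1)
    counts = counts.sort_values("Total", ascending=False)
    return HaplogroupFrequencyTable(counts)
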