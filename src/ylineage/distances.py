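"""Pairwise population distances (AMOVA F_ST / R_ST) with permutation tests,
and classical (Torgerson) multidimensional scaling.

Both fixation indices are single-level AMOVA variance-component ratios
``Phi = sigma2_among / (sigma2_among + sigma2_within)`` computed from a
matrix of squared inter-individual distances:

* F_ST — haplogroup identity: squared distance 0 if two chromosomes carry
  the same haplogroup, 1 otherwise;
* R_ST — stepwise model: squared distance = sum over analysis loci of the
  squared repeat-count difference (Slatkin's convention).

Permutation p-values randomly reassign individuals to the two populations;
p = (k+1)/(B+1) where k counts permuted statistics >= the observed one.
Group sizes are fixed under permutation, so Phi is a monotone decreasing
function of the within-group sum of squares, which is what the loop
compares.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .diversity import analysis_matrix
from .types import STRHaplotype

__all__ = [
    "DistanceMatrix",
    "MDSEmbedding",
    "amova_phi",
    "fst_haplogroup",
    "rst",
    "classical_mds",
]


@dataclass
class DistanceMatrix:
    """Symmetric population-pair distances with permutation p-values."""

    labels: list[str]
    values: np.ndarray
    pvalues: np.ndarray | None = None
    n_permutations: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values.copy(), index=self.labels, columns=self.labels)
        if self.pvalues is not None:
            # conventional layout: distances below the diagonal, p above
            for i in range(len(self.labels)):
                for j in range(i + 1, len(self.labels)):
                    df.iat[i, j] = self.pvalues[i, j]
        return df


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray  # (n_pops, k), centred at the origin
    eigenvalues: np.ndarray  # non-increasing


def _ssd_within(sqd: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    total = 0.0
    for idx in groups:
        if idx.size > 1:
            total += sqd[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def amova_phi(sqd: np.ndarray, sizes: Sequence[int]) -> float:
    """Phi_ST from a squared-distance matrix partitioned into consecutive
    groups of the given sizes (single grouping level)."""
    n = sqd.shape[0]
    if sum(sizes) != n:
        raise ValueError("group sizes do not sum to the matrix dimension")
    bounds = np.cumsum([0, *sizes])
    groups = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    return _phi_from_within(sqd, groups, sizes, sqd.sum() / (2.0 * n))


def _phi_from_within(sqd, groups, sizes, ssd_total=None, ssd_within=None) -> float:
    n = sqd.shape[0]
    g = len(sizes)
    if ssd_total is None:
        ssd_total = sqd.sum() / (2.0 * n)
    if ssd_within is None:
        ssd_within = _ssd_within(sqd, groups)
    ssd_among = ssd_total - ssd_within
    df_within = n - g
    df_among = g - 1
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    nbar = (n - sum(s * s for s in sizes) / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / nbar
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def _pairwise_phi(
    sqd_all: np.ndarray,
    pop_index: list[np.ndarray],
    labels: list[str],
    n_perm: int,
    rng: np.random.Generator,
) -> DistanceMatrix:
    k = len(pop_index)
    values = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.concatenate([pop_index[i], pop_index[j]])
            sub = sqd_all[np.ix_(idx, idx)]
            ni, nj = pop_index[i].size, pop_index[j].size
            sizes = (ni, nj)
            n = ni + nj
            groups = [np.arange(ni), np.arange(ni, n)]
            ssd_total = sub.sum() / (2.0 * n)
            obs_within = _ssd_within(sub, groups)
            phi = _phi_from_within(sub, groups, sizes, ssd_total, obs_within)
            values[i, j] = values[j, i] = phi
            if n_perm > 0:
                hits = 0
                order = np.arange(n)
                for _ in range(n_perm):
                    rng.shuffle(order)
                    perm_groups = [order[:ni], order[ni:]]
                    # larger Phi  <=>  smaller within-group SSD
                    if _ssd_within(sub, perm_groups) <= obs_within + 1e-12:
                        hits += 1
                pvals[i, j] = pvals[j, i] = (hits + 1) / (n_perm + 1)
    return DistanceMatrix(
        labels=labels, values=values,
        pvalues=pvals if n_perm > 0 else None, n_permutations=n_perm,
    )


def _check_pops(pops):
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for i, p in enumerate(pops):
        if len(p) < 2:
            raise ValueError(f"population {i} has fewer than two samples")


def fst_haplogroup(
    pops: Sequence[Sequence[Hashable]],
    n_perm: int = 10_000,
    labels: Sequence[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> DistanceMatrix:
    """Pairwise AMOVA F_ST between populations of haplogroup labels."""
    _check_pops(pops)
    labels = list(labels) if labels is not None else [f"pop{i}" for i in range(len(pops))]
    items = [x for p in pops for x in p]
    # identity distance: 0 if same label else 1
    codes: dict = {}
    coded = np.array([codes.setdefault(x, len(codes)) for x in items])
    sqd = (coded[:, None] != coded[None, :]).astype(float)
    sizes = [len(p) for p in pops]
    bounds = np.cumsum([0, *sizes])
    pop_index = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(pops))]
    rng = np.random.default_rng(seed)
    return _pairwise_phi(sqd, pop_index, labels, n_perm, rng)


def rst(
    pops: Sequence[Sequence[STRHaplotype]],
    loci: Sequence[str],
    n_perm: int = 10_000,
    labels: Sequence[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> DistanceMatrix:
    """Pairwise AMOVA R_ST between populations of complete STR haplotypes.

    Negative point estimates (within-variance exceeding the total) are
    reported as computed.
    """
    _check_pops(pops)
    labels = list(labels) if labels is not None else [f"pop{i}" for i in range(len(pops))]
    X = analysis_matrix([h for p in pops for h in p], loci)
    sqd = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    sizes = [len(p) for p in pops]
    bounds = np.cumsum([0, *sizes])
    pop_index = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(pops))]
    rng = np.random.default_rng(seed)
    return _pairwise_phi(sqd, pop_index, labels, n_perm, rng)


def classical_mds(d: DistanceMatrix | np.ndarray, k: int = 2) -> MDSEmbedding:
    """Torgerson classical scaling of a symmetric distance matrix.

    Negative input distances (possible for AMOVA point estimates) are clamped
    to 0 before embedding. If fewer than ``k`` positive eigenvalues exist the
    remaining coordinates are zero-padded with a warning.
    """
    import warnings

    D = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("need a symmetric square matrix")
    D = np.maximum(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(eigval.max(), 1.0)
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); padding {k - n_pos} coordinate(s) with zeros"
        )
    coords = np.zeros((n, k))
    m = min(k, n_pos)
    coords[:, :m] = eigvec[:, :m] * np.sqrt(eigval[:m])
    return MDSEmbedding(coordinates=coords, eigenvalues=eigval)


def plot_mds(emb: MDSEmbedding, labels: Sequence[str], path=None):
    """Scatter plot of the first two MDS coordinates (optional utility)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    xy = emb.coordinates
    ax.scatter(xy[:, 0], xy[:, 1])
    for (x, y), lab in zip(xy[:, :2], labels):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
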