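"""Cross-sample statistics.

Per-sample SV calls are aggregated into a genes x samples disruption
matrix.  Sample profiles are compared with a normalized mutual-information
distance (a metric on the binarized profiles), embedded with classical
multidimensional scaling, and cluster quality is summarised with a
compactness index.  Two diagnostics guard against batch effects: the
correlation between per-gene coverage and per-gene disruptions (large
values indicate coverage-driven artifacts), and a greedy variance
biclustering that restricts comparison to genes and samples with
consistent coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .detect import SVCall

__all__ = [
    "DisruptionMatrix",
    "read_gene_bed",
    "disruption_counts",
    "mi_distance",
    "mi_distance_matrix",
    "mds_first_coordinate",
    "c_index",
    "coverage_feature_correlation",
    "bicluster_consistent",
]

Gene = tuple[str, str, int, int]  # name, chrom, start, end (0-based half-open)


@dataclass
class DisruptionMatrix:
    """Genes x samples table of SV disruption counts."""

    genes: list[Gene]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints
    tissue: dict[str, str] = field(default_factory=dict)   # sample -> tumor/blood
    disease: dict[str, str] = field(default_factory=dict)  # sample -> disease label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape inconsistent with genes/samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=[g[0] for g in self.genes], columns=self.samples
        )

    def ranking(self, binary: bool = True) -> pd.DataFrame:
        """Genes ranked by the number of samples disrupted (or total calls)."""
        per_gene = (self.counts > 0).sum(axis=1) if binary else self.counts.sum(axis=1)
        df = pd.DataFrame(
            {"gene": [g[0] for g in self.genes], "n_samples_disrupted": per_gene}
        )
        return df.sort_values(
            ["n_samples_disrupted", "gene"], ascending=[False, True]
        ).reset_index(drop=True)


def read_gene_bed(path: str | Path) -> list[Gene]:
    """Load gene intervals from BED (chrom, start, end, name)."""
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            genes.append((name, f[0], int(f[1]), int(f[2])))
    return genes


def disruption_counts(
    calls_by_sample: Mapping[str, Sequence[SVCall]],
    genes: Sequence[Gene],
    tissue: Mapping[str, str] | None = None,
    disease: Mapping[str, str] | None = None,
) -> DisruptionMatrix:
    """Count, per gene and sample, the calls touching the gene.

    A call increments gene g when its regionA or regionB overlaps g; a call
    whose two ends hit two genes increments both, but a call hitting one
    gene with both ends counts once.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    trees: dict[str, IntervalTree] = {}
    for gi, (_, chrom, start, end) in enumerate(genes):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, gi)

    samples = sorted(calls_by_sample)
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for si, sample in enumerate(samples):
        for call in calls_by_sample[sample]:
            hit: set[int] = set()
            for chrom, start, end in (call.regionA, call.regionB):
                tree = trees.get(chrom)
                if tree is not None:
                    hit.update(iv.data for iv in tree.overlap(start, end))
            for gi in hit:
                counts[gi, si] += 1
    return DisruptionMatrix(
        genes=list(genes),
        samples=samples,
        counts=counts,
        tissue=dict(tissue or {}),
        disease=dict(disease or {}),
    )


def _entropy(p: np.ndarray) -> float:
    """Plug-in entropy (nats) with 0*log 0 = 0."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mi_distance(
    x: Sequence[float],
    y: Sequence[float],
    binarize: bool = True,
    n_bins: int = 4,
) -> float:
    """Normalized mutual-information distance D = 1 - I(X;Y)/H(X,Y).

    Entropies are plug-in estimates from the joint histogram of the two
    profiles.  In this normalization D is a metric on [0, 1]: 0 for
    identical (non-constant) profiles, 1 for independent ones.  Profiles
    are binarized (count > 0) by default; ``binarize=False`` uses
    quantile binning of counts into ``n_bins`` levels.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if binarize:
        xi = (x > 0).astype(int)
        yi = (y > 0).astype(int)
    else:
        xi = _quantile_bin(x, n_bins)
        yi = _quantile_bin(y, n_bins)
    joint = pd.crosstab(xi, yi).to_numpy(dtype=float)
    p = joint / joint.sum()
    h_joint = _entropy(p.ravel())
    if h_joint == 0.0:
        return 0.0  # both profiles constant
    h_x = _entropy(p.sum(axis=1))
    h_y = _entropy(p.sum(axis=0))
    mi = h_x + h_y - h_joint
    d = 1.0 - mi / h_joint
    return float(min(1.0, max(0.0, d)))


def _quantile_bin(v: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="left")


def mi_distance_matrix(
    profiles: np.ndarray, binarize: bool = True, n_bins: int = 4
) -> np.ndarray:
    """Pairwise MI distance between the columns of a genes x samples matrix."""
    n = profiles.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mi_distance(
                profiles[:, i], profiles[:, j], binarize=binarize, n_bins=n_bins
            )
    return D


def mds_first_coordinate(D: np.ndarray) -> np.ndarray:
    """First coordinate of the classical (Torgerson) MDS solution.

    Double-centers -D^2/2, takes the leading eigenpair and scales the
    eigenvector by the square root of its eigenvalue.  The sign is fixed so
    the largest-magnitude coordinate is positive.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    lam, v = evals[-1], evecs[:, -1]
    if lam <= 0:
        raise ValueError("degenerate geometry: top eigenvalue is not positive")
    coord = v * math.sqrt(lam)
    if coord[np.argmax(np.abs(coord))] < 0:
        coord = -coord
    return coord


def c_index(D: np.ndarray, cluster: Sequence[int]) -> float:
    """Cluster compactness index in [0, 1]; 1 = maximally compact.

    With S the sum of the m within-cluster pairwise distances and
    S_min/S_max the sums of the m smallest/largest distances anywhere in D,
    returns 1 - (S - S_min)/(S_max - S_min).  (This is one minus the
    Hubert-Levin C statistic, so that larger means better, matching how the
    index is quoted for good clusters.)
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    cluster = sorted(set(cluster))
    if not 2 <= len(cluster) < n:
        raise ValueError("cluster must contain between 2 and n-1 samples")
    iu = np.triu_indices(n, k=1)
    all_d = np.sort(D[iu])
    within = [
        D[a, b] for i, a in enumerate(cluster) for b in cluster[i + 1:]
    ]
    m = len(within)
    s = float(np.sum(within))
    s_min = float(all_d[:m].sum())
    s_max = float(all_d[-m:].sum())
    if s_max == s_min:
        warnings.warn("all pairwise distances equal; c-index degenerate, returning 1")
        return 1.0
    return 1.0 - (s - s_min) / (s_max - s_min)


def coverage_feature_correlation(
    coverage_per_gene: Sequence[float], disruptions_per_gene: Sequence[float]
) -> float:
    """Pearson correlation between per-gene coverage and disruption counts.

    A batch-effect diagnostic: strong correlation means calls track
    coverage rather than biology.  Returns NaN (with a warning) when either
    vector has zero variance.
    """
    x = np.asarray(coverage_per_gene, dtype=float)
    y = np.asarray(disruptions_per_gene, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: coverage/feature correlation undefined")
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _mean_squared_residue(M: np.ndarray) -> float:
    """Cheng-Church mean squared residue of a submatrix."""
    row_mean = M.mean(axis=1, keepdims=True)
    col_mean = M.mean(axis=0, keepdims=True)
    resid = M - row_mean - col_mean + M.mean()
    return float((resid ** 2).mean())


def bicluster_consistent(
    coverage: np.ndarray, max_variance: float
) -> tuple[list[int], list[int]]:
    """Greedy node-deletion biclustering toward consistent coverage.

    Iteratively removes the single row or column whose removal most reduces
    the mean squared residue, until the residue falls below
    ``max_variance``.  Ties break toward rows, then the earlier index.  If
    the matrix would shrink below 2x2 first, the best submatrix found is
    returned with a warning.
    """
    M = np.asarray(coverage, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("coverage matrix must be finite")
    rows = list(range(M.shape[0]))
    cols = list(range(M.shape[1]))
    while True:
        sub = M[np.ix_(rows, cols)]
        if _mean_squared_residue(sub) <= max_variance:
            return rows, cols
        if len(rows) <= 2 and len(cols) <= 2:
            warnings.warn(
                "variance threshold unreachable before 2x2; returning best found"
            )
            return rows, cols
        best: tuple[float, int, int] | None = None  # (msr, axis, position)
        if len(rows) > 2:
            for i in range(len(rows)):
                msr = _mean_squared_residue(
                    M[np.ix_(rows[:i] + rows[i + 1:], cols)]
                )
                if best is None or msr < best[0]:
                    best = (msr, 0, i)
        if len(cols) > 2:
            for j in range(len(cols)):
                msr = _mean_squared_residue(
                    M[np.ix_(rows, cols[:j] + cols[j + 1:])]
                )
                if best is None or msr < best[0]:
                    best = (msr, 1, j)
        assert best is not None
        _, axis, pos = best
        if axis == 0:
            del rows[pos]
        else:
            del cols[pos]
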