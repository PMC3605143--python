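"""Pre-analysis quality assurance.

Before any calling, each sample's insert-size distribution is estimated
nonparametrically, read groups are screened for batch anomalies against the
rest of the sample, and the cohort is reduced to regions with comparable
coverage across samples.  Only matched tumor/blood pairs in which both
samples pass are worth comparing: anomalies here otherwise dominate the
downstream cross-sample statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinAccumulator, BinKey, ReadPairRecord, SequenceDict, bin_index
from .io import density_on_grid
from .rules import RuleConfig, classify_pair

__all__ = [
    "InsertDistribution",
    "QAReport",
    "estimate_insert_distribution",
    "detect_readgroup_anomalies",
    "select_usable_regions",
    "coverage_track",
    "qa_verdict",
]

logger = logging.getLogger(__name__)

Region = tuple[str, int, int]


class InsufficientDataError(ValueError):
    pass


def _intrachrom_distances(pairs: Iterable) -> np.ndarray:
    """Extract |posB - posA| from records; plain numbers pass through."""
    out = []
    for p in pairs:
        if isinstance(p, ReadPairRecord):
            if p.chromA == p.chromB:
                out.append(p.distance)
        else:
            out.append(float(p))
    return np.asarray(out, dtype=float)


@dataclass
class InsertDistribution:
    """Nonparametric estimate of the pair-distance distribution.

    ``density`` is a Gaussian KDE (Silverman bandwidth) on ``grid``;
    quantiles and tail fractions are empirical, so the heavy right tail of
    a real library is represented exactly rather than smoothed away.
    """

    distances: np.ndarray
    grid: np.ndarray
    density: np.ndarray

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        return np.quantile(self.distances, q)

    def tail_fraction(self, d: float) -> float:
        """Proportion of pair distances strictly greater than ``d``."""
        return float(np.mean(self.distances > d))

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


def estimate_insert_distribution(
    pairs: Iterable,
    max_d: float = 1e6,
    grid_points: int = 512,
    min_pairs: int = 100,
) -> InsertDistribution:
    """Estimate the insert-size distribution from intrachromosomal pairs.

    ``pairs`` may be ReadPairRecords (interchromosomal ones are ignored) or
    raw distances.  Distances above ``max_d`` are excluded from the density
    grid but kept for quantiles and tail fractions.
    """
    d = _intrachrom_distances(pairs)
    if d.size < min_pairs:
        raise InsufficientDataError(
            f"need >= {min_pairs} intrachromosomal pairs, got {d.size}"
        )
    grid, density = density_on_grid(d, max_d=max_d, grid_points=grid_points)
    return InsertDistribution(distances=np.sort(d), grid=grid, density=density)


@dataclass
class QAReport:
    """QA outcome for one sample."""

    sample_id: str
    groups: pd.DataFrame  # read_group, n_pairs, median_distance, ks, odd_rate, status
    flags: list[tuple[str, str]] = field(default_factory=list)
    usable_regions: list[Region] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags and bool(self.usable_regions)


def detect_readgroup_anomalies(
    pairs: Iterable[ReadPairRecord],
    rules: RuleConfig | None = None,
    ks_max: float = 0.1,
    odd_rate_ratio_max: float = 2.0,
    min_pairs: int = 500,
    sample_id: str = "",
) -> QAReport:
    """Screen each read group against the rest of the sample.

    Each group with at least ``min_pairs`` pairs is compared to the pooled
    distances of the *other* groups by a two-sample Kolmogorov-Smirnov
    statistic, and its discordant-pair rate to the pooled rate.  Groups are
    flagged when KS > ``ks_max`` or the rate ratio exceeds
    ``odd_rate_ratio_max``; smaller groups are listed as "insufficient" and
    exempt.  Records without a read-group tag form one anonymous group.
    """
    rules = rules or RuleConfig()
    by_group: dict[str, list[ReadPairRecord]] = {}
    tagless = 0
    for rec in pairs:
        rg = rec.read_group
        if not rg:
            tagless += 1
            rg = ""
        by_group.setdefault(rg, []).append(rec)
    if tagless and len(by_group) == 1:
        logger.warning(
            "sample %s has no read-group tags; treating it as one group", sample_id
        )

    dist = {
        rg: _intrachrom_distances(recs) for rg, recs in by_group.items()
    }
    odd = {
        rg: sum(1 for r in recs if classify_pair(r, rules).is_odd)
        for rg, recs in by_group.items()
    }

    rows = []
    flags: list[tuple[str, str]] = []
    for rg in sorted(by_group):
        recs = by_group[rg]
        n = len(recs)
        others = [g for g in by_group if g != rg]
        row = {
            "read_group": rg,
            "n_pairs": n,
            "median_distance": float(np.median(dist[rg])) if dist[rg].size else math.nan,
            "ks": math.nan,
            "odd_rate": odd[rg] / n if n else math.nan,
            "status": "ok",
        }
        if n < min_pairs:
            row["status"] = "insufficient"
            rows.append(row)
            continue
        if others:
            pooled_d = np.concatenate([dist[g] for g in others if dist[g].size > 0]) \
                if any(dist[g].size for g in others) else np.array([])
            if dist[rg].size and pooled_d.size:
                row["ks"] = float(stats.ks_2samp(dist[rg], pooled_d).statistic)
                if row["ks"] > ks_max:
                    row["status"] = "flagged"
                    flags.append((rg, f"ks={row['ks']:.3f}>{ks_max}"))
            pooled_n = sum(len(by_group[g]) for g in others)
            pooled_odd = sum(odd[g] for g in others)
            pooled_rate = pooled_odd / pooled_n if pooled_n else 0.0
            if pooled_rate > 0:
                ratio = row["odd_rate"] / pooled_rate
            else:
                ratio = math.inf if row["odd_rate"] > 0 else 1.0
            if ratio > odd_rate_ratio_max:
                row["status"] = "flagged"
                flags.append((rg, f"odd_rate_ratio={ratio:.2f}>{odd_rate_ratio_max}"))
        rows.append(row)

    groups = pd.DataFrame(
        rows,
        columns=["read_group", "n_pairs", "median_distance", "ks", "odd_rate", "status"],
    )
    return QAReport(sample_id=sample_id, groups=groups, flags=flags)


def coverage_track(acc: BinAccumulator) -> dict[BinKey, int]:
    """Per-bin pair coverage from a finalized accumulator."""
    return {k: b.coverage_pairs for k, b in acc.counts1d.items()}


def select_usable_regions(
    coverage_tracks: Sequence[Mapping[BinKey, int]],
    seqdict: SequenceDict,
    bin_size: int = 1000,
    min_cov: int = 8,
    min_fraction_samples: float = 0.9,
) -> list[Region]:
    """Maximal runs of bins adequately covered in enough samples.

    A bin is usable when at least ``min_fraction_samples`` of the samples
    have >= ``min_cov`` pairs in it; usable runs are returned as sorted,
    non-overlapping, bin-aligned regions (clipped to chromosome length).
    """
    if not coverage_tracks:
        raise ValueError("no coverage tracks given")
    n = len(coverage_tracks)
    regions: list[Region] = []
    for chrom in seqdict.names():
        length = seqdict.length(chrom)
        n_bins = bin_index(length - 1, bin_size) + 1
        run_start: int | None = None
        for bi in range(n_bins):
            ok = sum(1 for t in coverage_tracks if t.get((chrom, bi), 0) >= min_cov)
            usable = ok / n >= min_fraction_samples
            if usable and run_start is None:
                run_start = bi
            elif not usable and run_start is not None:
                regions.append((chrom, run_start * bin_size, bi * bin_size))
                run_start = None
        if run_start is not None:
            regions.append((chrom, run_start * bin_size, min(n_bins * bin_size, length)))
    return regions


def qa_verdict(
    tumor: QAReport | None, blood: QAReport | None
) -> tuple[bool, list[str]]:
    """Pass/fail for one patient's matched tumor/blood pair, with reasons."""
    reasons: list[str] = []
    for label, rep in (("tumor", tumor), ("blood", blood)):
        if rep is None:
            reasons.append(f"{label}: unmatched")
            continue
        for rg, why in rep.flags:
            reasons.append(f"{label}: read group {rg!r} flagged ({why})")
        if not rep.usable_regions:
            reasons.append(f"{label}: no usable regions")
    return (not reasons, reasons)
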