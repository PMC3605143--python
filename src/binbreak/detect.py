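"""Two-pass structural-variation caller.

Pass 1 streams the mapped pairs once, classifying each and tallying it into
the binned accumulator.  Pass 2 walks the (much smaller) accumulator:
2D cells of the same discordant class in adjacent bins are merged by single
linkage into candidate features, each candidate is scored from the mapping
qualities of its supporting pairs, and candidates failing the support-count
or local-coverage-fraction rules are dropped.  No pairwise comparison of
reads ever happens, which keeps the whole analysis linear in input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    BinAccumulator,
    BinKey,
    PairClass,
    ReadPairRecord,
    SequenceDict,
)
from .rules import RuleConfig, classify_pair, scoring_mapq

__all__ = [
    "CallConfig",
    "SVCall",
    "Candidate",
    "pass1",
    "cluster_cells",
    "score_feature",
    "call_svs",
    "cluster_size_distribution",
    "local_topology_tree",
]

Region = tuple[str, int, int]


@dataclass(frozen=True)
class CallConfig:
    """Thresholds applied to candidate clusters before they become calls.

    Defaults implement "more than two supporting reads" and "more than 5%
    of the local coverage"; ``min_support=2`` reproduces the laxer variant.
    """

    min_support: int = 3
    min_support_fraction: float = 0.05
    adjacency_radius: int = 1

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 <= self.min_support_fraction < 1:
            raise ValueError("min_support_fraction must be in [0, 1)")
        if self.adjacency_radius < 0:
            raise ValueError("adjacency_radius must be >= 0")


@dataclass(frozen=True)
class SVCall:
    """A scored, filtered structural-variation feature linking two regions.

    Regions are bin-aligned, 0-based half-open, with regionA <= regionB in
    canonical order.  ``score`` is the probability that not every
    supporting pair was mismapped.
    """

    regionA: Region
    regionB: Region
    sv_class: PairClass
    n_support: int
    local_coverage: int
    support_fraction: float
    score: float
    sample_id: str = ""
    support_names: frozenset[str] = frozenset()


@dataclass
class Candidate:
    """A single-linkage cluster of same-class 2D cells, pre-filtering."""

    sv_class: PairClass
    chromA: str
    chromB: str
    binsA: tuple[int, int]  # inclusive bin range on the A axis
    binsB: tuple[int, int]
    support: dict[str, int] = field(default_factory=dict)  # name -> min mapq
    n_raw: int = 0

    @property
    def n_support(self) -> int:
        return len(self.support)


def pass1(
    pairs: Iterable[ReadPairRecord],
    seqdict: SequenceDict,
    rules: RuleConfig | None = None,
    bin_size: int = 1000,
) -> BinAccumulator:
    """Classify and accumulate every pair in a single pass.

    The returned accumulator is mergeable: partitioning the stream, running
    pass1 on each partition and merging gives a bit-exact identical result.
    """
    rules = rules or RuleConfig()
    acc = BinAccumulator(seqdict, bin_size=bin_size)
    for rec in pairs:
        acc.accumulate(rec, classify_pair(rec, rules))
    return acc


def cluster_cells(acc: BinAccumulator, cfg: CallConfig | None = None) -> list[Candidate]:
    """Merge same-class 2D cells in adjacent bins into candidate clusters.

    Two cells are adjacent when they share both chromosomes and their bin
    indices differ by at most ``adjacency_radius`` on both axes; clusters
    are the connected components (single linkage).  Output is sorted by
    (regionA, regionB, class) and is deterministic.
    """
    cfg = cfg or CallConfig()
    r = cfg.adjacency_radius

    # index cells per (class, chromA, chromB)
    groups: dict[tuple[PairClass, str, str], dict[tuple[int, int], dict[str, int]]] = {}
    raw: dict[tuple[PairClass, str, str], dict[tuple[int, int], int]] = {}
    for ((ca, ba), (cb, bb)), cell in acc.counts2d.items():
        for cls, names in cell.mapq_by_name.items():
            g = groups.setdefault((cls, ca, cb), {})
            g[(ba, bb)] = names
            raw.setdefault((cls, ca, cb), {})[(ba, bb)] = cell.class_tally[cls]

    candidates: list[Candidate] = []
    for (cls, ca, cb), cells in groups.items():
        seen: set[tuple[int, int]] = set()
        for start in cells:
            if start in seen:
                continue
            # BFS over the adjacency neighbourhood
            component = [start]
            seen.add(start)
            frontier = [start]
            while frontier:
                nxt: list[tuple[int, int]] = []
                for (ba, bb) in frontier:
                    for da in range(-r, r + 1):
                        for db in range(-r, r + 1):
                            nb = (ba + da, bb + db)
                            if nb in cells and nb not in seen:
                                seen.add(nb)
                                component.append(nb)
                                nxt.append(nb)
                frontier = nxt
            support: dict[str, int] = {}
            n_raw = 0
            for key in component:
                n_raw += raw[(cls, ca, cb)][key]
                for name, q in cells[key].items():
                    prev = support.get(name)
                    support[name] = q if prev is None else min(prev, q)
            ba_lo = min(k[0] for k in component)
            ba_hi = max(k[0] for k in component)
            bb_lo = min(k[1] for k in component)
            bb_hi = max(k[1] for k in component)
            candidates.append(
                Candidate(
                    sv_class=cls,
                    chromA=ca,
                    chromB=cb,
                    binsA=(ba_lo, ba_hi),
                    binsB=(bb_lo, bb_hi),
                    support=support,
                    n_raw=n_raw,
                )
            )

    candidates.sort(
        key=lambda c: (
            acc.seqdict.rank(c.chromA),
            c.binsA,
            acc.seqdict.rank(c.chromB),
            c.binsB,
            c.sv_class.value,
        )
    )
    return candidates


def score_feature(support_mapqs: Sequence[int]) -> float:
    """Probability that not all supporting pairs were mismapped.

    With p_i = 10^(-q_i/10) the per-pair mismap probability, the score is
    1 - prod(p_i).  It increases with both the number of supports and each
    quality; it is 0 only when every support has mapq 0.
    """
    if len(support_mapqs) == 0:
        raise ValueError("score_feature requires at least one supporting pair")
    prod = 1.0
    for q in support_mapqs:
        if q < 0:
            raise ValueError(f"negative mapq {q}")
        prod *= 10.0 ** (-q / 10.0)
    return 1.0 - prod


def _candidate_regions(
    cand: Candidate, acc: BinAccumulator
) -> tuple[Region, Region]:
    b = acc.bin_size
    ra: Region = (cand.chromA, cand.binsA[0] * b, (cand.binsA[1] + 1) * b)
    rb: Region = (cand.chromB, cand.binsB[0] * b, (cand.binsB[1] + 1) * b)
    return ra, rb


def _local_coverage(cand: Candidate, acc: BinAccumulator) -> int:
    """Pairs of any class whose leftmost end lies in the candidate's bins.

    A- and B-axis bins are pooled as a set, so a bin shared by both axes is
    counted once.
    """
    bins: set[BinKey] = set()
    for bi in range(cand.binsA[0], cand.binsA[1] + 1):
        bins.add((cand.chromA, bi))
    for bi in range(cand.binsB[0], cand.binsB[1] + 1):
        bins.add((cand.chromB, bi))
    return sum(
        acc.counts1d[k].coverage_left for k in bins if k in acc.counts1d
    )


def call_svs(
    acc: BinAccumulator,
    cfg: CallConfig | None = None,
    rules: RuleConfig | None = None,
    sample_id: str = "",
) -> list[SVCall]:
    """Filter and score candidates into SV calls.

    A candidate becomes a call when it has at least ``min_support`` distinct
    supporting pairs and those pairs make up more than
    ``min_support_fraction`` of the local pair coverage.  Pairs beyond the
    distance window are excluded from calling unless the rule config says
    otherwise.
    """
    cfg = cfg or CallConfig()
    rules = rules or RuleConfig()
    calls: list[SVCall] = []
    for cand in cluster_cells(acc, cfg):
        if cand.sv_class is PairClass.BEYOND_WINDOW and not rules.count_beyond_window:
            continue
        n = cand.n_support
        if n < cfg.min_support:
            continue
        cov = _local_coverage(cand, acc)
        frac = n / cov if cov else 0.0
        if frac <= cfg.min_support_fraction:
            continue
        mapqs = [scoring_mapq(q, rules) for q in cand.support.values()]
        ra, rb = _candidate_regions(cand, acc)
        calls.append(
            SVCall(
                regionA=ra,
                regionB=rb,
                sv_class=cand.sv_class,
                n_support=n,
                local_coverage=cov,
                support_fraction=frac,
                score=score_feature(mapqs),
                sample_id=sample_id,
                support_names=frozenset(cand.support),
            )
        )
    return calls


def cluster_size_distribution(
    acc: BinAccumulator, cfg: CallConfig | None = None
) -> pd.DataFrame:
    """Histogram of candidate-cluster sizes per class.

    Diagnostic used to choose the minimum-support threshold: in matched
    samples, large clusters are far more prevalent in tumor than in blood.
    Columns: sv_class, size (distinct supporting pairs), count.
    """
    tally: dict[tuple[str, int], int] = {}
    for cand in cluster_cells(acc, cfg):
        key = (cand.sv_class.value, cand.n_support)
        tally[key] = tally.get(key, 0) + 1
    rows = [
        {"sv_class": cls, "size": size, "count": n}
        for (cls, size), n in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["sv_class", "size", "count"])


def _overlaps(a: Region, b: Region) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def local_topology_tree(
    calls: Sequence[SVCall],
    anchor: Region,
    max_depth: int,
    seqdict: SequenceDict,
) -> dict:
    """Depth-first traversal of the call graph from an anchor region.

    Every call with an end overlapping the current region spawns a child
    node at its partner region.  Each call edge is used at most once, so
    cycles are broken; traversal stops at ``max_depth``.  Returns nested
    records: {region, n_support, sv_class, children}.
    """
    if anchor[0] not in seqdict:
        raise ValueError(f"anchor chromosome {anchor[0]!r} not in sequence dictionary")
    order = sorted(
        range(len(calls)),
        key=lambda i: (
            seqdict.rank(calls[i].regionA[0]),
            calls[i].regionA[1:],
            seqdict.rank(calls[i].regionB[0]),
            calls[i].regionB[1:],
        ),
    )
    used: set[int] = set()

    def expand(region: Region, depth: int) -> list[dict]:
        if depth >= max_depth:
            return []
        children = []
        for i in order:
            if i in used:
                continue
            call = calls[i]
            partner = None
            if _overlaps(call.regionA, region):
                partner = call.regionB
            elif _overlaps(call.regionB, region):
                partner = call.regionA
            if partner is None:
                continue
            used.add(i)
            children.append(
                {
                    "region": list(partner),
                    "n_support": call.n_support,
                    "sv_class": call.sv_class.value,
                    "children": expand(partner, depth + 1),
                }
            )
        return children

    return {
        "region": list(anchor),
        "n_support": None,
        "sv_class": None,
        "children": expand(anchor, 0),
    }
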