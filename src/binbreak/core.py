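"""Coordinate conventions and the mergeable binned accumulators.

All internal coordinates are 0-based, half-open.  Genomic positions are
coarse-grained into fixed-width bins (default 1000 bp, the longest pair
distance considered normal) so that clusters of discordant pairs can be
found by exact key lookup instead of pairwise comparison.  The accumulator
is a commutative monoid under :func:`BinAccumulator.merge`: any partition
of an input stream can be counted independently and merged, bit-exact,
which is what makes the two-pass analysis linear and distributable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "PairClass",
    "ReadPairRecord",
    "SequenceDict",
    "BinAccumulator",
    "bin_index",
    "canonical_2d_key",
]

DEFAULT_BIN_SIZE = 1000

#: MAPQ value reserved by the SAM spec for "quality unavailable".
MAPQ_UNAVAILABLE = 255


class PairClass(enum.Enum):
    """Classification of a mate pair: normal, or one of the discordant kinds."""

    NORMAL = "NORMAL"
    WINDOW_DISTANCE = "WINDOW_DISTANCE"
    BEYOND_WINDOW = "BEYOND_WINDOW"
    ORIENTATION = "ORIENTATION"
    INTERCHROM = "INTERCHROM"

    @property
    def is_odd(self) -> bool:
        return self is not PairClass.NORMAL


ABNORMAL_CLASSES = tuple(c for c in PairClass if c.is_odd)


class SequenceDict:
    """Ordered chromosome dictionary: name -> length.

    Chromosome order is the order of declaration (the input file's sequence
    dictionary), which fixes the canonical ordering used for 2D keys.
    """

    def __init__(self, lengths: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        if not items:
            raise ValueError("sequence dictionary must not be empty")
        self._lengths: dict[str, int] = {}
        self._order: dict[str, int] = {}
        for name, length in items:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            self._order[name] = len(self._order)
            self._lengths[name] = int(length)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceDict):
            return NotImplemented
        return self._lengths == other._lengths and self._order == other._order

    def length(self, name: str) -> int:
        return self._lengths[name]

    def rank(self, name: str) -> int:
        """Position of a chromosome in the canonical order."""
        return self._order[name]

    def names(self) -> list[str]:
        return list(self._lengths)

    def items(self) -> list[tuple[str, int]]:
        return list(self._lengths.items())


@dataclass(frozen=True)
class ReadPairRecord:
    """One mapped mate pair, the unit of streaming input.

    End A is the first end in canonical (chromosome order, position) order;
    use :meth:`make` to build records from unordered ends.
    """

    name: str
    chromA: str
    posA: int
    strandA: str
    chromB: str
    posB: int
    strandB: str
    mapqA: int
    mapqB: int
    read_group: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        for q in (self.mapqA, self.mapqB):
            if not 0 <= q <= 255:
                raise ValueError(f"mapq {q} outside [0, 255]")
        if self.posA < 0 or self.posB < 0:
            raise ValueError("positions must be >= 0")
        for s in (self.strandA, self.strandB):
            if s not in ("+", "-"):
                raise ValueError(f"invalid strand {s!r}")

    @classmethod
    def make(
        cls,
        name: str,
        end1: tuple[str, int, str, int],
        end2: tuple[str, int, str, int],
        seqdict: SequenceDict,
        read_group: str = "",
        sample_id: str = "",
    ) -> "ReadPairRecord":
        """Build a record with ends placed in canonical order.

        Each end is (chrom, pos, strand, mapq).
        """
        k1 = (seqdict.rank(end1[0]), end1[1])
        k2 = (seqdict.rank(end2[0]), end2[1])
        a, b = (end1, end2) if k1 <= k2 else (end2, end1)
        return cls(
            name=name,
            chromA=a[0], posA=a[1], strandA=a[2],
            chromB=b[0], posB=b[1], strandB=b[2],
            mapqA=a[3], mapqB=b[3],
            read_group=read_group, sample_id=sample_id,
        )

    @property
    def min_mapq(self) -> int:
        return min(self.mapqA, self.mapqB)

    @property
    def distance(self) -> int:
        """|posB - posA| between leftmost mapped positions (same-chromosome pairs)."""
        return abs(self.posB - self.posA)


def bin_index(pos: int, bin_size: int) -> int:
    """Bin index of a 0-based position; bins are half-open [k*b, (k+1)*b)."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if pos < 0:
        raise ValueError(f"position must be >= 0, got {pos}")
    return pos // bin_size


BinKey = tuple[str, int]


def canonical_2d_key(
    locA: BinKey, locB: BinKey, seqdict: SequenceDict
) -> tuple[BinKey, BinKey]:
    """Order two (chrom, bin) locations so A->B and B->A pairs share a key."""
    ka = (seqdict.rank(locA[0]), locA[1])
    kb = (seqdict.rank(locB[0]), locB[1])
    return (locA, locB) if ka <= kb else (locB, locA)


@dataclass
class Cell2D:
    """Counts for one 2D cell: pairs of one discordant class joining two bins.

    Per-pair minimum mapping quality is kept keyed by read name so that a
    pair observed twice is deduplicated and merging partial accumulators is
    order-independent (elementwise min).
    """

    n_odd: int = 0
    class_tally: dict[PairClass, int] = field(default_factory=dict)
    mapq_by_name: dict[PairClass, dict[str, int]] = field(default_factory=dict)

    @property
    def read_names(self) -> set[str]:
        out: set[str] = set()
        for names in self.mapq_by_name.values():
            out.update(names)
        return out

    @property
    def mapq_record(self) -> list[int]:
        """Sorted multiset of per-pair min mapq values, all classes pooled."""
        vals: list[int] = []
        for d in self.mapq_by_name.values():
            vals.extend(d.values())
        return sorted(vals)

    def add(self, cls: PairClass, name: str, min_mapq: int) -> None:
        self.n_odd += 1
        self.class_tally[cls] = self.class_tally.get(cls, 0) + 1
        d = self.mapq_by_name.setdefault(cls, {})
        prev = d.get(name)
        d[name] = min_mapq if prev is None else min(prev, min_mapq)

    def merge(self, other: "Cell2D") -> None:
        self.n_odd += other.n_odd
        for cls, n in other.class_tally.items():
            self.class_tally[cls] = self.class_tally.get(cls, 0) + n
        for cls, names in other.mapq_by_name.items():
            d = self.mapq_by_name.setdefault(cls, {})
            for name, q in names.items():
                prev = d.get(name)
                d[name] = q if prev is None else min(prev, q)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cell2D):
            return NotImplemented
        return (
            self.n_odd == other.n_odd
            and self.class_tally == other.class_tally
            and self.mapq_by_name == other.mapq_by_name
        )


@dataclass
class Bin1D:
    """Per-bin 1D tallies: pair coverage and discordant-pair counts by class."""

    coverage_pairs: int = 0   # pairs with either end in the bin (once per pair)
    coverage_left: int = 0    # pairs whose leftmost end is in the bin
    odd_by_class: dict[PairClass, int] = field(default_factory=dict)

    def merge(self, other: "Bin1D") -> None:
        self.coverage_pairs += other.coverage_pairs
        self.coverage_left += other.coverage_left
        for cls, n in other.odd_by_class.items():
            self.odd_by_class[cls] = self.odd_by_class.get(cls, 0) + n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bin1D):
            return NotImplemented
        return (
            self.coverage_pairs == other.coverage_pairs
            and self.coverage_left == other.coverage_left
            and self.odd_by_class == other.odd_by_class
        )


class IncompatibleAccumulatorError(ValueError):
    """Raised when merging accumulators with different bin size or sequences."""


class BinAccumulator:
    """Mergeable 1D/2D binned counting structure for one read-pair stream."""

    def __init__(self, seqdict: SequenceDict, bin_size: int = DEFAULT_BIN_SIZE):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.seqdict = seqdict
        self.bin_size = bin_size
        self.counts1d: dict[BinKey, Bin1D] = {}
        self.counts2d: dict[tuple[BinKey, BinKey], Cell2D] = {}
        self.n_pairs = 0
        self.n_skipped = 0

    # -- accumulation -----------------------------------------------------

    def accumulate(self, rec: ReadPairRecord, cls: PairClass) -> None:
        """Tally one classified pair; unknown chromosomes are skipped and counted."""
        if rec.chromA not in self.seqdict or rec.chromB not in self.seqdict:
            self.n_skipped += 1
            return
        binA: BinKey = (rec.chromA, bin_index(rec.posA, self.bin_size))
        binB: BinKey = (rec.chromB, bin_index(rec.posB, self.bin_size))
        self.n_pairs += 1

        cellA = self.counts1d.setdefault(binA, Bin1D())
        cellA.coverage_pairs += 1
        cellA.coverage_left += 1
        if binB != binA:
            self.counts1d.setdefault(binB, Bin1D()).coverage_pairs += 1

        if cls.is_odd:
            cellA.odd_by_class[cls] = cellA.odd_by_class.get(cls, 0) + 1
            key = canonical_2d_key(binA, binB, self.seqdict)
            self.counts2d.setdefault(key, Cell2D()).add(cls, rec.name, rec.min_mapq)

    # -- merge contract ----------------------------------------------------

    def merge(self, other: "BinAccumulator") -> "BinAccumulator":
        """Pointwise sum with ``other``, in place; returns self.

        Associative and commutative; merging with an empty accumulator is
        the identity.  The result is bit-exact equal to accumulating the
        concatenated input streams.
        """
        if other.bin_size != self.bin_size:
            raise IncompatibleAccumulatorError(
                f"bin_size mismatch: {self.bin_size} != {other.bin_size}"
            )
        if other.seqdict != self.seqdict:
            raise IncompatibleAccumulatorError("sequence dictionaries differ")
        for key1, b in other.counts1d.items():
            self.counts1d.setdefault(key1, Bin1D()).merge(b)
        for key2, c in other.counts2d.items():
            self.counts2d.setdefault(key2, Cell2D()).merge(c)
        self.n_pairs += other.n_pairs
        self.n_skipped += other.n_skipped
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinAccumulator):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.seqdict == other.seqdict
            and self.n_pairs == other.n_pairs
            and self.n_skipped == other.n_skipped
            and self.counts1d == other.counts1d
            and self.counts2d == other.counts2d
        )

    # -- totals ------------------------------------------------------------

    def total_odd_1d(self) -> dict[PairClass, int]:
        out: dict[PairClass, int] = {}
        for b in self.counts1d.values():
            for cls, n in b.odd_by_class.items():
                out[cls] = out.get(cls, 0) + n
        return out

    def total_odd_2d(self) -> dict[PairClass, int]:
        out: dict[PairClass, int] = {}
        for c in self.counts2d.values():
            for cls, n in c.class_tally.items():
                out[cls] = out.get(cls, 0) + n
        return out

    # -- text serialization --------------------------------------------------

    def _sort_key_1d(self, key: BinKey):
        return (self.seqdict.rank(key[0]), key[1])

    def dump(self, fh: TextIO) -> None:
        """Write a sorted, line-oriented TSV dump that round-trips bit-exact.

        Line kinds: ``SQ`` (sequence dict), ``META`` (bin size, totals),
        ``1D`` (per-bin coverage or class counts) and ``2D`` (one line per
        supporting pair name in a 2D cell).
        """
        for name, length in self.seqdict.items():
            fh.write(f"SQ\t{name}\t{length}\n")
        fh.write(f"META\tbin_size\t{self.bin_size}\n")
        fh.write(f"META\tn_pairs\t{self.n_pairs}\n")
        fh.write(f"META\tn_skipped\t{self.n_skipped}\n")
        for key in sorted(self.counts1d, key=self._sort_key_1d):
            b = self.counts1d[key]
            fh.write(f"1D\t{key[0]}\t{key[1]}\tCOVERAGE\t{b.coverage_pairs}\n")
            fh.write(f"1D\t{key[0]}\t{key[1]}\tCOVERAGE_LEFT\t{b.coverage_left}\n")
            for cls in PairClass:
                n = b.odd_by_class.get(cls, 0)
                if n:
                    fh.write(f"1D\t{key[0]}\t{key[1]}\t{cls.value}\t{n}\n")
        for key2 in sorted(
            self.counts2d, key=lambda k: (self._sort_key_1d(k[0]), self._sort_key_1d(k[1]))
        ):
            cell = self.counts2d[key2]
            (ca, ba), (cb, bb) = key2
            for cls in PairClass:
                tally = cell.class_tally.get(cls, 0)
                if not tally:
                    continue
                names = cell.mapq_by_name.get(cls, {})
                fh.write(
                    f"2D\t{ca}\t{ba}\t{cb}\t{bb}\t{cls.value}\t{tally}\t"
                    + ",".join(f"{n}:{q}" for n, q in sorted(names.items()))
                    + "\n"
                )

    @classmethod
    def load(cls, fh: TextIO) -> "BinAccumulator":
        seqs: list[tuple[str, int]] = []
        meta: dict[str, int] = {}
        lines_1d: list[list[str]] = []
        lines_2d: list[list[str]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "SQ":
                seqs.append((parts[1], int(parts[2])))
            elif parts[0] == "META":
                meta[parts[1]] = int(parts[2])
            elif parts[0] == "1D":
                lines_1d.append(parts)
            elif parts[0] == "2D":
                lines_2d.append(parts)
            elif parts[0]:
                raise ValueError(f"unrecognized dump line: {line!r}")
        acc = cls(SequenceDict(seqs), bin_size=meta["bin_size"])
        acc.n_pairs = meta.get("n_pairs", 0)
        acc.n_skipped = meta.get("n_skipped", 0)
        for _, chrom, b, kind, count in lines_1d:
            cell = acc.counts1d.setdefault((chrom, int(b)), Bin1D())
            if kind == "COVERAGE":
                cell.coverage_pairs = int(count)
            elif kind == "COVERAGE_LEFT":
                cell.coverage_left = int(count)
            else:
                cell.odd_by_class[PairClass(kind)] = int(count)
        for _, ca, ba, cb, bb, kind, tally, names in lines_2d:
            key = ((ca, int(ba)), (cb, int(bb)))
            cell2 = acc.counts2d.setdefault(key, Cell2D())
            pcls = PairClass(kind)
            cell2.class_tally[pcls] = int(tally)
            cell2.n_odd += int(tally)
            d = cell2.mapq_by_name.setdefault(pcls, {})
            if names:
                for entry in names.split(","):
                    name, q = entry.rsplit(":", 1)
                    d[name] = int(q)
        return acc
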