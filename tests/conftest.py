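import numpy as np
import pytest

from binbreak.core import ReadPairRecord, SequenceDict
from binbreak.rules import RuleConfig


@pytest.fixture
def seqdict() -> SequenceDict:
    return SequenceDict({"chr1": 10_000_000, "chr2": 8_000_000, "chr3": 5_000_000})


@pytest.fixture
def rules() -> RuleConfig:
    return RuleConfig()


@pytest.fixture
def mkrec(seqdict):
    """Build a canonical ReadPairRecord from two (chrom, pos, strand) ends."""

    counter = {"n": 0}

    def _mk(chromA, posA, strandA, chromB, posB, strandB,
            mapqA=60, mapqB=60, name=None, read_group="rg0", sample_id="s"):
        counter["n"] += 1
        return ReadPairRecord.make(
            name or f"t{counter['n']:06d}",
            (chromA, posA, strandA, mapqA),
            (chromB, posB, strandB, mapqB),
            seqdict,
            read_group=read_group,
            sample_id=sample_id,
        )

    return _mk


@pytest.fixture
def random_stream(seqdict, mkrec):
    """Seeded generator of random read-pair streams mixing all classes."""

    def _gen(n: int, seed: int, odd_fraction: float = 0.2):
        rng = np.random.default_rng(seed)
        chroms = seqdict.names()
        recs = []
        for i in range(n):
            name = f"s{seed}_{i:06d}"
            c = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(0, seqdict.length(c) - 20_000))
            r = rng.random()
            if r > odd_fraction:  # normal FR pair
                recs.append(mkrec(c, pos, "+", c, pos + int(rng.integers(100, 900)), "-", name=name))
            elif r > odd_fraction * 0.66:  # distance anomaly
                recs.append(mkrec(c, pos, "+", c, pos + int(rng.integers(1001, 15_000)), "-", name=name))
            elif r > odd_fraction * 0.33:  # orientation anomaly
                recs.append(mkrec(c, pos, "+", c, pos + int(rng.integers(100, 900)), "+", name=name))
            else:  # interchromosomal
                c2 = chroms[(chroms.index(c) + 1) % len(chroms)]
                pos2 = int(rng.integers(0, seqdict.length(c2) - 1000))
                recs.append(mkrec(c, pos, "+", c2, pos2, "-", name=name))
        return recs

    return _gen
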