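"""Seeded mate-pair simulator with planted structural variants.

Generates position-level paired-end data (no bases are simulated; mapping
is not modelled, only its output): background pairs with normally
distributed insert sizes in FR-inward orientation, a configurable fraction
of mismapped "noise" pairs with a uniformly random mate, and planted SVs --
deletions (distance signature), inversions (orientation signature) and
inter-chromosomal translocations -- each supported by a configurable number
of spanning pairs jittered within one bin of the breakpoints.

Determinism: one generator seeded from ``SimulationConfig.seed`` drives a
scenario; draws happen in a fixed order (background first, then each
planted SV in declaration order), so identical seeds yield byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import ReadPairRecord, SequenceDict

__all__ = [
    "SimulationConfig",
    "PlantedSV",
    "MatchedScenario",
    "simulate_background",
    "simulate_sv_support",
    "emit_alignment_file",
    "write_truth_bedpe",
    "scenario_matched_pair",
]

READ_LEN = 50  # placeholder read length used when emitting SAM


@dataclass(frozen=True)
class PlantedSV:
    """One planted structural variant and the evidence to emit for it."""

    kind: str                      # deletion | inversion | translocation
    chrom: str
    pos: int
    n_support: int = 8
    size: int = 3000               # deletion span; within the 1000-7000 window by default
    partner: tuple[str, int] | None = None  # translocation partner breakpoint

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "inversion", "translocation"):
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.kind == "translocation" and self.partner is None:
            raise ValueError("translocation requires a partner breakpoint")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults emulate a short-insert paired-end library (insert N(400, 50^2))
    at a modest pair density, with a 0.1% mismapped-pair rate -- the tail
    rate observed in well-behaved germline libraries -- and well-mapped true
    pairs (MAPQ 60) against low-confidence noise (MAPQ 15).
    """

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    pairs_per_kb: float = 1.0
    mismap_noise_rate: float = 0.001
    mapq_true: int = 60
    mapq_noise: int = 15
    bin_size: int = 1000
    planted: tuple[PlantedSV, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.mismap_noise_rate < 1:
            raise ValueError("mismap_noise_rate must be in [0, 1)")
        for _, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError("chromosome lengths must be positive")

    @property
    def seqdict(self) -> SequenceDict:
        return SequenceDict(self.chrom_lengths)


def _rng(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def simulate_background(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    read_group: str = "rg0",
    sample_id: str = "sample",
    name_prefix: str = "bg",
) -> list[ReadPairRecord]:
    """Background pairs: uniform leftmost positions, FR-inward, normal inserts.

    A ``mismap_noise_rate`` fraction of pairs has its mate re-assigned a
    uniformly random chromosome, position and strand at ``mapq_noise``.
    """
    rng = _rng(cfg, rng)
    sd = cfg.seqdict
    names = sd.names()
    lengths = np.array([sd.length(c) for c in names], dtype=float)
    n_pairs = int(round(cfg.pairs_per_kb * lengths.sum() / 1000.0))
    margin = READ_LEN + 1

    chrom_idx = rng.choice(len(names), size=n_pairs, p=lengths / lengths.sum())
    u_pos = rng.random(n_pairs)
    inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
    inserts = np.maximum(inserts, 1.0).astype(int)
    is_noise = rng.random(n_pairs) < cfg.mismap_noise_rate
    noise_chrom = rng.choice(len(names), size=n_pairs)
    noise_u = rng.random(n_pairs)
    noise_strand = rng.random(n_pairs) < 0.5

    records: list[ReadPairRecord] = []
    for i in range(n_pairs):
        chrom = names[chrom_idx[i]]
        length = int(lengths[chrom_idx[i]])
        ins = int(inserts[i])
        span = max(length - ins - 2 * margin, 1)
        pos_a = margin + int(u_pos[i] * span)
        end_a = (chrom, pos_a, "+", cfg.mapq_true)
        if is_noise[i]:
            mchrom = names[noise_chrom[i]]
            mlen = sd.length(mchrom)
            mpos = margin + int(noise_u[i] * max(mlen - 2 * margin, 1))
            end_b = (mchrom, mpos, "-" if noise_strand[i] else "+", cfg.mapq_noise)
        else:
            end_b = (chrom, pos_a + ins, "-", cfg.mapq_true)
        records.append(
            ReadPairRecord.make(
                f"{name_prefix}{i:07d}", end_a, end_b, sd,
                read_group=read_group, sample_id=sample_id,
            )
        )
    return records


def simulate_sv_support(
    sv: PlantedSV,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    read_group: str = "rg0",
    sample_id: str = "sample",
    name_prefix: str = "sv",
) -> list[ReadPairRecord]:
    """Spanning pairs for one planted SV, jittered within one bin.

    deletion: FR pairs with distance = insert + size (in the discordant
    window for default sizes); inversion: same-strand pairs straddling the
    locus; translocation: pairs with one end at the locus and one at the
    partner breakpoint.
    """
    rng = _rng(cfg, rng)
    sd = cfg.seqdict
    if sv.chrom not in sd or not 0 <= sv.pos < sd.length(sv.chrom):
        raise ValueError(f"SV locus {sv.chrom}:{sv.pos} outside chromosome bounds")
    if sv.kind == "deletion" and sv.pos + sv.size >= sd.length(sv.chrom):
        raise ValueError("deletion extends past chromosome end")
    if sv.partner is not None:
        pc, pp = sv.partner
        if pc not in sd or not 0 <= pp < sd.length(pc):
            raise ValueError(f"partner locus {pc}:{pp} outside chromosome bounds")

    b = cfg.bin_size
    records = []
    for i in range(sv.n_support):
        jit = int(rng.integers(1, b))
        pos_a = max(sv.pos - jit, 0)
        hi = sd.length(sv.chrom) - READ_LEN - 1
        if sv.kind == "deletion":
            ins = max(int(rng.normal(cfg.insert_mean, cfg.insert_sd)), 1)
            end_a = (sv.chrom, pos_a, "+", cfg.mapq_true)
            end_b = (sv.chrom, min(pos_a + sv.size + ins, hi), "-", cfg.mapq_true)
        elif sv.kind == "inversion":
            jit2 = int(rng.integers(1, b))
            end_a = (sv.chrom, pos_a, "+", cfg.mapq_true)
            end_b = (sv.chrom, min(sv.pos + jit2, hi), "+", cfg.mapq_true)
        else:  # translocation
            pc, pp = sv.partner  # type: ignore[misc]
            jit2 = int(rng.integers(1, b))
            end_a = (sv.chrom, pos_a, "+", cfg.mapq_true)
            end_b = (pc, max(pp - jit2, 0), "-", cfg.mapq_true)
        records.append(
            ReadPairRecord.make(
                f"{name_prefix}{i:05d}", end_a, end_b, sd,
                read_group=read_group, sample_id=sample_id,
            )
        )
    return records


def truth_regions(
    sv: PlantedSV, cfg: SimulationConfig
) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
    """Breakpoint neighbourhoods for matching calls against the truth.

    Padded by one bin plus the insert spread, since supporting pairs land
    within that range of the exact breakpoints at bin resolution.
    """
    pad = int(cfg.bin_size + cfg.insert_mean + 4 * cfg.insert_sd)
    a = (sv.chrom, max(sv.pos - pad, 0), sv.pos + pad)
    if sv.kind == "deletion":
        bpt = (sv.chrom, sv.pos + sv.size)
    elif sv.kind == "inversion":
        bpt = (sv.chrom, sv.pos)
    else:
        bpt = sv.partner  # type: ignore[assignment]
    b = (bpt[0], max(bpt[1] - pad, 0), bpt[1] + pad)
    return a, b


def _regions_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def matches_truth(call, sv: PlantedSV, cfg: SimulationConfig) -> bool:
    """Does a call's region pair hit a planted SV's breakpoint neighbourhoods?

    Calls order their regions canonically, so both orientations are checked.
    """
    ta, tb = truth_regions(sv, cfg)
    return (
        _regions_overlap(call.regionA, ta) and _regions_overlap(call.regionB, tb)
    ) or (
        _regions_overlap(call.regionA, tb) and _regions_overlap(call.regionB, ta)
    )


def emit_alignment_file(
    records: Sequence[ReadPairRecord],
    seqdict: SequenceDict,
    path: str | Path,
    sample_id: str = "sample",
) -> None:
    """Write records as a coordinate-sorted, well-formed SAM file.

    Both mates are emitted per template with correct flags and mate fields;
    positions are converted back to SAM's 1-based convention by pysam.
    Reading the file back reconstructs the records exactly.
    """
    read_groups = sorted({r.read_group for r in records} or {"rg0"})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in seqdict.items()],
        "RG": [{"ID": rg, "SM": sample_id} for rg in read_groups],
    }
    segs: list[tuple[int, int, "pysam.AlignedSegment"]] = []

    def seg(rec: ReadPairRecord, first: bool) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment()
        chrom, pos, strand, mapq = (
            (rec.chromA, rec.posA, rec.strandA, rec.mapqA)
            if first
            else (rec.chromB, rec.posB, rec.strandB, rec.mapqB)
        )
        mchrom, mpos, mstrand = (
            (rec.chromB, rec.posB, rec.strandB)
            if first
            else (rec.chromA, rec.posA, rec.strandA)
        )
        a.query_name = rec.name
        a.reference_id = seqdict.rank(chrom)
        a.reference_start = pos
        a.mapping_quality = mapq
        a.query_sequence = "N" * READ_LEN
        a.cigar = [(0, READ_LEN)]
        a.next_reference_id = seqdict.rank(mchrom)
        a.next_reference_start = mpos
        flag = 0x1 | (0x40 if first else 0x80)
        if strand == "-":
            flag |= 0x10
        if mstrand == "-":
            flag |= 0x20
        a.flag = flag
        a.set_tag("RG", rec.read_group or "rg0")
        return a

    for rec in records:
        for first in (True, False):
            s = seg(rec, first)
            segs.append((s.reference_id, s.reference_start, s))
    segs.sort(key=lambda t: (t[0], t[1], t[2].query_name, t[2].flag))

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, _, s in segs:
            out.write(s)


def write_truth_bedpe(
    planted: Sequence[PlantedSV], cfg: SimulationConfig, path: str | Path
) -> None:
    """Truth file: one breakpoint-neighbourhood pair per planted SV."""
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tkind\tn_support\n")
        for sv in planted:
            ra, rb = truth_regions(sv, cfg)
            fh.write(
                f"{ra[0]}\t{ra[1]}\t{ra[2]}\t{rb[0]}\t{rb[1]}\t{rb[2]}\t"
                f"{sv.kind}\t{sv.n_support}\n"
            )


@dataclass
class MatchedScenario:
    """A matched tumor/blood pair from one patient plus the planted truth."""

    tumor: list[ReadPairRecord]
    blood: list[ReadPairRecord]
    truth: tuple[PlantedSV, ...]
    cfg_tumor: SimulationConfig
    cfg_blood: SimulationConfig
    patient_id: str = "patient0"

    @property
    def seqdict(self) -> SequenceDict:
        return self.cfg_tumor.seqdict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit tumor/blood SAM, truth BEDPE and a manifest; return the paths."""
        from .io import SampleManifest, write_manifest

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tumor": outdir / f"{self.patient_id}_tumor.sam",
            "blood": outdir / f"{self.patient_id}_blood.sam",
            "truth": outdir / f"{self.patient_id}_truth.bedpe",
            "manifest": outdir / "manifest.tsv",
        }
        emit_alignment_file(
            self.tumor, self.seqdict, paths["tumor"], sample_id=f"{self.patient_id}_tumor"
        )
        emit_alignment_file(
            self.blood, self.seqdict, paths["blood"], sample_id=f"{self.patient_id}_blood"
        )
        write_truth_bedpe(self.truth, self.cfg_tumor, paths["truth"])
        write_manifest(
            [
                SampleManifest(f"{self.patient_id}_tumor", str(paths["tumor"]),
                               "tumor", self.patient_id),
                SampleManifest(f"{self.patient_id}_blood", str(paths["blood"]),
                               "blood", self.patient_id),
            ],
            paths["manifest"],
        )
        return paths


def scenario_matched_pair(
    cfg_tumor: SimulationConfig,
    cfg_blood: SimulationConfig | None = None,
    patient_id: str = "patient0",
) -> MatchedScenario:
    """Simulate one patient: blood = background only, tumor = background + SVs.

    Both samples share the chromosome dictionary.  The blood config defaults
    to the tumor config with no planted events and an offset seed.
    """
    if cfg_blood is None:
        cfg_blood = replace(cfg_tumor, planted=(), seed=cfg_tumor.seed + 10_007)
    if cfg_blood.chrom_lengths != cfg_tumor.chrom_lengths:
        raise ValueError("matched samples must share the chromosome dictionary")

    rng_t = np.random.default_rng(cfg_tumor.seed)
    tumor = simulate_background(
        cfg_tumor, rng_t, sample_id=f"{patient_id}_tumor", name_prefix="bgT"
    )
    for k, sv in enumerate(cfg_tumor.planted):
        tumor.extend(
            simulate_sv_support(
                sv, cfg_tumor, rng_t,
                sample_id=f"{patient_id}_tumor", name_prefix=f"sv{k:02d}_",
            )
        )
    rng_b = np.random.default_rng(cfg_blood.seed)
    blood = simulate_background(
        cfg_blood, rng_b, sample_id=f"{patient_id}_blood", name_prefix="bgB"
    )
    return MatchedScenario(
        tumor=tumor, blood=blood, truth=tuple(cfg_tumor.planted),
        cfg_tumor=cfg_tumor, cfg_blood=cfg_blood, patient_id=patient_id,
    )
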