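"""SAM/BAM input, BEDPE output and tab-separated diagnostics.

All writers are deterministic given identical inputs: stable sorts, fixed
rounding.  Positions are converted from SAM's 1-based convention to the
package's 0-based half-open convention at this boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam
from scipy import stats

from .core import PairClass, ReadPairRecord, SequenceDict
from .detect import SVCall

__all__ = [
    "SampleManifest",
    "PairReader",
    "read_seqdict",
    "write_bedpe",
    "read_bedpe",
    "write_density_table",
    "density_on_grid",
    "read_manifest",
    "write_manifest",
]

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "class", "n_support", "support_fraction",
)


@dataclass(frozen=True)
class SampleManifest:
    """One sample in a cohort: id, alignment path, tissue label, patient."""

    sample_id: str
    path: str
    tissue: str = "unknown"  # tumor | blood | unknown
    patient_id: str = ""


def read_seqdict(path: str | Path) -> SequenceDict:
    with pysam.AlignmentFile(str(path), check_sq=True) as af:
        return SequenceDict(list(zip(af.references, af.lengths)))


class PairReader:
    """Stream ReadPairRecords from a coordinate-mapped SAM/BAM file.

    One record is yielded per template, built from the first-encountered
    primary alignment of each mate.  Unmapped, secondary, supplementary and
    duplicate-flagged records are skipped; every skip is tallied by reason
    in :attr:`skip_counts`.  Mates are joined by template name, with the
    mate-reference fields as a consistency check.
    """

    def __init__(self, path: str | Path, sample_id: str | None = None):
        self.path = str(path)
        try:
            self._af = pysam.AlignmentFile(self.path, check_sq=True)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read alignment file {self.path}: {exc}") from exc
        self.seqdict = SequenceDict(list(zip(self._af.references, self._af.lengths)))
        self.skip_counts: dict[str, int] = {}
        if sample_id is None:
            rgs = self._af.header.to_dict().get("RG", [])
            sample_id = rgs[0].get("SM", "") if rgs else ""
        self.sample_id = sample_id

    def _skip(self, reason: str) -> None:
        self.skip_counts[reason] = self.skip_counts.get(reason, 0) + 1

    def __iter__(self) -> Iterator[ReadPairRecord]:
        pending: dict[str, pysam.AlignedSegment] = {}
        for aln in self._af:
            if aln.is_unmapped:
                self._skip("unmapped")
                continue
            if aln.is_secondary:
                self._skip("secondary")
                continue
            if aln.is_supplementary:
                self._skip("supplementary")
                continue
            if aln.is_duplicate:
                self._skip("duplicate")
                continue
            if not aln.is_paired or aln.mate_is_unmapped:
                self._skip("mate_unmapped")
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            # consistency: each record's mate pointer must name the other
            if (
                mate.next_reference_name != aln.reference_name
                or mate.next_reference_start != aln.reference_start
                or aln.next_reference_name != mate.reference_name
                or aln.next_reference_start != mate.reference_start
            ):
                self._skip("mate_inconsistent")
                continue
            yield self._build(mate, aln)
        for _ in pending:
            self._skip("mate_missing")
        self._af.close()

    def _build(
        self, r1: pysam.AlignedSegment, r2: pysam.AlignedSegment
    ) -> ReadPairRecord:
        def end(r: pysam.AlignedSegment) -> tuple[str, int, str, int]:
            strand = "-" if r.is_reverse else "+"
            # pysam reference_start is already 0-based
            return (r.reference_name, r.reference_start, strand, r.mapping_quality)

        rg = ""
        if r1.has_tag("RG"):
            rg = str(r1.get_tag("RG"))
        elif r2.has_tag("RG"):
            rg = str(r2.get_tag("RG"))
        return ReadPairRecord.make(
            r1.query_name, end(r1), end(r2), self.seqdict,
            read_group=rg, sample_id=self.sample_id,
        )


def write_bedpe(calls: Sequence[SVCall], path: str | Path) -> None:
    """Write calls as BEDPE (0-based half-open), sorted and fixed-precision."""
    rows = sorted(
        calls, key=lambda c: (c.regionA[0], c.regionA[1], c.regionB[0], c.regionB[1])
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for i, c in enumerate(rows):
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.regionA[0], c.regionA[1], c.regionA[2],
                        c.regionB[0], c.regionB[1], c.regionB[2],
                        f"{c.sample_id or 'sv'}_{i + 1}",
                        f"{c.score:.4f}",
                        ".", ".",
                        c.sv_class.value,
                        c.n_support,
                        f"{c.support_fraction:.6f}",
                    )
                )
                + "\n"
            )


def read_bedpe(path: str | Path) -> list[SVCall]:
    """Read a BEDPE written by :func:`write_bedpe` back into SVCall objects."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            n_support = int(f[11])
            frac = float(f[12])
            cov = round(n_support / frac) if frac > 0 else 0
            calls.append(
                SVCall(
                    regionA=(f[0], int(f[1]), int(f[2])),
                    regionB=(f[3], int(f[4]), int(f[5])),
                    sv_class=PairClass(f[10]),
                    n_support=n_support,
                    local_coverage=cov,
                    support_fraction=frac,
                    score=float(f[7]),
                    sample_id=f[6].rsplit("_", 1)[0],
                )
            )
    return calls


def density_on_grid(
    distances: Sequence[int] | np.ndarray,
    max_d: float | None = None,
    grid_points: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density (Silverman bandwidth) of pair distances.

    The grid spans [0, max distance].  A zero-variance sample (all
    distances equal) degenerates to a point mass on the nearest grid point.
    """
    d = np.asarray(distances, dtype=float)
    if max_d is not None:
        d = d[d <= max_d]
    if d.size == 0:
        raise ValueError("no intrachromosomal pairs")
    hi = float(d.max())
    grid = np.linspace(0.0, hi if hi > 0 else 1.0, grid_points)
    if np.ptp(d) == 0.0:
        density = np.zeros_like(grid)
        j = int(np.argmin(np.abs(grid - d[0])))
        dx = grid[1] - grid[0]
        density[j] = 1.0 / dx
        return grid, density
    kde = stats.gaussian_kde(d, bw_method="silverman")
    return grid, kde(grid)


def write_density_table(
    distances: Sequence[int] | np.ndarray,
    path: str | Path,
    max_d: float | None = None,
    grid_points: int = 512,
) -> None:
    """Two-column TSV (distance, density) for external plotting."""
    grid, density = density_on_grid(distances, max_d=max_d, grid_points=grid_points)
    with open(path, "w") as fh:
        fh.write("distance\tdensity\n")
        for x, y in zip(grid, density):
            fh.write(f"{x:.6f}\t{y:.10g}\n")


def read_manifest(path: str | Path) -> list[SampleManifest]:
    out = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "sample_id":  # header
                continue
            if f[0] in seen:
                raise ValueError(f"duplicate sample_id {f[0]!r} in manifest")
            seen.add(f[0])
            out.append(
                SampleManifest(
                    sample_id=f[0],
                    path=f[1],
                    tissue=f[2] if len(f) > 2 else "unknown",
                    patient_id=f[3] if len(f) > 3 else "",
                )
            )
    return out


def write_manifest(samples: Sequence[SampleManifest], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpath\ttissue\tpatient_id\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.path}\t{s.tissue}\t{s.patient_id}\n")
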