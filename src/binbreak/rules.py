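"""Pair-classification rules.

Each mapped mate pair is assigned exactly one class.  Three discordant
signatures are recognised: mates on different chromosomes, unexpected
relative orientation, and an abnormal separation between mapped positions.
Separations in the (window_min, window_max] window (1000-7000 bp by
default) are the signal band used for calling; longer separations are
tallied but excluded from calling by default, since they are dominated by
noise and by germline variation relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TextIO

from .core import PairClass, ReadPairRecord

__all__ = ["RuleConfig", "classify_pair"]


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the pair-classification rules.

    ``normal_max_distance`` is the longest separation considered normal; it
    also sets the recommended bin size.  The discordant-distance window is
    half-open on the left: d = window_min is normal, d = window_max is in
    the window.  MAPQ 255 ("unavailable") is replaced by
    ``default_mapq_for_unavailable`` for scoring only, never classification.
    """

    normal_max_distance: int = 1000
    window_min: int = 1000
    window_max: int = 7000
    expected_orientation: str = "FR-inward"
    count_beyond_window: bool = False
    default_mapq_for_unavailable: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.normal_max_distance <= self.window_min < self.window_max):
            raise ValueError(
                "require 0 < normal_max_distance <= window_min < window_max, got "
                f"{self.normal_max_distance}, {self.window_min}, {self.window_max}"
            )
        if self.expected_orientation not in ("FR-inward", "RF-outward"):
            raise ValueError(f"unknown orientation {self.expected_orientation!r}")

    # -- config file -------------------------------------------------------

    _INT_KEYS = (
        "normal_max_distance",
        "window_min",
        "window_max",
        "default_mapq_for_unavailable",
    )

    @classmethod
    def from_file(cls, path: str | Path | TextIO) -> "RuleConfig":
        """Load from a key-value file (``key = value`` or ``key: value`` lines,
        ``#`` comments)."""
        if hasattr(path, "read"):
            text = path.read()
        else:
            text = Path(path).read_text()
        kwargs = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    break
            else:
                raise ValueError(f"cannot parse config line: {raw!r}")
            key, val = key.strip(), val.strip()
            if key in cls._INT_KEYS:
                kwargs[key] = int(val)
            elif key == "count_beyond_window":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key == "expected_orientation":
                kwargs[key] = val
            # unknown keys are ignored so one file can configure several tools
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "RuleConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def _orientation_expected(rec: ReadPairRecord, cfg: RuleConfig) -> bool:
    # End A is leftmost by construction; FR-inward means A forward, B reverse.
    if cfg.expected_orientation == "FR-inward":
        return rec.strandA == "+" and rec.strandB == "-"
    return rec.strandA == "-" and rec.strandB == "+"


def classify_pair(rec: ReadPairRecord, cfg: RuleConfig) -> PairClass:
    """Assign one class to a pair.

    Precedence: different chromosomes first (no meaningful 1-D distance),
    then orientation, then distance.  Distance d = posB - posA falls in
    WINDOW_DISTANCE when window_min < d <= window_max, BEYOND_WINDOW when
    d > window_max, otherwise NORMAL.
    """
    if rec.chromA != rec.chromB:
        return PairClass.INTERCHROM
    if not _orientation_expected(rec, cfg):
        return PairClass.ORIENTATION
    d = rec.posB - rec.posA
    if cfg.window_min < d <= cfg.window_max:
        return PairClass.WINDOW_DISTANCE
    if d > cfg.window_max:
        return PairClass.BEYOND_WINDOW
    return PairClass.NORMAL


def scoring_mapq(q: int, cfg: RuleConfig) -> int:
    """MAPQ as used for scoring: 255 means unavailable and gets the default."""
    return cfg.default_mapq_for_unavailable if q == 255 else q
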