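"""Peak containers and the BED6+3 peak dialect.

A peak is a contiguous interval of ChIP enrichment over input, with a
summit (the most enriched base), an amplitude (the maximum binned pileup
inside the interval — the height one sees in a genome browser), the Poisson
p-value at the summit and the browser score -10*log10(p).

Peaks serialize as BED6+3: the six standard columns (score column =
browser score rounded and capped at 1000, strand '.') plus three extra
columns summit, amplitude, and the full-precision score. The p-value is
recovered from the score on read (p = 10**(-score/10)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd

from .errors import DataError, FormatError

SCORE_CAP = 3100.0


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: str
    summit: int
    amplitude: float
    p_value: float
    score: float
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"peak {self.name}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise DataError(f"peak {self.name}: summit outside interval")

    def with_category(self, category: str) -> "Peak":
        return replace(self, category=category)


def score_from_p(p: float, cap: float = SCORE_CAP) -> float:
    """Browser score -10*log10(p), capped when p underflows."""
    if p <= 0.0:
        return cap
    return min(cap, -10.0 * math.log10(p))


class PeakSet:
    """An ordered collection of peaks from one sample."""

    def __init__(self, peaks: Iterable[Peak] = ()):  # keeps insertion order
        self._peaks: list[Peak] = list(peaks)

    def __len__(self) -> int:
        return len(self._peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks)

    def __getitem__(self, i: int) -> Peak:
        return self._peaks[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._peaks == other._peaks

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self._peaks:
            seen.setdefault(p.chrom, None)
        return list(seen)

    def on(self, chrom: str) -> list[Peak]:
        return [p for p in self._peaks if p.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(chrom=p.chrom, start=p.start, end=p.end, name=p.name,
                  summit=p.summit, amplitude=p.amplitude, p_value=p.p_value,
                  score=p.score, category=p.category)
             for p in self._peaks],
            columns=["chrom", "start", "end", "name", "summit", "amplitude",
                     "p_value", "score", "category"],
        )

    def category_fractions(self) -> dict[str, float]:
        if not self._peaks:
            return {}
        counts: dict[str, int] = {}
        for p in self._peaks:
            counts[p.category or "unclassified"] = counts.get(p.category or "unclassified", 0) + 1
        n = len(self._peaks)
        return {k: v / n for k, v in counts.items()}

    # -- BED6+3 -------------------------------------------------------------

    def to_bed(self) -> str:
        lines = []
        for p in self._peaks:
            bed_score = min(1000, int(round(p.score)))
            amp = repr(float(p.amplitude))
            sc = repr(float(p.score))
            lines.append(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{bed_score}"
                         f"\t.\t{p.summit}\t{amp}\t{sc}")
        return "\n".join(lines) + ("\n" if lines else "")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_bed())

    @classmethod
    def read_bed(cls, path) -> "PeakSet":
        peaks = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}:{ln}: expected 9 BED6+3 columns")
                try:
                    score = float(parts[8])
                    peaks.append(Peak(
                        chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                        name=parts[3], summit=int(parts[6]),
                        amplitude=float(parts[7]),
                        p_value=10.0 ** (-score / 10.0), score=score,
                    ))
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: malformed field: {exc}") from exc
        return cls(peaks)
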