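"""Fixed-step binned coverage tracks and the plain-text wiggle dialect.

A CoverageTrack holds, per chromosome, the read pileup binned at a fixed
step (the MACS ``--space`` parameter; 50 bp here by default) where the bin
value is the number of extended fragments overlapping the bin. Only the
fixed-step WIG dialect with step == span is supported; variable-step
records are rejected with the offending line number.

Serialization is bit-stable: ``read_wiggle(write_wiggle(t)) == t`` for
finite values, because values are written with ``repr`` (integral values as
integers).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

DEFAULT_STEP = 50
DEFAULT_TAG_SIZE = 49
DEFAULT_EXTENSION = 300


@dataclass
class CoverageTrack:
    """Per-chromosome binned pileup with library metadata.

    values: chrom -> 1-D float array of non-negative bin values. Bin i of
    chromosome c covers [i*step, (i+1)*step) (0-based); the WIG file
    declares the equivalent 1-based fixed-step records.
    """

    values: dict[str, np.ndarray]
    step: int = DEFAULT_STEP
    total_reads: int = 0
    tag_size: int = DEFAULT_TAG_SIZE
    extension: int = DEFAULT_EXTENSION
    starts: dict[str, int] = field(default_factory=dict)  # 0-based bin-0 offset

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if v.size and float(np.min(v)) < 0:
                raise FormatError(f"negative bin value on {c}")
        for c in self.values:
            self.starts.setdefault(c, 0)

    @property
    def span(self) -> int:
        """Fixed-step dialect: span equals step."""
        return self.step

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    def genome_mean(self) -> float:
        n = self.n_bins
        if n == 0:
            return 0.0
        return float(sum(v.sum() for v in self.values.values()) / n)

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            values={c: v * factor for c, v in self.values.items()},
            step=self.step, total_reads=self.total_reads,
            tag_size=self.tag_size, extension=self.extension,
            starts=dict(self.starts),
        )

    def __eq__(self, other) -> bool:  # empty chromosomes compare equal to absent
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if (self.step, self.total_reads, self.tag_size, self.extension) != (
                other.step, other.total_reads, other.tag_size, other.extension):
            return False
        chroms = set(self.values) | set(other.values)
        for c in chroms:
            a = self.values.get(c, np.empty(0))
            b = other.values.get(c, np.empty(0))
            if a.size != b.size or not np.array_equal(a, b):
                return False
            if a.size and self.starts.get(c, 0) != other.starts.get(c, 0):
                return False
        return True


def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v)


def write_wiggle(track: CoverageTrack, path) -> None:
    """Write a fixed-step WIG file (1-based starts, step == span).

    Chromosomes with no bins are omitted; library metadata travels in
    comment lines so a round trip restores it.
    """
    with open(path, "w") as fh:
        fh.write('track type=wiggle_0 name="h3k4diff"\n')
        fh.write(f"# total_reads={track.total_reads} tag_size={track.tag_size} "
                 f"extension={track.extension}\n")
        for chrom in track.chroms:
            vals = track.values[chrom]
            if vals.size == 0:
                continue
            start1 = track.starts.get(chrom, 0) + 1  # WIG is 1-based
            fh.write(f"fixedStep chrom={chrom} start={start1} "
                     f"step={track.step} span={track.step}\n")
            fh.write("\n".join(_fmt(v) for v in vals))
            fh.write("\n")


def read_wiggle(path) -> CoverageTrack:
    """Parse a fixed-step WIG file written by :func:`write_wiggle` (or MACS).

    Raises FormatError naming the line for variable-step records, negative
    values, or a span differing from the step.
    """
    values: dict[str, list[float]] = {}
    starts: dict[str, int] = {}
    meta = {"total_reads": 0, "tag_size": DEFAULT_TAG_SIZE,
            "extension": DEFAULT_EXTENSION}
    step = None
    current: list[float] | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("track") or line.startswith("browser"):
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        if k in meta:
                            meta[k] = int(v)
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"line {ln}: variableStep records are unsupported")
            if line.startswith("fixedStep"):
                fields = dict(tok.split("=", 1) for tok in line.split()[1:])
                try:
                    chrom = fields["chrom"]
                    this_step = int(fields["step"])
                    start1 = int(fields.get("start", 1))
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"line {ln}: malformed fixedStep header") from exc
                span = int(fields.get("span", this_step))
                if span != this_step:
                    raise FormatError(f"line {ln}: span != step is unsupported")
                if step is not None and this_step != step:
                    raise FormatError(f"line {ln}: mixed step sizes")
                step = this_step
                current = values.setdefault(chrom, [])
                starts[chrom] = start1 - 1
                continue
            if current is None:
                raise FormatError(f"line {ln}: data value before any fixedStep header")
            try:
                v = float(line)
            except ValueError as exc:
                raise FormatError(f"line {ln}: not a number: {line!r}") from exc
            if v < 0:
                raise FormatError(f"line {ln}: negative coverage value {v}")
            current.append(v)
    return CoverageTrack(
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
        step=step if step is not None else DEFAULT_STEP,
        total_reads=meta["total_reads"], tag_size=meta["tag_size"],
        extension=meta["extension"], starts=starts,
    )
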