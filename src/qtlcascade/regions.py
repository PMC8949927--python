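"""Genomic interval primitives shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

MBP = 1_000_000


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) in base pairs."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mbp(self) -> float:
        return self.length_bp / MBP

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps_span(self, start: int, end: int) -> bool:
        """Overlap with a closed 1-based span [start, end] (gene convention)."""
        return end >= self.start and start < self.end

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (bp, half-open)."""
        chrom, _, span = text.partition(":")
        if not _ or "-" not in span:
            raise ValueError(f"cannot parse interval {text!r}")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo.replace(",", "")), int(hi.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"
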