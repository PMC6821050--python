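"""Core domain types shared across the package.

All genomic coordinates are 0-based, half-open (BED convention). Any source
dialect that differs is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # start + floor(length / 2); integer midpoint used for distances
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Enhancer:
    """An enhancer call with a per-cell-type activity score.

    The activity score is the synthesized signal intensity from the enhancer
    annotation, used as a proxy for enhancer activity in each cell type.
    """

    id: str
    interval: GenomicInterval
    activity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, score in self.activity.items():
            if score < 0:
                raise ValueError(
                    f"enhancer {self.id}: negative activity {score} in {cell}"
                )


@dataclass
class Gene:
    """A gene with its TSS, strand, body interval and per-cell-type FPKM."""

    id: str
    chrom: str
    tss: int
    strand: str
    body: GenomicInterval
    promoter: GenomicInterval | None = None
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        for cell, fpkm in self.expression.items():
            if fpkm < 0:
                raise ValueError(f"gene {self.id}: negative FPKM {fpkm} in {cell}")


@dataclass(frozen=True)
class InteractionRecord:
    """One intra-chromosomal chromatin loop: two anchors in a given cell type.

    Loops come from ChIA-PET or Hi-C experiments (or the synthetic generator)
    and define the ground-truth labels for candidate enhancer-gene pairs.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    cell_type: str
    source: str = "ChIA-PET"

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                "inter-chromosomal interaction records are not supported: "
                f"{self.anchor1.chrom} vs {self.anchor2.chrom}"
            )
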