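"""Genomic intervals and coordinate conventions.

All internal coordinates are 0-based, half-open (BED convention).
Conversion to the 1-based inclusive GFF3 convention happens only at
serialization time (see :mod:`lincphylo.reports`).
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A strand-aware interval on one chromosome of one species' genome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start``
    always. Bounds against the actual chromosome length are checked when
    the interval is resolved against a :class:`~lincphylo.genome.Genome`.
    """

    species_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.species_id}:{self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Overlap in nt with another interval (0 if different chrom/species)."""
        if (self.species_id, self.chrom) != (other.species_id, other.chrom):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomeInterval") -> int | None:
        """Distance in nt between two non-overlapping intervals.

        Returns 0 for overlapping/abutting intervals, ``None`` if the
        intervals are on different chromosomes or species.
        """
        if (self.species_id, self.chrom) != (other.species_id, other.chrom):
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def key(self) -> tuple[str, str, int, int]:
        return (self.species_id, self.chrom, self.start, self.end)
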