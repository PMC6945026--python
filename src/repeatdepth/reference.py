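"""Reference genome model for tandem-repeat copy-number estimation.

A :class:`ReferenceModel` bundles what every estimator needs to know about
the reference assembly: the sequences themselves (optional — counting only
needs lengths), the total genome length ``G``, the collapsed repeat locus
(most assemblies carry a single unit of a tandem array), the length of one
repeat unit ``L_r``, and a panel of single-copy control regions used to
audit coverage inflation.

Coordinates are normalized internally to 0-based half-open. Constructors
accept 1-based inclusive coordinates (the convention of genome browsers and
of most published locus descriptions) via ``GenomicRegion.from_one_based``.
BED input/output is 0-based half-open as the format requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicRegion",
    "ReferenceModel",
    "read_bed",
    "write_bed",
    "celegans_reference",
    "cerevisiae_unit_length",
]

#: Length of the unmasked C. elegans WS235 assembly (bp).
CELEGANS_GENOME_LENGTH = 100_286_070
#: Single 45S rDNA repeat unit length in C. elegans (bp).
CELEGANS_RDNA_UNIT = 7_197
#: rDNA counting interval on WS235 ChrI, 1-based inclusive (spans the array
#: locus including the flanking partial units rrn-3.56 and rrn-1.2).
CELEGANS_RDNA_SPAN = ("ChrI", 15_060_299, 15_071_033)
#: Single rDNA repeat unit length in S. cerevisiae (bp).
CEREVISIAE_RDNA_UNIT = 9_100


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open interval ``[start, end)`` on a named sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid region {self.name}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @classmethod
    def from_one_based(cls, name: str, start: int, end: int) -> "GenomicRegion":
        """Build from 1-based inclusive coordinates (the convention of genome browsers and printed locus tables)."""
        return cls(name, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.name == other.name
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReferenceModel:
    """Reference description consumed by all read-depth estimators.

    Parameters
    ----------
    genome_length
        Total assembly length ``G`` (bp), the numerator scale of the
        relative-read formula.
    repeat_region
        The interval over which repeat-mapping reads are counted. May be
        longer than one unit (e.g. the worm locus spans 10,735 bp around a
        7,197 bp unit); the counting span and the unit length are
        independent parameters by design.
    repeat_unit_length
        Length of a single repeat unit ``L_r`` (bp), the denominator scale.
    control_regions
        Disjoint single-copy regions for the coverage-inflation audit.
    sequences
        Optional name -> sequence mapping. Required only by operations that
        read bases (GC-profile fitting); pure counting works without it.
    """

    genome_length: int
    repeat_region: GenomicRegion
    repeat_unit_length: int
    control_regions: list[GenomicRegion] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.repeat_unit_length <= 0:
            raise ValueError("repeat_unit_length must be positive")
        for region in [self.repeat_region, *self.control_regions]:
            if self.sequences and region.name not in self.sequences:
                raise ValueError(f"region on unknown sequence {region.name!r}")
            if self.sequences and region.end > len(self.sequences[region.name]):
                raise ValueError(
                    f"region {region.name}:{region.start}-{region.end} "
                    "extends past the end of its sequence"
                )
        for region in self.control_regions:
            if region.overlaps(self.repeat_region):
                raise ValueError(
                    f"control region {region.name}:{region.start}-{region.end} "
                    "overlaps the repeat region"
                )

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        repeat_region: GenomicRegion,
        repeat_unit_length: int,
        control_regions: Sequence[GenomicRegion] = (),
        genome_length: int | None = None,
    ) -> "ReferenceModel":
        sequences = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        if not sequences:
            raise ValueError(f"no sequences in {fasta_path}")
        if genome_length is None:
            genome_length = sum(len(s) for s in sequences.values())
        return cls(
            genome_length=genome_length,
            repeat_region=repeat_region,
            repeat_unit_length=repeat_unit_length,
            control_regions=list(control_regions),
            sequences=sequences,
        )

    def write_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    def gc_fraction(self, region: GenomicRegion) -> float:
        """Observed G+C fraction of the bases in ``region``."""
        seq = self.sequences[region.name][region.start : region.end]
        if not seq:
            return 0.0
        gc = sum(seq.count(b) for b in "GCgc")
        return gc / len(seq)


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read regions from a BED file (0-based half-open, first 3 columns)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append(GenomicRegion(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\n")


def celegans_reference() -> ReferenceModel:
    """Counting constants of the C. elegans (WS235) rDNA workflow.

    Sequence-free: suitable for relative-read estimation from alignment
    counts, where only lengths and coordinates enter the formula.
    """
    name, start, end = CELEGANS_RDNA_SPAN
    return ReferenceModel(
        genome_length=CELEGANS_GENOME_LENGTH,
        repeat_region=GenomicRegion.from_one_based(name, start, end),
        repeat_unit_length=CELEGANS_RDNA_UNIT,
    )


def cerevisiae_unit_length() -> int:
    """Single rDNA repeat unit length in S. cerevisiae (bp)."""
    return CEREVISIAE_RDNA_UNIT
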