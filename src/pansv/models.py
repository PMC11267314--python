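"""Core domain types shared across the pipeline.

All coordinates are 1-based inclusive internally; conversion to on-disk
conventions (BED 0-based half-open, VCF/GFF3 1-based) happens only at
serialization boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

GROUPS = ("RF", "YF", "GF")
SV_TYPES = ("INS", "DEL", "INV", "TRA")

#: SV types that describe a presence/absence allele and enter the
#: non-redundant catalog and the variation graph.
PAV_TYPES = ("INS", "DEL")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class HaplotypeAssembly:
    """One haplotype-resolved assembly of an accession."""

    haplotype_id: str
    accession: str
    group: str
    chrom_lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for {self.haplotype_id}; "
                f"expected one of {GROUPS}"
            )
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValidationError(f"non-positive length for {chrom}")


@dataclass
class Cohort:
    """Registry of haplotype assemblies with accession/group lookups."""

    assemblies: Sequence[HaplotypeAssembly]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        acc_group: dict[str, str] = {}
        for asm in self.assemblies:
            if asm.haplotype_id in seen:
                raise ValidationError(f"duplicate haplotype id {asm.haplotype_id}")
            seen.add(asm.haplotype_id)
            prev = acc_group.setdefault(asm.accession, asm.group)
            if prev != asm.group:
                raise ValidationError(
                    f"accession {asm.accession} assigned to both {prev} and {asm.group}"
                )
        self._by_hap = {asm.haplotype_id: asm for asm in self.assemblies}

    # -- lookups ---------------------------------------------------------
    @property
    def haplotype_ids(self) -> list[str]:
        return [asm.haplotype_id for asm in self.assemblies]

    @property
    def accessions(self) -> list[str]:
        out: list[str] = []
        for asm in self.assemblies:
            if asm.accession not in out:
                out.append(asm.accession)
        return out

    def accession_of(self, haplotype_id: str) -> str:
        return self._by_hap[haplotype_id].accession

    def group_of_haplotype(self, haplotype_id: str) -> str:
        return self._by_hap[haplotype_id].group

    def group_of_accession(self, accession: str) -> str:
        for asm in self.assemblies:
            if asm.accession == accession:
                return asm.group
        raise KeyError(accession)

    def haplotypes_of_accession(self, accession: str) -> list[str]:
        out = [a.haplotype_id for a in self.assemblies if a.accession == accession]
        if not out:
            raise KeyError(accession)
        return out

    def haplotypes_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return [a.haplotype_id for a in self.assemblies if a.group == group]

    def __contains__(self, haplotype_id: str) -> bool:
        return haplotype_id in self._by_hap

    def __len__(self) -> int:
        return len(self.assemblies)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene model with exon structure.

    ``exons`` are 1-based inclusive, sorted and pairwise disjoint intervals
    within ``[start, end]``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValidationError(f"{self.gene_id}: bad span {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene without exons")
        prev_end = self.start - 1
        for (s, e) in self.exons:
            if s > e or s <= prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons not sorted/disjoint at {s}-{e}"
                )
            prev_end = e
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise ValidationError(f"{self.gene_id}: exon outside gene span")

    def promoter_interval(self, length: int) -> tuple[int, int]:
        """Strand-aware window immediately upstream of the annotated start."""
        if self.strand == "+":
            return (max(1, self.start - length), self.start - 1)
        return (self.end + 1, self.end + length)

    def downstream_interval(self, length: int) -> tuple[int, int]:
        if self.strand == "+":
            return (self.end + 1, self.end + length)
        return (max(1, self.start - length), self.start - 1)


@dataclass(frozen=True)
class SVRecord:
    """A single per-haplotype structural-variant call (VCF POS convention).

    For DEL/INV the affected interval is ``[pos, pos + length - 1]``; an INS
    is anchored after ``pos``. TRA records carry no interval semantics beyond
    POS.
    """

    chrom: str
    pos: int
    svtype: str
    length: int
    source_haplotype: str
    alt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown svtype {self.svtype!r}")
        if self.pos < 1:
            raise ValidationError(f"POS must be >= 1, got {self.pos}")
        if self.length < 1:
            raise ValidationError(f"length must be >= 1, got {self.length}")

    def interval(self) -> tuple[int, int]:
        """Affected reference interval; a point for INS/TRA."""
        if self.svtype in ("DEL", "INV"):
            return (self.pos, self.pos + self.length - 1)
        return (self.pos, self.pos)


def check_chroms(records: Iterable[SVRecord], chrom_lengths: Mapping[str, int]) -> None:
    """Validate that every record sits on a known chromosome and, for
    DEL/INV, within its bounds."""
    for rec in records:
        if rec.chrom not in chrom_lengths:
            raise ValidationError(
                f"record at {rec.chrom}:{rec.pos} ({rec.svtype}) on unknown chromosome"
            )
        if rec.svtype in ("DEL", "INV"):
            if rec.pos + rec.length - 1 > chrom_lengths[rec.chrom]:
                raise ValidationError(
                    f"{rec.svtype} at {rec.chrom}:{rec.pos} extends past chromosome end"
                )
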