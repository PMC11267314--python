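"""Merging of per-haplotype SV calls into a non-redundant catalog.

Only presence/absence alleles (INS/DEL) are merged; inversions and
translocations are cataloged per accession without merging. Clustering is a
deterministic greedy left-to-right single pass over records sorted by
(chrom, svtype, pos): a record joins the currently open cluster iff its
position is within ``max_distance`` of the cluster representative and its
length within ``max_size_difference`` (both absolute bp, start-to-start),
otherwise it opens a new cluster. The representative is always the leftmost
member and is never re-centered, which makes merging idempotent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import Cohort, SVRecord, ValidationError, PAV_TYPES, SV_TYPES


@dataclass
class NonRedundantSV:
    """A merged SV locus with its member calls and carrier haplotypes."""

    id: str
    chrom: str
    pos: int
    svtype: str
    length: int
    members: list[SVRecord] = field(default_factory=list)
    alt_seq: str | None = None
    _carriers: frozenset[str] | None = None

    @property
    def carriers(self) -> frozenset[str]:
        if self._carriers is not None:
            return self._carriers
        return frozenset(m.source_haplotype for m in self.members)

    def carrier_accessions(self, cohort: Cohort) -> frozenset[str]:
        return frozenset(cohort.accession_of(h) for h in self.carriers)

    def interval(self) -> tuple[int, int]:
        if self.svtype in ("DEL", "INV"):
            return (self.pos, self.pos + self.length - 1)
        return (self.pos, self.pos)


def merge_svs(
    records: Iterable[SVRecord],
    max_distance: int = 50,
    max_size_difference: int = 20,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[NonRedundantSV]:
    """Cluster INS/DEL records into a non-redundant catalog.

    The output is sorted by (chrom, pos) and is invariant to the input
    record order. Raises :class:`ValidationError` for non-PAV record types
    or records on chromosomes absent from ``chrom_lengths`` (when given).
    """
    recs = list(records)
    for rec in recs:
        if rec.svtype not in PAV_TYPES:
            raise ValidationError(
                f"merge_svs only accepts {PAV_TYPES}, got {rec.svtype} "
                f"at {rec.chrom}:{rec.pos}"
            )
        if chrom_lengths is not None and rec.chrom not in chrom_lengths:
            raise ValidationError(
                f"record at {rec.chrom}:{rec.pos} on unknown chromosome {rec.chrom}"
            )
    recs.sort(key=lambda r: (r.chrom, r.svtype, r.pos, r.length, r.source_haplotype))

    clusters: list[list[SVRecord]] = []
    open_key: tuple[str, str] | None = None
    for rec in recs:
        key = (rec.chrom, rec.svtype)
        if clusters and key == open_key:
            rep = clusters[-1][0]
            if (
                abs(rec.pos - rep.pos) <= max_distance
                and abs(rec.length - rep.length) <= max_size_difference
            ):
                clusters[-1].append(rec)
                continue
        clusters.append([rec])
        open_key = key

    clusters.sort(key=lambda c: (c[0].chrom, c[0].pos, c[0].svtype))
    out: list[NonRedundantSV] = []
    for i, members in enumerate(clusters):
        rep = members[0]
        out.append(
            NonRedundantSV(
                id=f"nrsv{i + 1:06d}",
                chrom=rep.chrom,
                pos=rep.pos,
                svtype=rep.svtype,
                length=rep.length,
                members=members,
                alt_seq=rep.alt_seq,
            )
        )
    return out


def frequency_spectrum(
    catalog: Sequence[NonRedundantSV], cohort: Cohort
) -> dict[int, int]:
    """Counts of catalog entries carried by exactly ``a`` accessions.

    Both haplotypes of an accession collapse to a single carrier; the
    spectrum sums to the catalog size.
    """
    n_acc = len(cohort.accessions)
    spectrum = {a: 0 for a in range(1, n_acc + 1)}
    for sv in catalog:
        a = len(sv.carrier_accessions(cohort))
        if a == 0:
            raise ValidationError(f"catalog entry {sv.id} has no carriers")
        spectrum[a] += 1
    return spectrum


def per_accession_counts(
    records: Iterable[SVRecord], cohort: Cohort
) -> pd.DataFrame:
    """Pre-merge call counts per accession and SV type."""
    table = pd.DataFrame(
        0, index=pd.Index(cohort.accessions, name="accession"), columns=list(SV_TYPES)
    )
    for rec in records:
        acc = cohort.accession_of(rec.source_haplotype)
        table.loc[acc, rec.svtype] += 1
    return table
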