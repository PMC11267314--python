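"""Readers and writers for the standard formats the pipeline touches.

VCF and GFF3 are read through pysam/gffutils; writing uses minimal plain-text
emitters restricted to the fields the pipeline produces. Internal coordinates
are 1-based inclusive; BED is converted to 0-based half-open on disk.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Cohort, GeneModel, HaplotypeAssembly, SVRecord, ValidationError
from .svcatalog import NonRedundantSV

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    """Raised for a structurally malformed VCF body line."""


# ---------------------------------------------------------------------------
# cohort labels / chromosome lengths
# ---------------------------------------------------------------------------

def read_labels(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> Cohort:
    """Read a haplotype_id / accession / group TSV into a :class:`Cohort`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"haplotype_id", "accession", "group"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"labels file {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    assemblies = [
        HaplotypeAssembly(row.haplotype_id, row.accession, row.group)
        for row in df.itertuples()
    ]
    return Cohort(assemblies, dict(chrom_lengths or {}))


def write_labels(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype_id\taccession\tgroup\n")
        for asm in cohort.assemblies:
            fh.write(f"{asm.haplotype_id}\t{asm.accession}\t{asm.group}\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#", dtype={"chrom": str, "length": int})
    return dict(zip(df.chrom, df.length))


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

@dataclass
class SVReadResult:
    """Records plus a skip log from one VCF."""

    records: list[SVRecord] = field(default_factory=list)
    n_short_skipped: int = 0
    record_errors: list[str] = field(default_factory=list)


def _prescan_vcf(path: str | Path) -> None:
    """Cheap structural validation so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(parts)}"
                )
            if not parts[1].isdigit():
                raise VcfParseError(
                    f"{path}: line {lineno}: POS is not an integer: {parts[1]!r}"
                )


def _info_int(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0]
    return int(value)


def read_sv_vcf(
    path: str | Path, haplotype_id: str, min_len: int = 50
) -> SVReadResult:
    """Read one per-haplotype SV VCF (symbolic or explicit alleles).

    INS/DEL records shorter than ``min_len`` are dropped and counted in
    ``n_short_skipped``. Records whose SVTYPE is missing and not inferable
    are logged in ``record_errors`` and skipped; the file continues.
    """
    _prescan_vcf(path)
    result = SVReadResult()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                parsed = _parse_variant(rec, haplotype_id)
            except ValueError as exc:
                msg = f"{path}:{rec.chrom}:{rec.pos}: {exc}"
                logger.warning(msg)
                result.record_errors.append(msg)
                continue
            if parsed is None:
                continue
            if parsed.svtype in ("INS", "DEL") and parsed.length < min_len:
                result.n_short_skipped += 1
                continue
            result.records.append(parsed)
    if result.n_short_skipped:
        logger.info(
            "%s: dropped %d INS/DEL records shorter than %d bp",
            path, result.n_short_skipped, min_len,
        )
    return result


def _parse_variant(rec, haplotype_id: str) -> SVRecord | None:
    if not rec.alts:
        raise ValueError("record without ALT allele")
    alt = rec.alts[0]
    info = dict(rec.info)
    if alt.startswith("<"):
        svtype = info.get("SVTYPE") or alt.strip("<>")
        if svtype not in ("DEL", "INS", "INV", "TRA"):
            raise ValueError(f"SVTYPE missing or unrecognized: {svtype!r}")
        svlen = _info_int(info.get("SVLEN"))
        end = _info_int(info.get("END")) or rec.stop
        if svlen is not None:
            length = abs(svlen)
        elif end is not None and svtype in ("DEL", "INV"):
            length = end - rec.pos + 1
        elif svtype == "TRA":
            length = 1
        else:
            raise ValueError(f"cannot determine length of symbolic {svtype}")
        if svtype == "TRA":
            length = max(length, 1)
        alt_seq = info.get("SEQ") if svtype == "INS" else None
        return SVRecord(rec.chrom, rec.pos, svtype, length, haplotype_id, alt_seq)
    # explicit REF/ALT alleles
    ref = rec.ref or ""
    if len(alt) == len(ref):
        raise ValueError("explicit alleles of equal length are not an SV")
    if len(alt) > len(ref):
        if not alt.startswith(ref):
            raise ValueError("explicit INS allele where REF is not a prefix of ALT")
        return SVRecord(
            rec.chrom, rec.pos + len(ref) - 1, "INS",
            len(alt) - len(ref), haplotype_id, alt[len(ref):],
        )
    if not ref.startswith(alt):
        raise ValueError("explicit DEL allele where ALT is not a prefix of REF")
    # first deleted base is POS + len(ALT)
    return SVRecord(
        rec.chrom, rec.pos + len(alt), "DEL", len(ref) - len(alt), haplotype_id
    )


_VCF_INFO_HEADER = (
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n'
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="Last affected reference base">\n'
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">\n'
    '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Carrier haplotypes">\n'
    '##INFO=<ID=NMEMBERS,Number=1,Type=Integer,Description="Merged member calls">\n'
)


def _vcf_header(chrom_lengths: Mapping[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=pansv"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    return "\n".join(lines) + "\n" + _VCF_INFO_HEADER + \
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    ref_seqs: Mapping[str, str] | None = None,
) -> None:
    """Write per-haplotype SV calls as VCF 4.2.

    INS records are written as explicit REF/ALT alleles when ``ref_seqs`` is
    provided (and the record carries ``alt_seq``), otherwise symbolically
    with the inserted sequence in INFO/SEQ. DEL/INV/TRA are symbolic.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.svtype))
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths))
        for i, rec in enumerate(recs):
            fh.write(_format_record(rec, f"sv{i + 1:06d}", ref_seqs) + "\n")


def _format_record(
    rec: SVRecord, rec_id: str, ref_seqs: Mapping[str, str] | None
) -> str:
    if rec.svtype == "INS" and rec.alt_seq and ref_seqs is not None:
        base = ref_seqs[rec.chrom][rec.pos - 1]
        return (
            f"{rec.chrom}\t{rec.pos}\t{rec_id}\t{base}\t{base}{rec.alt_seq}"
            f"\t.\t.\tSVTYPE=INS;SVLEN={rec.length}"
        )
    if rec.svtype == "INS":
        info = f"SVTYPE=INS;SVLEN={rec.length}"
        if rec.alt_seq:
            info += f";SEQ={rec.alt_seq}"
        return f"{rec.chrom}\t{rec.pos}\t{rec_id}\tN\t<INS>\t.\t.\t{info}"
    svlen = -rec.length if rec.svtype == "DEL" else rec.length
    end = rec.pos + rec.length - 1 if rec.svtype in ("DEL", "INV") else rec.pos
    return (
        f"{rec.chrom}\t{rec.pos}\t{rec_id}\tN\t<{rec.svtype}>\t.\t.\t"
        f"SVTYPE={rec.svtype};SVLEN={svlen};END={end}"
    )


def write_merged_vcf(
    catalog: Sequence[NonRedundantSV],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write the non-redundant catalog with CARRIERS/NMEMBERS INFO fields."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(chrom_lengths))
        for sv in catalog:
            svlen = -sv.length if sv.svtype == "DEL" else sv.length
            end = sv.pos + sv.length - 1 if sv.svtype in ("DEL", "INV") else sv.pos
            info = (
                f"SVTYPE={sv.svtype};SVLEN={svlen};END={end};"
                f"CARRIERS={','.join(sorted(sv.carriers))};"
                f"NMEMBERS={len(sv.members) or 1}"
            )
            if sv.svtype == "INS" and sv.alt_seq:
                info += f";SEQ={sv.alt_seq}"
            fh.write(f"{sv.chrom}\t{sv.pos}\t{sv.id}\tN\t<{sv.svtype}>\t.\t.\t{info}\n")


def read_merged_vcf(path: str | Path) -> list[NonRedundantSV]:
    """Read a catalog written by :func:`write_merged_vcf`."""
    _prescan_vcf(path)
    out: list[NonRedundantSV] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            svtype = info.get("SVTYPE")
            if svtype is None:
                raise VcfParseError(f"{path}: {rec.chrom}:{rec.pos} lacks SVTYPE")
            length = abs(_info_int(info.get("SVLEN")) or 1)
            carriers = info.get("CARRIERS", ())
            if isinstance(carriers, str):
                carriers = (carriers,)
            out.append(
                NonRedundantSV(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    svtype=svtype,
                    length=length,
                    alt_seq=info.get("SEQ"),
                    _carriers=frozenset(carriers),
                )
            )
    return out


# ---------------------------------------------------------------------------
# orthogroup tables
# ---------------------------------------------------------------------------

def read_orthogroups(
    path: str | Path, cohort: Cohort | None = None
) -> dict[str, dict[str, list[str]]]:
    """Parse an orthogroup cluster table (tab-separated, one haplotype per
    column, comma-separated gene ids in cells).

    Every gene id must appear in exactly one cluster; when ``cohort`` is
    given, the header haplotypes are cross-checked against it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ValidationError(f"orthogroup table {path} has no haplotype columns")
    haps = list(df.columns[1:])
    if cohort is not None:
        unknown = [h for h in haps if h not in cohort]
        if unknown:
            raise ValidationError(
                f"orthogroup table header haplotypes not in cohort labels: {unknown}"
            )
    out: dict[str, dict[str, list[str]]] = {}
    seen: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cluster = row[0]
        entry: dict[str, list[str]] = {}
        for hap, cell in zip(haps, row[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()]
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"gene id {g!r} appears in clusters {seen[g]} and {cluster}"
                    )
                seen[g] = cluster
            entry[hap] = genes
        if cluster in out:
            raise ValidationError(f"duplicate cluster id {cluster}")
        out[cluster] = entry
    return out


def write_orthogroups(
    orthogroups: Mapping[str, Mapping[str, Sequence[str]]],
    path: str | Path,
    haplotypes: Sequence[str],
) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(haplotypes) + "\n")
        for cluster, entry in orthogroups.items():
            cells = [", ".join(entry.get(h, [])) for h in haplotypes]
            fh.write(cluster + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            (c.start, c.end)
            for c in db.children(g, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(g.id, g.seqid, g.start, g.end, g.strand, exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tpansv\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tpansv\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Iterable[tuple], path: str | Path, header: str = "chrom\tstart\tend\tname"
) -> None:
    """Write 1-based inclusive internal intervals as 0-based half-open BED.

    Each interval is ``(chrom, start, end)`` or ``(chrom, start, end, name)``.
    """
    with open(path, "w") as fh:
        fh.write("#" + header + "\n")
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            rest = "\t" + "\t".join(str(x) for x in iv[3:]) if len(iv) > 3 else ""
            fh.write(f"{chrom}\t{start - 1}\t{end}{rest}\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED back into 1-based inclusive tuples."""
    out: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]), *parts[3:]))
    return out


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix: genes as rows, samples as columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
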