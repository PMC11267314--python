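"""Genomic-context classification of SVs and group/expression intersections.

Context labels form a partition with priority
``exonic > intronic > promoter > downstream > intergenic``; the promoter is
the strand-aware window immediately upstream of the annotated gene start
(2 kb by default), the downstream window mirrors it on the other side.
Overlap means at least 1 bp of intersection with the SV's reference
interval (a point for INS).
"""
from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import Cohort, GeneModel, ValidationError
from .svcatalog import NonRedundantSV

logger = logging.getLogger(__name__)

CONTEXTS = ("exonic", "intronic", "promoter", "downstream", "intergenic")
_PRIORITY = {c: i for i, c in enumerate(CONTEXTS)}


@dataclass(frozen=True)
class SVContext:
    sv_id: str
    context: str
    linked_gene: str | None
    distance_to_gene: int


@dataclass(frozen=True)
class GroupSpecificSV:
    sv_id: str
    focal_group: str
    mode: str  # presence_specific | absence_specific
    carriers: frozenset[str]


class GeneIndex:
    """Per-chromosome gene lookup with flank-aware candidate scans."""

    def __init__(self, genes: Sequence[GeneModel], flank: int = 2000) -> None:
        self.flank = flank
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_span: dict[str, int] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            self._starts[chrom] = [g.start for g in gs]
            self._max_span[chrom] = max(g.end - g.start + 1 for g in gs)

    def candidates(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose flank-extended footprint may overlap [start, end]."""
        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        starts = self._starts[chrom]
        reach = self._max_span[chrom] + self.flank
        lo = bisect.bisect_left(starts, start - reach)
        hi = bisect.bisect_right(starts, end + self.flank)
        return gs[lo:hi]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for gs in self._by_chrom.values() for g in gs}


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _gene_relation(
    iv: tuple[int, int], gene: GeneModel, promoter_len: int, downstream_len: int
) -> str | None:
    if _overlaps(iv, (gene.start, gene.end)):
        for exon in gene.exons:
            if _overlaps(iv, exon):
                return "exonic"
        return "intronic"
    if _overlaps(iv, gene.promoter_interval(promoter_len)):
        return "promoter"
    if _overlaps(iv, gene.downstream_interval(downstream_len)):
        return "downstream"
    return None


def _body_distance(iv: tuple[int, int], gene: GeneModel) -> int:
    if _overlaps(iv, (gene.start, gene.end)):
        return 0
    if iv[1] < gene.start:
        return gene.start - iv[1]
    return iv[0] - gene.end


def classify_context(
    sv,
    index: GeneIndex,
    promoter_len: int = 2000,
    downstream_len: int = 2000,
) -> SVContext:
    """Classify one SV-like object (needs chrom/pos/svtype/length, optional id).

    Ties between genes at equal priority are broken by distance to the gene
    body, then by gene start, keeping the result deterministic.
    """
    sv_id = getattr(sv, "id", None) or f"{sv.chrom}:{sv.pos}:{sv.svtype}"
    iv = sv.interval() if hasattr(sv, "interval") else (sv.pos, sv.pos)
    best: tuple[int, int, int, str, str] | None = None
    for gene in index.candidates(sv.chrom, iv[0], iv[1]):
        rel = _gene_relation(iv, gene, promoter_len, downstream_len)
        if rel is None:
            continue
        key = (_PRIORITY[rel], _body_distance(iv, gene), gene.start, gene.gene_id, rel)
        if best is None or key[:4] < best[:4]:
            best = key
    if best is not None:
        return SVContext(sv_id, best[4], best[3], best[1])
    genes = index.genes_on(sv.chrom)
    if not genes:
        return SVContext(sv_id, "intergenic", None, 0)
    nearest = min(genes, key=lambda g: (_body_distance(iv, g), g.start, g.gene_id))
    return SVContext(sv_id, "intergenic", nearest.gene_id, _body_distance(iv, nearest))


def classify_contexts(
    svs: Iterable,
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
    downstream_len: int = 2000,
) -> list[SVContext]:
    index = GeneIndex(genes, flank=max(promoter_len, downstream_len))
    return [classify_context(sv, index, promoter_len, downstream_len) for sv in svs]


def context_fractions(contexts: Sequence[SVContext]) -> pd.DataFrame:
    """Five-way context fractions plus a collapsed three-way view that folds
    promoter/downstream into intergenic."""
    n = len(contexts)
    counts = {c: 0 for c in CONTEXTS}
    for ctx in contexts:
        counts[ctx.context] += 1
    five = {c: counts[c] / n if n else 0.0 for c in CONTEXTS}
    three = {
        "exonic": five["exonic"],
        "intronic": five["intronic"],
        "intergenic_incl_flanks": five["promoter"] + five["downstream"] + five["intergenic"],
    }
    rows = [("five_way", k, v) for k, v in five.items()]
    rows += [("three_way", k, v) for k, v in three.items()]
    return pd.DataFrame(rows, columns=["view", "context", "fraction"])


# ---------------------------------------------------------------------------
# differential-expression surrogate (synthetic data only)
# ---------------------------------------------------------------------------

def naive_de(
    expression: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Naive per-gene DE surrogate: Welch t-test on log2(x+1) plus a fold
    change threshold.

    This is a deliberately simple stand-in used for synthetic cohorts only;
    it is NOT equivalent to a negative-binomial DE model. ``status`` is
    'up' when expression is higher in ``samples_b``.
    """
    a = np.log2(expression[list(samples_a)].to_numpy(dtype=float) + 1.0)
    b = np.log2(expression[list(samples_b)].to_numpy(dtype=float) + 1.0)
    log2fc = np.log2(
        (expression[list(samples_b)].mean(axis=1) + 0.5)
        / (expression[list(samples_a)].mean(axis=1) + 0.5)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    status = np.full(len(expression), "ns", dtype=object)
    sig = (np.abs(log2fc) > min_abs_log2fc) & (pvals < max_p)
    status[sig & (log2fc > 0)] = "up"
    status[sig & (log2fc < 0)] = "down"
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "status": status}, index=expression.index
    )


# ---------------------------------------------------------------------------
# promoter-SV / expression intersection
# ---------------------------------------------------------------------------

@dataclass
class PromoterDEResult:
    n_genes: int
    frac_up: float
    frac_down: float
    frac_ns: float
    genes: dict[str, str]  # gene -> status
    empty: bool


def promoter_de_overlap(
    catalog: Sequence[NonRedundantSV],
    contexts: Sequence[SVContext],
    accession_pair: tuple[str, str],
    de_status: Mapping[str, str],
    cohort: Cohort,
) -> PromoterDEResult:
    """Fractions of promoter-SV genes that are up / down / not DE between
    two accessions.

    Only SVs polymorphic between the pair qualify: carried by at least one
    haplotype of exactly one of the two accessions (any-haplotype dominant
    coding).
    """
    for acc in accession_pair:
        if acc not in cohort.accessions:
            raise ValidationError(f"accession {acc!r} not in cohort")
    haps_a = set(cohort.haplotypes_of_accession(accession_pair[0]))
    haps_b = set(cohort.haplotypes_of_accession(accession_pair[1]))
    ctx_by_id = {c.sv_id: c for c in contexts}
    genes: dict[str, str] = {}
    for sv in catalog:
        ctx = ctx_by_id.get(sv.id)
        if ctx is None or ctx.context != "promoter" or ctx.linked_gene is None:
            continue
        in_a = bool(sv.carriers & haps_a)
        in_b = bool(sv.carriers & haps_b)
        if in_a == in_b:
            continue
        gene = ctx.linked_gene
        genes[gene] = de_status.get(gene, "ns")
    n = len(genes)
    if n == 0:
        return PromoterDEResult(0, 0.0, 0.0, 0.0, {}, empty=True)
    ups = sum(1 for s in genes.values() if s == "up")
    downs = sum(1 for s in genes.values() if s == "down")
    return PromoterDEResult(
        n_genes=n,
        frac_up=ups / n,
        frac_down=downs / n,
        frac_ns=(n - ups - downs) / n,
        genes=genes,
        empty=False,
    )


# ---------------------------------------------------------------------------
# group-specific SVs
# ---------------------------------------------------------------------------

def group_specific_svs(
    catalog: Sequence[NonRedundantSV], cohort: Cohort, focal_group: str
) -> list[GroupSpecificSV]:
    """SVs whose carriers (presence mode) or non-carriers (absence mode) are
    a non-empty subset of the focal group's haplotypes.

    An SV carried by some-but-not-all focal haplotypes and zero non-focal
    haplotypes qualifies as presence-specific.
    """
    focal = set(cohort.haplotypes_in_group(focal_group))
    if not focal:
        raise ValidationError(f"group {focal_group!r} has no haplotypes")
    all_haps = set(cohort.haplotype_ids)
    out: list[GroupSpecificSV] = []
    for sv in catalog:
        carriers = set(sv.carriers)
        unknown = carriers - all_haps
        if unknown:
            raise ValidationError(f"{sv.id}: carriers not in cohort: {sorted(unknown)}")
        if carriers and carriers <= focal:
            out.append(
                GroupSpecificSV(sv.id, focal_group, "presence_specific",
                                frozenset(carriers))
            )
        non_carriers = all_haps - carriers
        if non_carriers and non_carriers <= focal:
            out.append(
                GroupSpecificSV(sv.id, focal_group, "absence_specific",
                                frozenset(carriers))
            )
    return out


# ---------------------------------------------------------------------------
# pathway associations
# ---------------------------------------------------------------------------

def pathway_sv_association(
    catalog: Sequence[NonRedundantSV],
    contexts: Sequence[SVContext],
    pathway_genes: Sequence[str],
    known_gene_ids: set[str] | None = None,
) -> pd.DataFrame:
    """SVs whose linked gene belongs to a pathway gene list, with their
    context (intergenic-nearest links included).

    Pathway ids absent from the gene models are warned about and skipped.
    """
    wanted = []
    for gid in pathway_genes:
        if known_gene_ids is not None and gid not in known_gene_ids:
            logger.warning("pathway gene %s absent from gene models; skipped", gid)
            continue
        wanted.append(gid)
    wanted_set = set(wanted)
    ctx_by_id = {c.sv_id: c for c in contexts}
    rows = []
    for sv in catalog:
        ctx = ctx_by_id.get(sv.id)
        if ctx is None or ctx.linked_gene not in wanted_set:
            continue
        rows.append(
            {
                "sv_id": sv.id,
                "chrom": sv.chrom,
                "pos": sv.pos,
                "svtype": sv.svtype,
                "gene": ctx.linked_gene,
                "context": ctx.context,
                "distance_to_gene": ctx.distance_to_gene,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sv_id", "chrom", "pos", "svtype", "gene", "context",
                 "distance_to_gene"],
    )
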