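"""Synthetic cohort generator.

Produces a fully specified on-disk bundle (reference FASTA, per-haplotype
GFF3 and CDS FASTA, orthogroup table, per-haplotype SV VCFs, expression
matrix, group labels, truth table) whose statistical structure matches what
the downstream analyses assume: planted cluster-category proportions, SV
hotspots, one group-exclusive promoter deletion coupled to an expression
effect, and category effects on CDS length and expression.

Everything is driven by a single seeded generator, so the same seed yields
a byte-identical bundle.
"""
from __future__ import annotations

import bisect
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .models import Cohort, GeneModel, HaplotypeAssembly, SVRecord, ValidationError

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP_CODONS = sorted(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
)

# gene layout constants: slot pitch leaves an intergenic gap large enough
# for an unambiguous promoter placement of the planted deletion
_SLOT_PITCH = 2500
_GENE_LEN = 1200
_CHROM_MARGIN = 5000
_EXONS_REL = ((0, 499), (700, 1199))  # relative to gene start
_PLANTED_PROMOTER_OFFSET = 151  # planted DEL covers [start-151, start-101]


@dataclass
class PlantedSVSpec:
    svtype: str = "DEL"
    length: int = 51
    #: carrier haplotypes; None picks hap2 of the first GF accession and
    #: hap1 of the second (when present)
    carriers: tuple[str, ...] | None = None


@dataclass
class ExpressionSpec:
    dispersion: float = 0.1
    mean_log_mu: float = float(np.log(50.0))
    mean_log_sigma: float = 1.0
    core_mean_multiplier: float = 2.0
    planted_fold_change: float = 6.0
    n_replicates: int = 3
    stages: tuple[str, str] = ("early", "late")


@dataclass
class CohortSpec:
    """Parameter bundle for :func:`generate_cohort`."""

    n_accessions: int = 7
    haplotypes_per_accession: int = 2
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"RF": 2, "YF": 3, "GF": 2}
    )
    n_chroms: int = 3
    chrom_len: int = 2_000_000
    n_clusters: int = 2000
    category_proportions: tuple[float, float, float, float] = (0.466, 0.126, 0.407, 0.001)
    softcore_fraction: float = 0.80
    #: average SV calls per non-reference haplotype
    n_svs_per_haplotype: int = 100
    n_hotspots: int = 2
    hotspot_sv_multiplier: float = 8.0
    #: planted hotspot region size and alignment grid; match the scan
    #: window/step used downstream so the planted region fills whole windows
    hotspot_window: int = 400_000
    hotspot_step: int = 200_000
    planted_sv: PlantedSVSpec = field(default_factory=PlantedSVSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    #: probability that a present cluster has a second gene copy in a
    #: haplotype (only clusters that own a duplicate slot)
    dup_copy_prob: float = 0.10
    dup_slot_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValidationError("category_proportions must sum to 1")
        positives = (
            self.n_accessions, self.haplotypes_per_accession, self.n_chroms,
            self.chrom_len, self.n_clusters, self.n_svs_per_haplotype,
        )
        if any(x <= 0 for x in positives):
            raise ValidationError("all cohort counts must be positive")
        if sum(self.group_sizes.values()) != self.n_accessions:
            raise ValidationError("group_sizes must sum to n_accessions")
        if self.n_hotspots < 0 or self.hotspot_sv_multiplier < 1:
            raise ValidationError("bad hotspot parameters")
        if self.n_hotspots > 0 and self.chrom_len < self.hotspot_window + 2 * self.hotspot_step:
            raise ValidationError(
                "chrom_len too small for the hotspot window; shrink "
                "hotspot_window/hotspot_step or set n_hotspots=0"
            )

    # -- derived naming ---------------------------------------------------
    @property
    def accession_names(self) -> list[str]:
        out = []
        for group in ("RF", "YF", "GF"):
            for i in range(self.group_sizes.get(group, 0)):
                out.append(f"{group}{i + 1}")
        return out

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def cohort(self) -> Cohort:
        assemblies = []
        lengths = {c: self.chrom_len for c in self.chrom_names}
        for acc in self.accession_names:
            group = acc[:2]
            for j in range(self.haplotypes_per_accession):
                assemblies.append(
                    HaplotypeAssembly(f"{acc}.hap{j + 1}", acc, group, lengths)
                )
        return Cohort(assemblies, dict(lengths))

    @property
    def reference_haplotype(self) -> str:
        return f"{self.accession_names[0]}.hap1"

    @property
    def contrast_pair(self) -> tuple[str, str]:
        """Reference accession versus first green-fleshed accession."""
        gf = [a for a in self.accession_names if a.startswith("GF")]
        if not gf:
            raise ValidationError("cohort has no GF accessions")
        return (self.accession_names[0], gf[0])


@dataclass
class CohortBundle:
    """Paths of everything :func:`generate_cohort` wrote."""

    root: Path
    ref_fasta: Path
    gff3_dir: Path
    cds_dir: Path
    vcf_dir: Path
    orthogroups: Path
    expression: Path
    labels: Path
    chrom_lengths: Path
    pathway_genes: Path
    truth: Path
    spec: CohortSpec

    def gff3_for(self, haplotype_id: str) -> Path:
        return self.gff3_dir / f"{haplotype_id}.gff3"

    def cds_for(self, haplotype_id: str) -> Path:
        return self.cds_dir / f"{haplotype_id}.fa"

    def vcf_for(self, haplotype_id: str) -> Path:
        return self.vcf_dir / f"{haplotype_id}.vcf"


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def largest_remainder_counts(proportions: Sequence[float], total: int) -> list[int]:
    """Deterministic integer apportionment of ``total`` by proportions."""
    raw = [p * total for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class _Locus:
    id: str
    chrom: str
    pos: int
    svtype: str
    length: int
    carriers: tuple[str, ...]
    alt_seq: str | None = None
    planted: bool = False


def _presence_sets(
    rng: np.random.Generator, spec: CohortSpec, haps: list[str]
) -> tuple[list[str], dict[str, list[str]], dict[str, str]]:
    """Cluster ids, presence sets and truth categories, planted exactly."""
    n = len(haps)
    n_core, n_soft, n_shell, n_cloud = largest_remainder_counts(
        spec.category_proportions, spec.n_clusters
    )
    soft_min = int(np.floor(spec.softcore_fraction * n)) + 1
    while soft_min / n <= spec.softcore_fraction:
        soft_min += 1
    if soft_min > n - 1 and n_soft > 0:
        raise ValidationError("no presence count satisfies the softcore band")
    shell_max = soft_min - 1
    if shell_max < 2 and n_shell > 0:
        raise ValidationError("no presence count satisfies the shell band")

    categories = (
        ["core"] * n_core + ["softcore"] * n_soft
        + ["shell"] * n_shell + ["cloud"] * n_cloud
    )
    rng.shuffle(categories)
    clusters = [f"OG{i + 1:07d}" for i in range(spec.n_clusters)]
    presence: dict[str, list[str]] = {}
    truth_cat: dict[str, str] = {}
    for cluster, cat in zip(clusters, categories):
        if cat == "core":
            chosen = list(haps)
        elif cat == "cloud":
            chosen = [haps[int(rng.integers(n))]]
        else:
            if cat == "softcore":
                k = int(rng.integers(soft_min, n))  # soft_min .. n-1
            else:
                k = int(rng.integers(2, shell_max + 1))  # 2 .. shell_max
            idx = rng.choice(n, size=k, replace=False)
            chosen = [haps[i] for i in sorted(idx)]
        presence[cluster] = chosen
        truth_cat[cluster] = cat
    return clusters, presence, truth_cat


def _draw_carriers(
    rng: np.random.Generator, cohort: Cohort, reference_hap: str
) -> tuple[str, ...]:
    """Carrier haplotypes for one SV locus; skewed toward single accessions."""
    accessions = cohort.accessions
    max_a = min(6, len(accessions))
    weights = np.array([0.50, 0.20, 0.12, 0.08, 0.06, 0.04][:max_a])
    weights /= weights.sum()
    while True:
        a = int(rng.choice(np.arange(1, max_a + 1), p=weights))
        accs = rng.choice(len(accessions), size=a, replace=False)
        carriers: list[str] = []
        for ai in sorted(accs):
            haps = cohort.haplotypes_of_accession(accessions[ai])
            if rng.random() < 0.4:
                chosen = haps
            else:
                chosen = [haps[int(rng.integers(len(haps)))]]
            carriers.extend(h for h in chosen if h != reference_hap)
        if carriers:
            return tuple(carriers)


class _SeparationIndex:
    """Sorted interval lists used to keep SV loci well separated so that
    merging, hotspot counting and graph construction stay unambiguous."""

    def __init__(self, pad: int = 100) -> None:
        self.pad = pad
        self._starts: dict[str, list[int]] = {}
        self._ivs: dict[str, list[tuple[int, int]]] = {}

    def fits(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._ivs.get(chrom, [])
        starts = self._starts.get(chrom, [])
        i = bisect.bisect_left(starts, start)
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if start - self.pad <= e and s <= end + self.pad:
                    return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ivs = self._ivs.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ivs.insert(i, (start, end))


def _weighted_position(
    rng: np.random.Generator,
    spec: CohortSpec,
    hotspots: list[tuple[str, int, int]],
    max_len: int,
) -> tuple[str, int]:
    """Draw (chrom, pos) with hotspot windows receiving multiplier-weighted
    mass."""
    usable = spec.chrom_len - 2 * _CHROM_MARGIN - max_len
    chrom_w = []
    for chrom in spec.chrom_names:
        hot = sum(e - s + 1 for c, s, e in hotspots if c == chrom)
        chrom_w.append(usable + hot * (spec.hotspot_sv_multiplier - 1.0))
    chrom_w = np.array(chrom_w, dtype=float)
    chrom = spec.chrom_names[int(rng.choice(len(chrom_w), p=chrom_w / chrom_w.sum()))]
    regions = [(s, e) for c, s, e in hotspots if c == chrom]
    weights = [float(usable)] + [
        (e - s + 1) * spec.hotspot_sv_multiplier for s, e in regions
    ]
    w = np.array(weights) / sum(weights)
    pick = int(rng.choice(len(weights), p=w))
    if pick == 0:
        pos = int(rng.integers(_CHROM_MARGIN + 1, spec.chrom_len - _CHROM_MARGIN - max_len))
    else:
        s, e = regions[pick - 1]
        pos = int(rng.integers(s, e + 1))
    return chrom, pos


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, outdir: str | Path) -> CohortBundle:
    """Write the full synthetic bundle under ``outdir`` and return its paths."""
    rng = np.random.default_rng(spec.seed)
    root = Path(outdir)
    gff3_dir = root / "genes"
    cds_dir = root / "cds"
    vcf_dir = root / "svs"
    for d in (root, gff3_dir, cds_dir, vcf_dir):
        d.mkdir(parents=True, exist_ok=True)

    cohort = spec.cohort()
    haps = cohort.haplotype_ids
    ref_hap = spec.reference_haplotype
    chrom_names = spec.chrom_names
    truth_rows: list[tuple[str, str, str]] = []

    # 1. reference sequences ------------------------------------------------
    ref_seqs = {c: _random_seq(rng, spec.chrom_len) for c in chrom_names}

    # 2. gene slots ----------------------------------------------------------
    slots: list[tuple[str, int]] = []  # (chrom, gene start)
    for chrom in chrom_names:
        start = _CHROM_MARGIN + 1
        while start + _GENE_LEN - 1 <= spec.chrom_len - _CHROM_MARGIN:
            slots.append((chrom, start))
            start += _SLOT_PITCH
    n_dup_slots = min(
        int(spec.dup_slot_fraction * spec.n_clusters), len(slots) - spec.n_clusters
    )
    if n_dup_slots < 0:
        raise ValidationError(
            f"{spec.n_clusters} clusters do not fit into {len(slots)} gene slots; "
            "increase chrom_len or n_chroms"
        )
    slot_order = rng.permutation(len(slots))
    primary_slot = {  # cluster index -> slot index
        ci: int(slot_order[ci]) for ci in range(spec.n_clusters)
    }
    dup_slot: dict[int, int] = {}
    if n_dup_slots:
        dup_clusters = rng.choice(spec.n_clusters, size=n_dup_slots, replace=False)
        for k, ci in enumerate(sorted(dup_clusters)):
            dup_slot[ci] = int(slot_order[spec.n_clusters + k])

    # 3. cluster presence ----------------------------------------------------
    clusters, presence, truth_cat = _presence_sets(rng, spec, haps)
    strands = rng.choice(np.array(["+", "-"]), size=spec.n_clusters)
    dup_present: dict[tuple[int, str], bool] = {}
    for ci, cluster in enumerate(clusters):
        if ci not in dup_slot:
            continue
        for hap in presence[cluster]:
            dup_present[(ci, hap)] = bool(rng.random() < spec.dup_copy_prob)

    # 4. choose the planted promoter-effect gene cluster: a core cluster whose
    # left-neighbor slot is also a primary gene slot, so the promoter
    # placement is unambiguous
    slot_to_cluster = {s: ci for ci, s in primary_slot.items()}
    dup_slot_to_cluster = {s: ci for ci, s in dup_slot.items()}
    ordered_slots = sorted(range(len(slots)), key=lambda i: slots[i])
    prev_slot_of = {}
    for a, b in zip(ordered_slots, ordered_slots[1:]):
        if slots[a][0] == slots[b][0]:
            prev_slot_of[b] = a
    candidates = [
        ci for ci, cluster in enumerate(clusters)
        if truth_cat[cluster] == "core" and primary_slot[ci] in prev_slot_of
    ]
    if not candidates:
        raise ValidationError("could not place the planted promoter SV")
    planted_ci = int(rng.choice(np.array(sorted(candidates))))
    # force strands so the planted deletion lies unambiguously in the
    # planted gene's promoter: the gene itself on +, and whichever cluster
    # owns the left-neighbor slot (if any) on + as well
    strands[planted_ci] = "+"
    prev = prev_slot_of[primary_slot[planted_ci]]
    if prev in slot_to_cluster:
        strands[slot_to_cluster[prev]] = "+"
    elif prev in dup_slot_to_cluster:
        strands[dup_slot_to_cluster[prev]] = "+"
    planted_cluster = clusters[planted_ci]
    planted_chrom, planted_gene_start = slots[primary_slot[planted_ci]]

    # 5. hotspot regions (window-grid aligned, distinct chromosomes) --------
    window, step = spec.hotspot_window, spec.hotspot_step
    hotspot_regions: list[tuple[str, int, int]] = []
    hot_chroms = rng.choice(
        len(chrom_names), size=min(spec.n_hotspots, len(chrom_names)), replace=False
    )
    for i, ci in enumerate(sorted(hot_chroms)):
        chrom = chrom_names[ci]
        max_k = (spec.chrom_len - window) // step
        k = int(rng.integers(1, max(2, max_k)))
        start = 1 + k * step
        hotspot_regions.append((chrom, start, start + window - 1))
        truth_rows.append(("hotspot", f"hs{i + 1}", f"{chrom}:{start}-{start + window - 1}"))

    # 6. SV loci -------------------------------------------------------------
    sep = _SeparationIndex(pad=100)
    loci: list[_Locus] = []

    planted = spec.planted_sv
    planted_pos = planted_gene_start - _PLANTED_PROMOTER_OFFSET
    if planted.svtype != "DEL":
        raise ValidationError("planted promoter SV must be a deletion")
    gf_haps = set(cohort.haplotypes_in_group("GF"))
    if planted.carriers is None:
        gf_accs = [a for a in cohort.accessions if cohort.group_of_accession(a) == "GF"]
        carriers = [cohort.haplotypes_of_accession(gf_accs[0])[-1]]
        if len(gf_accs) > 1:
            carriers.append(cohort.haplotypes_of_accession(gf_accs[1])[0])
        planted_carriers = tuple(carriers)
    else:
        planted_carriers = tuple(planted.carriers)
    if not set(planted_carriers) <= gf_haps:
        raise ValidationError("planted SV carriers must be GF haplotypes")
    planted_locus = _Locus(
        id="", chrom=planted_chrom, pos=planted_pos, svtype="DEL",
        length=planted.length, carriers=planted_carriers, planted=True,
    )
    sep.add(planted_chrom, planted_pos, planted_pos + planted.length - 1)
    loci.append(planted_locus)

    target_records = spec.n_svs_per_haplotype * (len(haps) - 1)
    total_records = len(planted_carriers)
    svtype_p = np.array([0.45, 0.45, 0.06, 0.04])
    svtypes = np.array(["DEL", "INS", "INV", "TRA"])
    max_len = 2000
    attempts = 0
    while total_records < target_records:
        attempts += 1
        if attempts > 100 * target_records:
            raise ValidationError("could not place SV loci; genome too dense")
        svtype = str(rng.choice(svtypes, p=svtype_p))
        length = min(max_len, int(50 + rng.exponential(150.0)))
        chrom, pos = _weighted_position(rng, spec, hotspot_regions, max_len)
        end = pos + length - 1 if svtype in ("DEL", "INV") else pos
        if not sep.fits(chrom, pos, end):
            continue
        carriers = _draw_carriers(rng, cohort, ref_hap)
        alt_seq = _random_seq(rng, length) if svtype == "INS" else None
        sep.add(chrom, pos, end)
        loci.append(
            _Locus("", chrom, pos, svtype, length, carriers, alt_seq)
        )
        total_records += len(carriers)

    loci.sort(key=lambda l: (l.chrom, l.pos))
    for i, locus in enumerate(loci):
        locus.id = f"sv{i + 1:05d}"
    planted_id = next(l.id for l in loci if l.planted)

    for locus in loci:
        label = (
            f"{locus.svtype}|{locus.chrom}:{locus.pos}|len={locus.length}"
            f"|carriers={','.join(sorted(locus.carriers))}"
        )
        truth_rows.append(("sv", locus.id, label))
    truth_rows.append((
        "planted_promoter_sv", planted_id,
        f"DEL|{planted_chrom}:{planted_pos}|len={planted.length}"
        f"|carriers={','.join(sorted(planted_carriers))}",
    ))

    # 7. per-haplotype SV VCFs (jittered within the merge tolerance) --------
    per_hap_records: dict[str, list[SVRecord]] = {h: [] for h in haps if h != ref_hap}
    for locus in loci:
        for hap in locus.carriers:
            if locus.planted:
                dpos, dlen = 0, 0
            else:
                dpos = int(rng.integers(-20, 21))
                dlen = 0 if locus.svtype != "DEL" else int(rng.integers(-5, 6))
                dlen = max(dlen, 50 - locus.length)
            per_hap_records[hap].append(
                SVRecord(
                    locus.chrom, locus.pos + dpos, locus.svtype,
                    locus.length + dlen, hap, locus.alt_seq,
                )
            )
    chrom_lengths = {c: spec.chrom_len for c in chrom_names}
    for hap, records in per_hap_records.items():
        pio.write_sv_vcf(records, vcf_dir / f"{hap}.vcf", chrom_lengths, ref_seqs)
        truth_rows.append(("hap_sv_count", hap, str(len(records))))
        for svtype in ("DEL", "INS", "INV", "TRA"):
            n = sum(1 for r in records if r.svtype == svtype)
            truth_rows.append(("hap_svtype_count", f"{hap}:{svtype}", str(n)))

    # 8. gene models, orthogroups, CDS --------------------------------------
    orthogroups: dict[str, dict[str, list[str]]] = {c: {} for c in clusters}
    ancestral_cds: dict[int, str] = {}
    for ci, cluster in enumerate(clusters):
        if truth_cat[cluster] == "core":
            n_codons = int(rng.integers(150, 400))
        else:
            n_codons = int(rng.integers(80, 250))
        codons = rng.choice(np.array(_NONSTOP_CODONS), size=n_codons)
        ancestral_cds[ci] = "".join(codons)

    gene_of: dict[tuple[int, str, int], str] = {}
    for hap in haps:
        genes: list[GeneModel] = []
        cds_seqs: dict[str, str] = {}
        for ci, cluster in enumerate(clusters):
            if hap not in presence[cluster]:
                continue
            copies = [primary_slot[ci]]
            if dup_present.get((ci, hap)):
                copies.append(dup_slot[ci])
            for copy_no, slot in enumerate(copies, start=1):
                chrom, start = slots[slot]
                gene_id = f"{hap}.{cluster}.g{copy_no}"
                exons = tuple(
                    (start + s, start + e) for s, e in _EXONS_REL
                )
                genes.append(
                    GeneModel(gene_id, chrom, start, start + _GENE_LEN - 1,
                              str(strands[ci]), exons)
                )
                orthogroups[cluster].setdefault(hap, []).append(gene_id)
                cds_seqs[gene_id] = _mutate_cds(rng, ancestral_cds[ci], rate=0.02)
                gene_of[(ci, hap, copy_no)] = gene_id
        pio.write_gff3(genes, gff3_dir / f"{hap}.gff3")
        pio.write_fasta(cds_seqs, cds_dir / f"{hap}.fa")

    pio.write_orthogroups(orthogroups, root / "orthogroups.tsv", haps)
    for cluster in clusters:
        truth_rows.append(("cluster", cluster, truth_cat[cluster]))

    planted_ref_gene = gene_of[(planted_ci, ref_hap, 1)]
    truth_rows.append(("planted_gene", planted_ref_gene, "up_in_focal_late"))
    truth_rows.append(("planted_cluster", planted_cluster, truth_cat[planted_cluster]))

    # 9. pathway gene list ---------------------------------------------------
    ref_genes = sorted(
        gid for (ci, hap, copy), gid in gene_of.items() if hap == ref_hap
    )
    others = [g for g in ref_genes if g != planted_ref_gene]
    n_extra = min(20, len(others))
    extra = [others[i] for i in sorted(rng.choice(len(others), size=n_extra, replace=False))]
    pathway = sorted([planted_ref_gene] + extra)
    with open(root / "pathway_genes.txt", "w") as fh:
        fh.write("\n".join(pathway) + "\n")

    # 10. expression ---------------------------------------------------------
    acc_a, acc_b = spec.contrast_pair
    truth_rows.append(("contrast_pair", "accessions", f"{acc_a},{acc_b}"))
    ex = spec.expression
    columns = []
    for acc in (acc_a, acc_b):
        for stage in ex.stages:
            for rep in range(1, ex.n_replicates + 1):
                columns.append(f"{acc}_{stage}_rep{rep}")
    cluster_of_gene = {}
    for (ci, hap, copy), gid in gene_of.items():
        if hap == ref_hap:
            cluster_of_gene[gid] = ci
    base_mean = {}
    for gid in ref_genes:
        ci = cluster_of_gene[gid]
        mean = float(rng.lognormal(ex.mean_log_mu, ex.mean_log_sigma))
        if truth_cat[clusters[ci]] == "core":
            mean *= ex.core_mean_multiplier
        base_mean[gid] = mean
    base_mean[planted_ref_gene] = 100.0
    matrix = np.zeros((len(ref_genes), len(columns)))
    for gi, gid in enumerate(ref_genes):
        for si, col in enumerate(columns):
            acc, stage, _rep = col.rsplit("_", 2)
            mean = base_mean[gid]
            if (
                gid == planted_ref_gene
                and stage == ex.stages[-1]
                and acc == acc_b
            ):
                mean *= ex.planted_fold_change
            n_param = 1.0 / ex.dispersion
            p_param = n_param / (n_param + mean)
            matrix[gi, si] = rng.negative_binomial(n_param, p_param)
    expr = pd.DataFrame(matrix, index=pd.Index(ref_genes, name="gene"),
                        columns=columns)
    expr.to_csv(root / "expression.tsv", sep="\t")

    # 11. labels, lengths, reference FASTA, truth ---------------------------
    pio.write_labels(cohort, root / "labels.tsv")
    pio.write_chrom_lengths(chrom_lengths, root / "chrom_lengths.tsv")
    pio.write_fasta(ref_seqs, root / "reference.fa")
    truth = pd.DataFrame(truth_rows, columns=["entity_type", "id", "planted_label"])
    truth.to_csv(root / "truth.tsv", sep="\t", index=False)

    return CohortBundle(
        root=root,
        ref_fasta=root / "reference.fa",
        gff3_dir=gff3_dir,
        cds_dir=cds_dir,
        vcf_dir=vcf_dir,
        orthogroups=root / "orthogroups.tsv",
        expression=root / "expression.tsv",
        labels=root / "labels.tsv",
        chrom_lengths=root / "chrom_lengths.tsv",
        pathway_genes=root / "pathway_genes.txt",
        truth=root / "truth.tsv",
        spec=spec,
    )


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Substitute bases at ``rate``, skipping any substitution that would
    create a stop codon."""
    n_mut = rng.binomial(len(cds), rate)
    if n_mut == 0:
        return cds
    positions = sorted(int(p) for p in rng.choice(len(cds), size=n_mut, replace=False))
    seq = list(cds)
    for pos in positions:
        base = "ACGT"[int(rng.integers(4))]
        if base == seq[pos]:
            continue
        old = seq[pos]
        seq[pos] = base
        codon_start = (pos // 3) * 3
        codon = "".join(seq[codon_start : codon_start + 3])
        if codon in ("TAA", "TAG", "TGA"):
            seq[pos] = old
    return "".join(seq)
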