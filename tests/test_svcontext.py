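import numpy as np
import pandas as pd
import pytest

import pansv.io as pio
from pansv.models import Cohort, GeneModel, HaplotypeAssembly, SVRecord, ValidationError
from pansv.svcontext import (
    CONTEXTS,
    GeneIndex,
    classify_context,
    classify_contexts,
    context_fractions,
    group_specific_svs,
    naive_de,
    pathway_sv_association,
    promoter_de_overlap,
)
from pansv.svcatalog import NonRedundantSV

from conftest import find_catalog_entry, make_rec, planted_sv_truth

PRIORITY = {c: i for i, c in enumerate(CONTEXTS)}


def gene(gene_id, start, end, strand="+", exons=None, chrom="chr1"):
    return GeneModel(gene_id, chrom, start, end, strand, tuple(exons or [(start, end)]))


def oracle_context(sv, genes, promoter_len=2000, downstream_len=2000):
    """Interval-algebra oracle: test the SV interval against every exon,
    intron and flank interval of every gene explicitly."""
    s, e = sv.interval()
    best = None
    for g in genes:
        if g.chrom != sv.chrom:
            continue
        label = None
        if any(xs <= e and s <= xe for xs, xe in g.exons):
            label = "exonic"
        else:
            introns = [
                (a[1] + 1, b[0] - 1) for a, b in zip(g.exons, g.exons[1:]) if a[1] + 1 <= b[0] - 1
            ]
            if any(xs <= e and s <= xe for xs, xe in introns):
                label = "intronic"
            else:
                ps, pe = g.promoter_interval(promoter_len)
                ds, de = g.downstream_interval(downstream_len)
                if ps <= e and s <= pe:
                    label = "promoter"
                elif ds <= e and s <= de:
                    label = "downstream"
        if label is None:
            continue
        dist = 0 if (g.start <= e and s <= g.end) else (
            g.start - e if e < g.start else s - g.end
        )
        key = (PRIORITY[label], dist, g.start, g.gene_id, label)
        if best is None or key[:4] < best[:4]:
            best = key
    if best:
        return best[4], best[3]
    on_chrom = [g for g in genes if g.chrom == sv.chrom]
    if not on_chrom:
        return "intergenic", None
    def dist(g):
        return 0 if (g.start <= e and s <= g.end) else (g.start - e if e < g.start else s - g.end)
    nearest = min(on_chrom, key=lambda g: (dist(g), g.start, g.gene_id))
    return "intergenic", nearest.gene_id


class TestClassifyContext:
    def test_del_inside_exon(self):
        genes = [gene("g1", 1000, 2000)]
        ctx = classify_context(make_rec(pos=1100, length=60), GeneIndex(genes))
        assert ctx.context == "exonic" and ctx.linked_gene == "g1"

    def test_intronic(self):
        genes = [gene("g1", 1000, 3000, exons=[(1000, 1200), (2800, 3000)])]
        ctx = classify_context(make_rec(pos=1500, length=60), GeneIndex(genes))
        assert ctx.context == "intronic"

    def test_planted_style_promoter_deletion(self):
        # 51 bp DEL inside [start-2000, start-1] of a + strand gene
        genes = [gene("g1", 10000, 11000)]
        sv = make_rec(pos=10000 - 151, length=51)
        ctx = classify_context(sv, GeneIndex(genes))
        assert ctx.context == "promoter" and ctx.linked_gene == "g1"
        assert ctx.distance_to_gene == 101

    def test_minus_strand_promoter_is_right_of_gene(self):
        genes = [gene("g1", 10000, 11000, strand="-")]
        ctx = classify_context(make_rec(pos=11500, length=60), GeneIndex(genes))
        assert ctx.context == "promoter"
        ctx2 = classify_context(make_rec(pos=9500, length=60), GeneIndex(genes))
        assert ctx2.context == "downstream"

    def test_intergenic_nearest_gene(self):
        genes = [gene("g1", 1000, 2000), gene("g2", 50000, 51000)]
        ctx = classify_context(make_rec(pos=10000, length=60), GeneIndex(genes))
        assert ctx.context == "intergenic" and ctx.linked_gene == "g1"
        assert ctx.distance_to_gene == 10000 - 2000

    def test_empty_chromosome(self):
        ctx = classify_context(make_rec(chrom="chr9", pos=10), GeneIndex([gene("g1", 5, 10)]))
        assert ctx.context == "intergenic" and ctx.linked_gene is None

    def test_random_svs_match_interval_algebra_oracle(self):
        rng = np.random.default_rng(53)
        genes = []
        pos = 3000
        for i in range(40):
            pos += int(rng.integers(2500, 9000))
            length = int(rng.integers(500, 2400))
            strand = "+-"[rng.integers(2)]
            n_ex = int(rng.integers(1, 4))
            # alternate exon/intron segments starting and ending with an exon
            cuts = sorted(
                int(c) for c in rng.choice(
                    np.arange(1, length), size=2 * (n_ex - 1), replace=False
                )
            )
            bounds = [0] + cuts + [length]
            exons = tuple(
                (pos + bounds[2 * j] + (1 if j else 0), pos + bounds[2 * j + 1])
                for j in range(n_ex)
            )
            genes.append(
                GeneModel(f"g{i}", "chr1", pos, pos + length, strand, exons)
            )
        index = GeneIndex(genes)
        for _ in range(300):
            svtype = ["DEL", "INS", "INV"][rng.integers(3)]
            sv = make_rec(
                pos=int(rng.integers(1, 300000)),
                svtype=svtype,
                length=int(rng.integers(50, 500)),
                alt_seq=None,
            )
            got = classify_context(sv, index)
            exp_ctx, exp_gene = oracle_context(sv, genes)
            assert (got.context, got.linked_gene) == (exp_ctx, exp_gene)

    def test_partition_and_fraction_sum(self):
        rng = np.random.default_rng(61)
        genes = [gene(f"g{i}", 1 + i * 10000, 3000 + i * 10000) for i in range(10)]
        svs = [make_rec(pos=int(rng.integers(1, 120000)), length=60) for _ in range(100)]
        ctxs = classify_contexts(svs, genes)
        assert len(ctxs) == 100
        frac = context_fractions(ctxs)
        five = frac[frac.view == "five_way"].fraction.sum()
        three = frac[frac.view == "three_way"].fraction.sum()
        assert five == pytest.approx(1.0)
        assert three == pytest.approx(1.0)

    def test_strand_reflection_symmetry(self):
        L = 100000
        genes = [
            gene("g1", 10000, 12000, "+", [(10000, 10500), (11500, 12000)]),
            gene("g2", 40000, 43000, "-"),
        ]
        rng = np.random.default_rng(67)
        svs = [make_rec(pos=int(rng.integers(1, L - 600)), length=int(rng.integers(50, 300)))
               for _ in range(200)]
        mirrored_genes = []
        for g in genes:
            ms, me = L - g.end + 1, L - g.start + 1
            mexons = tuple(sorted((L - e + 1, L - s + 1) for s, e in g.exons))
            mirrored_genes.append(
                GeneModel(g.gene_id, g.chrom, ms, me, "-" if g.strand == "+" else "+", mexons)
            )
        for sv in svs:
            s, e = sv.interval()
            mirrored = make_rec(pos=L - e + 1, length=sv.length, svtype=sv.svtype)
            a = classify_context(sv, GeneIndex(genes))
            b = classify_context(mirrored, GeneIndex(mirrored_genes))
            assert a.context == b.context


def cohort4():
    return Cohort(
        [
            HaplotypeAssembly("r.hap1", "r", "RF"),
            HaplotypeAssembly("r.hap2", "r", "RF"),
            HaplotypeAssembly("g.hap1", "g", "GF"),
            HaplotypeAssembly("g.hap2", "g", "GF"),
        ]
    )


def nrsv(sv_id, carriers, chrom="chr1", pos=100, svtype="DEL", length=60):
    return NonRedundantSV(sv_id, chrom, pos, svtype, length, _carriers=frozenset(carriers))


class TestGroupSpecific:
    def test_two_gf_haplotype_carriers(self):
        cat = [nrsv("sv1", {"g.hap1", "g.hap2"})]
        hits = group_specific_svs(cat, cohort4(), "GF")
        assert [(h.sv_id, h.mode) for h in hits] == [("sv1", "presence_specific")]

    def test_partial_focal_carriers_qualify(self):
        cat = [nrsv("sv1", {"g.hap2"})]
        hits = group_specific_svs(cat, cohort4(), "GF")
        assert hits[0].mode == "presence_specific"
        assert hits[0].carriers == frozenset({"g.hap2"})

    def test_universal_carrier_not_specific(self):
        cat = [nrsv("sv1", {"r.hap1", "r.hap2", "g.hap1", "g.hap2"})]
        for group in ("RF", "GF"):
            assert group_specific_svs(cat, cohort4(), group) == []

    def test_absence_specific(self):
        cat = [nrsv("sv1", {"r.hap1", "r.hap2", "g.hap1"})]
        hits = group_specific_svs(cat, cohort4(), "GF")
        assert [(h.sv_id, h.mode) for h in hits] == [("sv1", "absence_specific")]

    def test_random_carrier_sets_match_subset_oracle(self):
        rng = np.random.default_rng(71)
        cohort = cohort4()
        haps = cohort.haplotype_ids
        for trial in range(100):
            k = int(rng.integers(1, 5))
            carriers = set(rng.choice(haps, size=k, replace=False))
            cat = [nrsv("sv1", carriers)]
            for group in ("RF", "GF"):
                focal = set(cohort.haplotypes_in_group(group))
                expected = set()
                if carriers and carriers <= focal:
                    expected.add("presence_specific")
                non = set(haps) - carriers
                if non and non <= focal:
                    expected.add("absence_specific")
                got = {h.mode for h in group_specific_svs(cat, cohort, group)}
                assert got == expected

    def test_group_without_haplotypes_errors(self):
        with pytest.raises(ValidationError):
            group_specific_svs([], cohort4(), "YF")

    def test_group_relabel_symmetry(self):
        # swapping the RF and GF labels swaps the hits
        cat = [nrsv("sv1", {"g.hap1", "g.hap2"})]
        swapped = Cohort(
            [
                HaplotypeAssembly("r.hap1", "r", "GF"),
                HaplotypeAssembly("r.hap2", "r", "GF"),
                HaplotypeAssembly("g.hap1", "g", "RF"),
                HaplotypeAssembly("g.hap2", "g", "RF"),
            ]
        )
        assert [h.sv_id for h in group_specific_svs(cat, cohort4(), "GF")] == [
            h.sv_id for h in group_specific_svs(cat, swapped, "RF")
        ]


class TestPromoterDE:
    def test_empty_result_flagged(self):
        res = promoter_de_overlap([], [], ("r", "g"), {}, cohort4())
        assert res.empty and res.n_genes == 0

    def test_unknown_accession(self):
        with pytest.raises(ValidationError):
            promoter_de_overlap([], [], ("r", "nope"), {}, cohort4())

    def test_hand_built_fractions(self):
        from pansv.svcontext import SVContext

        cat = [nrsv(f"sv{i}", {"g.hap1"}, pos=100 + 1000 * i) for i in range(4)]
        ctxs = [SVContext(f"sv{i}", "promoter", f"gene{i}", 10) for i in range(4)]
        de = {"gene0": "up", "gene1": "ns", "gene2": "ns", "gene3": "ns"}
        res = promoter_de_overlap(cat, ctxs, ("r", "g"), de, cohort4())
        assert res.n_genes == 4
        assert (res.frac_up, res.frac_down, res.frac_ns) == (0.25, 0.0, 0.75)
        assert res.frac_up + res.frac_down + res.frac_ns == pytest.approx(1.0)

    def test_sv_in_both_accessions_excluded(self):
        from pansv.svcontext import SVContext

        cat = [nrsv("sv1", {"g.hap1", "r.hap1"})]
        ctxs = [SVContext("sv1", "promoter", "geneA", 10)]
        res = promoter_de_overlap(cat, ctxs, ("r", "g"), {"geneA": "up"}, cohort4())
        assert res.empty


class TestNaiveDE:
    def test_planted_difference_detected(self):
        rng = np.random.default_rng(73)
        base = rng.lognormal(3, 0.2, size=(50, 6))
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        expr.loc["g0", ["b0", "b1", "b2"]] *= 8
        de = naive_de(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert de.loc["g0", "status"] == "up"
        assert (de.status == "ns").sum() > 40


class TestPathway:
    def test_empty_list(self, catalog, contexts):
        df = pathway_sv_association(catalog, contexts, [])
        assert df.empty

    def test_toy_nearest_intergenic_link(self):
        from pansv.svcontext import SVContext

        cat = [nrsv("sv1", {"g.hap1"}), nrsv("sv2", {"g.hap1"}, pos=5000),
               nrsv("sv3", {"g.hap1"}, pos=9000)]
        ctxs = [
            SVContext("sv1", "intergenic", "pw1", 500),
            SVContext("sv2", "exonic", "other", 0),
            SVContext("sv3", "intergenic", "other", 99),
        ]
        df = pathway_sv_association(cat, ctxs, ["pw1"])
        assert list(df.sv_id) == ["sv1"]
        assert list(df.context) == ["intergenic"]

    def test_missing_pathway_gene_skipped(self, caplog):
        df = pathway_sv_association([], [], ["ghost"], known_gene_ids={"real"})
        assert df.empty

    def test_planted_sv_reported_as_promoter(self, bundle, catalog, contexts, truth):
        pathway = pio.read_gene_list(bundle.pathway_genes)
        planted_gene_name = truth[truth.entity_type == "planted_gene"].iloc[0]["id"]
        assert planted_gene_name in pathway
        df = pathway_sv_association(catalog, contexts, pathway)
        planted = planted_sv_truth(truth)
        entry = find_catalog_entry(catalog, planted["chrom"], planted["pos"], "DEL")
        row = df[df.sv_id == entry.id]
        assert len(row) == 1
        assert row.iloc[0].context == "promoter"
        assert row.iloc[0].gene == planted_gene_name


class TestOnSyntheticCohort:
    def test_planted_gf_specific_with_exact_carriers(self, catalog, cohort, truth):
        planted = planted_sv_truth(truth)
        entry = find_catalog_entry(catalog, planted["chrom"], planted["pos"], "DEL")
        hits = group_specific_svs(catalog, cohort, "GF")
        mine = [h for h in hits if h.sv_id == entry.id]
        assert len(mine) == 1
        assert mine[0].mode == "presence_specific"
        assert mine[0].carriers == planted["carriers"]

    def test_planted_gene_in_up_fraction(self, bundle, catalog, contexts, cohort, truth):
        pair = tuple(
            truth[truth.entity_type == "contrast_pair"].iloc[0].planted_label.split(",")
        )
        expr = pio.read_expression(bundle.expression)
        cols_a = [c for c in expr.columns if c.startswith(f"{pair[0]}_late")]
        cols_b = [c for c in expr.columns if c.startswith(f"{pair[1]}_late")]
        de = naive_de(expr, cols_a, cols_b)
        res = promoter_de_overlap(
            catalog, contexts, pair, de["status"].to_dict(), cohort
        )
        planted_gene_name = truth[truth.entity_type == "planted_gene"].iloc[0]["id"]
        assert res.genes.get(planted_gene_name) == "up"
        assert res.frac_up > 0
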