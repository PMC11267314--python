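"""Shared fixtures: one default synthetic cohort generated per session."""
from __future__ import annotations

import pandas as pd
import pytest

import pansv.io as pio
from pansv.models import SVRecord
from pansv.simulate import CohortSpec, generate_cohort
from pansv.svcatalog import merge_svs

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return generate_cohort(
        CohortSpec(seed=DEFAULT_SEED), tmp_path_factory.mktemp("cohort")
    )


@pytest.fixture(scope="session")
def cohort(bundle):
    return pio.read_labels(bundle.labels, pio.read_chrom_lengths(bundle.chrom_lengths))


@pytest.fixture(scope="session")
def truth(bundle) -> pd.DataFrame:
    return pd.read_csv(bundle.truth, sep="\t", dtype=str)


@pytest.fixture(scope="session")
def all_records(bundle, cohort):
    records = []
    for hap in cohort.haplotype_ids:
        path = bundle.vcf_for(hap)
        if path.exists():
            records.extend(pio.read_sv_vcf(path, hap).records)
    return records


@pytest.fixture(scope="session")
def catalog(all_records, cohort):
    pav = [r for r in all_records if r.svtype in ("INS", "DEL")]
    return merge_svs(pav, chrom_lengths=cohort.chrom_lengths)


@pytest.fixture(scope="session")
def ref_genes(bundle):
    return pio.read_gff3(bundle.gff3_for(bundle.spec.reference_haplotype))


@pytest.fixture(scope="session")
def contexts(catalog, ref_genes):
    from pansv.svcontext import classify_contexts

    return classify_contexts(catalog, ref_genes)


def make_rec(
    chrom="chr1", pos=100, svtype="DEL", length=60, hap="A.hap1", alt_seq=None
) -> SVRecord:
    return SVRecord(chrom, pos, svtype, length, hap, alt_seq)


def planted_sv_truth(truth: pd.DataFrame) -> dict:
    row = truth[truth.entity_type == "planted_promoter_sv"].iloc[0]
    svtype, loc, lenpart, carrierpart = row.planted_label.split("|")
    chrom, pos = loc.split(":")
    return {
        "id": row["id"],
        "svtype": svtype,
        "chrom": chrom,
        "pos": int(pos),
        "length": int(lenpart.split("=")[1]),
        "carriers": frozenset(carrierpart.split("=")[1].split(",")),
    }


def find_catalog_entry(catalog, chrom, pos, svtype, tol=50):
    hits = [
        sv
        for sv in catalog
        if sv.chrom == chrom and sv.svtype == svtype and abs(sv.pos - pos) <= tol
    ]
    assert len(hits) == 1, f"expected exactly one catalog hit at {chrom}:{pos}"
    return hits[0]
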