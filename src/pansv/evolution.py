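"""Ka/Ks for aligned coding-sequence pairs and category contrast statistics.

The Ka/Ks estimator is the classical counting method: per-codon synonymous
site fractions averaged over both sequences, all mutational pathways of a
multi-difference codon weighted equally, and a Jukes-Cantor correction
``d = -(3/4) * ln(1 - 4p/3)`` applied to the proportions. Changes that
create a stop codon are counted as nonsynonymous (both in site counting and
along pathways), which keeps N_sites + S_sites exactly equal to the aligned
length.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})
_BASES = "ACGT"


class KaKsUndefined(UserWarning):
    """Emitted when the distance correction is undefined (p >= 3/4)."""


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    n_sites: tuple[float, float]  # (N_sites, S_sites)
    n_diffs: tuple[float, float]  # (Nd, Sd)


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for base in _BASES:
            if base == codon[i]:
                continue
            mutant = codon[:i] + base + codon[i + 1 :]
            if CODON_TO_AA[mutant] == aa and CODON_TO_AA[mutant] != "*":
                syn += 1.0
    syn /= 3.0
    return (3.0 - syn, syn)


@lru_cache(maxsize=None)
def _codon_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over all mutational pathways."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    nd_total = 0.0
    sd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        nd = sd = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = CODON_TO_AA[current], CODON_TO_AA[nxt]
            if aa_from == aa_to and aa_to != "*":
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        nd_total += nd
        sd_total += sd
        n_paths += 1
    return (nd_total / n_paths, sd_total / n_paths)


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        warnings.warn(
            f"proportion of differences p={p:.3f} >= 3/4; distance undefined",
            KaKsUndefined,
            stacklevel=3,
        )
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Ka/Ks for two pre-aligned coding sequences (equal length, multiple of
    3, codon-aligned, no internal stop codons; a terminal stop is allowed).

    Symmetric in its arguments; ``ratio`` is NaN when ks is 0 or undefined.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0 or not a:
        raise ValueError("sequence length must be a positive multiple of 3")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    for name, codons in (("first", codons_a), ("second", codons_b)):
        for j, codon in enumerate(codons):
            if any(base not in _BASES for base in codon):
                raise ValueError(f"{name} sequence: non-ACGT base in codon {j + 1}")
            if CODON_TO_AA[codon] == "*" and j != len(codons) - 1:
                raise ValueError(f"{name} sequence: internal stop codon at codon {j + 1}")

    n_sites = s_sites = 0.0
    nd = sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = _codon_diff_counts(ca, cb)
        nd += d_n
        sd += d_s

    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = _jukes_cantor(pn)
    ks = _jukes_cantor(ps)
    ratio = ka / ks if (ks and not math.isnan(ks) and not math.isnan(ka)) else math.nan
    return KaKsResult(ka, ks, ratio, (n_sites, s_sites), (nd, sd))


# ---------------------------------------------------------------------------
# category contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    metric: str
    medians: dict[str, float]
    n: dict[str, int]
    comparisons: dict[tuple[str, str], tuple[float, float]]  # (U, p)

    def p_value(self, cat_a: str, cat_b: str) -> float:
        key = (cat_a, cat_b) if (cat_a, cat_b) in self.comparisons else (cat_b, cat_a)
        return self.comparisons[key][1]


#: exact enumeration is used when both groups have at most this many values
EXACT_MAX_N = 10
# C(20, 10) = 184756 distinct splits; this bound keeps the permutation
# method exact (not Monte Carlo) for every case we enumerate.
_PERMUTATION_RESAMPLES = 200_000


def category_contrast(
    values: Sequence[float],
    labels: Sequence[str],
    metric: str = "value",
) -> ContrastResult:
    """Medians per category plus two-sided Mann-Whitney U between every
    category pair.

    Exact permutation enumeration when both groups have <= 10 values;
    normal approximation with tie correction otherwise. Monotone transforms
    of the values leave U and p unchanged.
    """
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    by_cat: dict[str, list[float]] = {}
    for v, lab in zip(values, labels):
        by_cat.setdefault(str(lab), []).append(float(v))
    if len(by_cat) < 2:
        raise ValueError("need at least 2 categories")
    for cat, vals in by_cat.items():
        if len(vals) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 values")

    cats = sorted(by_cat)
    comparisons: dict[tuple[str, str], tuple[float, float]] = {}
    for ca, cb in itertools.combinations(cats, 2):
        x, y = by_cat[ca], by_cat[cb]
        if max(len(x), len(y)) <= EXACT_MAX_N:
            method = stats.PermutationMethod(n_resamples=_PERMUTATION_RESAMPLES)
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        comparisons[(ca, cb)] = (float(res.statistic), float(res.pvalue))
    return ContrastResult(
        metric=metric,
        medians={c: float(np.median(by_cat[c])) for c in cats},
        n={c: len(by_cat[c]) for c in cats},
        comparisons=comparisons,
    )


def haplotype_cds_pairs(
    orthogroups: Mapping[str, Mapping[str, Sequence[str]]],
    hap_a: str,
    hap_b: str,
) -> list[tuple[str, str, str]]:
    """Clusters with exactly one gene in each of the two haplotypes, as
    (cluster, gene_a, gene_b) tuples; other clusters are skipped."""
    pairs = []
    for cluster, entry in orthogroups.items():
        genes_a = entry.get(hap_a, [])
        genes_b = entry.get(hap_b, [])
        if len(genes_a) == 1 and len(genes_b) == 1:
            pairs.append((cluster, genes_a[0], genes_b[0]))
    return pairs
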