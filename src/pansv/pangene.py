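"""Presence/absence matrix, pan-gene classification and saturation curves.

Cluster categories over ``N`` assemblies:

* ``core``     — present in all ``N``
* ``cloud``    — present in exactly 1
* ``softcore`` — present in ``1 < k < N`` with ``k / N`` strictly greater
  than the softcore fraction (default 0.80)
* ``shell``    — the remainder

Both cluster-level fractions (each cluster weighs 1) and gene-level
fractions (clusters weighted by their total gene membership) are reported,
clearly labeled, because the two weightings answer different questions.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ValidationError

CATEGORIES = ("core", "softcore", "shell", "cloud")


@dataclass
class PresenceMatrix:
    """Boolean clusters x haplotypes table plus per-cell gene counts."""

    clusters: list[str]
    haplotypes: list[str]
    gene_counts: np.ndarray  # shape (n_clusters, n_haplotypes), int

    def __post_init__(self) -> None:
        self.gene_counts = np.asarray(self.gene_counts, dtype=int)
        if self.gene_counts.shape != (len(self.clusters), len(self.haplotypes)):
            raise ValidationError("gene_counts shape does not match labels")
        if (self.gene_counts < 0).any():
            raise ValidationError("negative gene counts")
        empty = np.flatnonzero(self.gene_counts.sum(axis=1) == 0)
        if empty.size:
            raise ValidationError(
                f"clusters present in no haplotype: "
                f"{[self.clusters[i] for i in empty[:5]]}"
            )

    @property
    def present(self) -> np.ndarray:
        return self.gene_counts > 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @classmethod
    def from_orthogroups(
        cls,
        orthogroups: Mapping[str, Mapping[str, Sequence[str]]],
        haplotypes: Sequence[str] | None = None,
    ) -> "PresenceMatrix":
        clusters = list(orthogroups)
        if haplotypes is None:
            haps: list[str] = []
            for entry in orthogroups.values():
                for h in entry:
                    if h not in haps:
                        haps.append(h)
            haplotypes = haps
        counts = np.zeros((len(clusters), len(haplotypes)), dtype=int)
        hap_idx = {h: j for j, h in enumerate(haplotypes)}
        for i, cluster in enumerate(clusters):
            for h, genes in orthogroups[cluster].items():
                if h in hap_idx:
                    counts[i, hap_idx[h]] = len(genes)
        return cls(clusters, list(haplotypes), counts)


@dataclass
class PanClassification:
    labels: dict[str, str]
    counts: dict[str, int]
    cluster_fractions: dict[str, float]
    gene_fractions: dict[str, float]
    softcore_fraction: float

    @property
    def n_clusters(self) -> int:
        return sum(self.counts.values())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_clusters": pd.Series(self.counts),
                "cluster_fraction": pd.Series(self.cluster_fractions),
                "gene_fraction": pd.Series(self.gene_fractions),
            }
        ).loc[list(CATEGORIES)]


def classify_clusters(
    matrix: PresenceMatrix, softcore_fraction: float = 0.80
) -> PanClassification:
    """Label every cluster core/softcore/shell/cloud.

    ``softcore`` uses a strict inequality (``k / N > softcore_fraction``)
    and core takes precedence, so a count of ``N`` is never softcore.
    """
    n = matrix.n_haplotypes
    if n < 2:
        raise ValidationError("classification needs at least 2 haplotypes")
    presence = matrix.present.sum(axis=1)
    labels: dict[str, str] = {}
    for cluster, k in zip(matrix.clusters, presence):
        if k == n:
            cat = "core"
        elif k == 1:
            cat = "cloud"
        elif k / n > softcore_fraction:
            cat = "softcore"
        else:
            cat = "shell"
        labels[cluster] = cat

    counts = {c: 0 for c in CATEGORIES}
    gene_weight = {c: 0 for c in CATEGORIES}
    totals = matrix.gene_counts.sum(axis=1)
    for cluster, w in zip(matrix.clusters, totals):
        cat = labels[cluster]
        counts[cat] += 1
        gene_weight[cat] += int(w)
    n_clusters = len(matrix.clusters)
    n_genes = int(totals.sum())
    return PanClassification(
        labels=labels,
        counts=counts,
        cluster_fractions={c: counts[c] / n_clusters for c in CATEGORIES},
        gene_fractions={c: gene_weight[c] / n_genes for c in CATEGORIES},
        softcore_fraction=softcore_fraction,
    )


def per_assembly_composition(
    matrix: PresenceMatrix, classification: PanClassification
) -> pd.DataFrame:
    """Gene-level category composition per haplotype (rows sum to 1)."""
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    rows = np.array([cat_idx[classification.labels[c]] for c in matrix.clusters])
    out = np.zeros((matrix.n_haplotypes, len(CATEGORIES)))
    for ci in range(len(CATEGORIES)):
        mask = rows == ci
        out[:, ci] = matrix.gene_counts[mask].sum(axis=0)
    totals = out.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("haplotype with zero genes")
    return pd.DataFrame(
        out / totals, index=pd.Index(matrix.haplotypes, name="haplotype"),
        columns=list(CATEGORIES),
    )


@dataclass
class SaturationCurve:
    """Pan/core cluster counts versus number of assemblies sampled."""

    k: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_orderings: int
    exhaustive: bool
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_mean": self.pan_mean,
                "pan_sd": self.pan_sd,
                "core_mean": self.core_mean,
                "core_sd": self.core_sd,
            }
        ).set_index("k")


def saturation_curve(
    matrix: PresenceMatrix,
    n_permutations: int = 100,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> SaturationCurve:
    """Pan/core cluster counts over random orderings of the haplotypes.

    For each ordering and prefix length ``k``: pan = clusters present in at
    least one of the first ``k`` haplotypes, core = clusters present in all
    of them. When ``exhaustive`` is None it is enabled automatically for
    ``N <= 8`` (at most 40320 orderings).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = matrix.n_haplotypes
    present = matrix.present
    if exhaustive is None:
        exhaustive = n <= 8
    if exhaustive:
        orderings = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orderings = [rng.permutation(n) for _ in range(n_permutations)]
    pans = np.empty((len(orderings), n), dtype=int)
    cores = np.empty((len(orderings), n), dtype=int)
    for i, order in enumerate(orderings):
        cols = present[:, order]
        pans[i] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        cores[i] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
    return SaturationCurve(
        k=np.arange(1, n + 1),
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0),
        n_orderings=len(orderings),
        exhaustive=exhaustive,
        seed=seed,
    )


def new_cluster_increments(
    matrix: PresenceMatrix, ordering: Sequence[str]
) -> list[int]:
    """Per-step counts of clusters unseen in all previous haplotypes.

    Increments sum to the total cluster count.
    """
    if sorted(ordering) != sorted(matrix.haplotypes):
        raise ValidationError("ordering is not a permutation of the haplotypes")
    hap_idx = {h: j for j, h in enumerate(matrix.haplotypes)}
    seen = np.zeros(len(matrix.clusters), dtype=bool)
    increments: list[int] = []
    for hap in ordering:
        col = matrix.present[:, hap_idx[hap]]
        new = col & ~seen
        increments.append(int(new.sum()))
        seen |= col
    return increments
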