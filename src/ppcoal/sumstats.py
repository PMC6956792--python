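"""Summary statistics compared between empirical and predictive data.

Data-based: multi-locus pairwise F_ST (Hudson's estimator, combined
across loci as a ratio of sums), its mean and range over species pairs.
Inference-based: Robinson-Foulds and Kuhner-Felsenstein (branch-score)
tree distances, and the mean/SD of sampled tree likelihoods.

Negative per-pair F_ST values are reported as computed, never clamped:
clamping would bias the tail counts of the posterior predictive check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .simulate import SNPMatrix
from .treeio import SpeciesTree, TraceLog

__all__ = [
    "PairwiseFstMatrix",
    "LikelihoodSummary",
    "hudson_fst_locus",
    "pairwise_fst",
    "fst_mean",
    "fst_range",
    "rf_distance",
    "kf_distance",
    "likelihood_mean_sd",
]


@dataclass
class PairwiseFstMatrix:
    """Symmetric per-pair multi-locus F_ST with bookkeeping.

    ``values[i, j]`` is the ratio-of-sums F_ST between ``species[i]``
    and ``species[j]``; NaN marks a pair with no informative loci.
    """

    species: list[str]
    values: np.ndarray
    per_pair_loci: np.ndarray

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.values[i, j])

    def defined_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(len(self.species)):
            for j in range(i + 1, len(self.species)):
                v = self.values[i, j]
                if not np.isnan(v):
                    out.append((self.species[i], self.species[j], float(v)))
        return out


@dataclass
class LikelihoodSummary:
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# F_ST


def hudson_fst_locus(
    allele_counts_a: tuple[float, float], allele_counts_b: tuple[float, float]
) -> tuple[float, float]:
    """Per-locus Hudson F_ST numerator and denominator.

    Given (derived, total) haploid allele counts in each population with
    sample frequencies p1, p2:

        N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    The two correction terms make N unbiased for small samples; N may be
    negative. Multi-locus F_ST is sum(N)/sum(D) (ratio of sums), which
    is robust to loci with small denominators.
    """
    d1, n1 = allele_counts_a
    d2, n2 = allele_counts_b
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 haploid samples")
    p1 = d1 / n1
    p2 = d2 / n2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(snps: SNPMatrix) -> PairwiseFstMatrix:
    """Multi-locus Hudson F_ST for every unordered species pair.

    Loci monomorphic within a pooled pair are uninformative for that
    pair and excluded from its sums. A pair left with no informative
    loci is reported NaN with a warning.
    """
    species = snps.species
    if len(species) < 2:
        raise ValueError("need >= 2 species for pairwise F_ST")
    counts = {}
    for sp in species:
        rows = snps.species_rows(sp)
        if len(rows) < 2:
            raise ValueError(
                f"species {sp!r} has {len(rows)} haploid sample(s); "
                "Hudson's correction terms require >= 2"
            )
        counts[sp] = (snps.genotypes[rows].sum(axis=0).astype(float), float(len(rows)))
    k = len(species)
    values = np.full((k, k), np.nan)
    per_pair = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d1, n1 = counts[species[i]]
            d2, n2 = counts[species[j]]
            pooled = d1 + d2
            informative = (pooled > 0) & (pooled < n1 + n2)
            p1 = d1[informative] / n1
            p2 = d2[informative] / n2
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (n1 - 1)
                - p2 * (1 - p2) / (n2 - 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
            per_pair[i, j] = per_pair[j, i] = int(informative.sum())
            dsum = den.sum()
            if dsum > 0:
                values[i, j] = values[j, i] = num.sum() / dsum
            else:
                warnings.warn(
                    f"pair ({species[i]}, {species[j]}) has no informative "
                    "loci; F_ST undefined",
                    stacklevel=2,
                )
    return PairwiseFstMatrix(species=list(species), values=values, per_pair_loci=per_pair)


def _defined_values(m: PairwiseFstMatrix) -> np.ndarray:
    iu = np.triu_indices(len(m.species), k=1)
    vals = m.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined species pairs")
    return vals


def fst_mean(m: PairwiseFstMatrix) -> float:
    """Arithmetic mean F_ST over defined species pairs (statistic FSTA)."""
    return float(_defined_values(m).mean())


def fst_range(m: PairwiseFstMatrix) -> float:
    """Max minus min F_ST over defined species pairs (statistic FSTR)."""
    vals = _defined_values(m)
    return float(vals.max() - vals.min())


# ---------------------------------------------------------------------------
# tree distances


def _common_namespace(t1: SpeciesTree, t2: SpeciesTree) -> tuple[dendropy.Tree, dendropy.Tree]:
    if frozenset(t1.tip_labels) != frozenset(t2.tip_labels):
        raise ValueError(
            f"tip sets differ: {sorted(t1.tip_labels)} vs {sorted(t2.tip_labels)}"
        )
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.to_newick(), schema="newick", taxon_namespace=ns,
        preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=t2.to_newick(), schema="newick", taxon_namespace=ns,
        preserve_underscores=True,
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return a, b


def rf_distance(t1: SpeciesTree, t2: SpeciesTree, normalized: bool = True) -> float:
    """Robinson-Foulds symmetric-difference distance (topology only).

    Computed on the unrooted view of the trees; when ``normalized`` the
    count is divided by its maximum ``2*(n-3)`` so identical topologies
    score 0 and maximally different ones score 1. Trees with fewer than
    4 tips have no non-trivial bipartitions; their normalized distance
    is 0 by convention.
    """
    a, b = _common_namespace(t1, t2)
    raw = float(treecompare.symmetric_difference(a, b))
    if not normalized:
        return raw
    n = t1.n_tips
    denom = 2.0 * (n - 3)
    if denom <= 0:
        return 0.0
    return raw / denom


def kf_distance(t1: SpeciesTree, t2: SpeciesTree) -> float:
    """Kuhner-Felsenstein branch-score distance (topology + lengths).

    sqrt of the summed squared branch-length differences over the union
    of bipartitions, a bipartition absent from a tree contributing its
    full length from the other. Unnormalized: the posterior predictive
    procedure only ever compares KF values on a common tip set, so the
    scale cancels.
    """
    a, b = _common_namespace(t1, t2)
    return float(treecompare.euclidean_distance(a, b))


# ---------------------------------------------------------------------------
# likelihood trace


def likelihood_mean_sd(log: TraceLog) -> LikelihoodSummary:
    """Mean and sample SD (n-1 denominator) of the trace likelihoods."""
    vals = log.likelihoods
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 trace rows for a standard deviation, got {len(vals)}"
        )
    return LikelihoodSummary(
        mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=len(vals)
    )
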