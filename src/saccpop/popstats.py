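"""Nucleotide diversity, Watterson's theta, and polymorphism partitions.

Diploid IUPAC calls are expanded to two allele copies (a heterozygous
call contributes one copy of each allele).  Per-site statistics use only
sites where at least 80% of the group's isolates are non-missing; the
genome-scale denominator additionally counts invariant callable sites,
which the variant-only matrix does not store and must be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from saccpop.snpcall import BASE_ORDER, GenotypeMatrix, HET_CODES, IUPAC_ALLELES


@dataclass(frozen=True)
class PopStatsResult:
    group: str
    pi: float
    theta: float
    S: int
    n_alleles: int
    n_sites_analyzed: int


@dataclass(frozen=True)
class PolymorphismPartition:
    group_a: str
    group_b: str
    shared: int
    fixed: int
    private_a: int
    private_b: int
    analyzed_sites: int

    def swap(self) -> "PolymorphismPartition":
        return PolymorphismPartition(self.group_b, self.group_a, self.shared,
                                     self.fixed, self.private_b,
                                     self.private_a, self.analyzed_sites)


_ALLELE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}


def _allele_count_columns(calls: np.ndarray) -> np.ndarray:
    """(n_sites, 4) allele-copy counts from a (n_isolates, n_sites) call
    block, expanding het codes to one copy of each allele."""
    n_sites = calls.shape[1]
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    for b in BASE_ORDER:
        counts[:, _ALLELE_IDX[b]] += 2 * (calls == b).sum(axis=0)
    for code, (a, b) in IUPAC_ALLELES.items():
        mask = (calls == code).sum(axis=0)
        counts[:, _ALLELE_IDX[a]] += mask
        counts[:, _ALLELE_IDX[b]] += mask
    return counts


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (Watterson's denominator uses a_{n-1})."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


def nucleotide_diversity(matrix: GenotypeMatrix, members: Sequence[str],
                         invariant_callable_sites: int = 0,
                         min_group_coverage: float = 0.80,
                         group_id: str = "group") -> PopStatsResult:
    """Pi and Watterson's theta for one group of isolates.

    Sites qualify when >= ``min_group_coverage`` of the group's isolates
    are non-missing.  pi_site is the mean pairwise difference over the
    allele copies present; the per-site denominators add
    ``invariant_callable_sites`` so the result is a genome-scale
    per-site quantity.
    """
    if len(members) < 2:
        raise ValueError("group must contain at least 2 isolates")
    sub = matrix.subset(list(members))
    non_n = sub.calls != "N"
    qualifying = non_n.mean(axis=0) >= min_group_coverage
    counts = _allele_count_columns(sub.calls[:, qualifying])
    k = counts.sum(axis=1)  # allele copies present per site
    # mean pairwise difference over copies: (k^2 - sum c_i^2) / (k (k-1))
    sq = (counts.astype(float) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(k >= 2, (k.astype(float) ** 2 - sq)
                           / (k * (k - 1.0)), 0.0)
    segregating = (counts > 0).sum(axis=1) >= 2
    S = int(segregating.sum())
    denom = int(qualifying.sum()) + invariant_callable_sites
    pi = float(pi_site.sum() / denom) if denom > 0 else float("nan")
    n_alleles = 2 * len(members)
    a = harmonic_number(n_alleles - 1)
    theta = float(S / a / denom) if denom > 0 else float("nan")
    return PopStatsResult(group_id, pi, theta, S, n_alleles,
                          int(qualifying.sum()))


def polymorphism_partition(matrix: GenotypeMatrix, group_a: Sequence[str],
                           group_b: Sequence[str],
                           min_nonmissing: float = 0.75,
                           drop_singletons: bool = True,
                           mode: str = "ambiguity",
                           labels: tuple[str, str] = ("A", "B"),
                           ) -> PolymorphismPartition:
    """Shared/fixed/private polymorphism counts between two groups.

    Retained sites have non-missing data in >= ``min_nonmissing`` of the
    pooled isolates; sites whose variant allele is carried by exactly
    one isolate (singletons) are removed.  In ``ambiguity`` mode IUPAC
    het codes are valid data and sites may carry more than two alleles;
    in ``biallelic`` mode het codes are treated as missing and sites
    with more than two alleles are excluded.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group must contain at least 2 isolates")
    if mode not in ("ambiguity", "biallelic"):
        raise ValueError("mode must be 'ambiguity' or 'biallelic'")

    sub_a = matrix.subset(list(group_a)).calls.copy()
    sub_b = matrix.subset(list(group_b)).calls.copy()
    if mode == "biallelic":
        for block in (sub_a, sub_b):
            block[np.isin(block, list(HET_CODES))] = "N"

    pooled = np.vstack([sub_a, sub_b])
    valid = pooled != "N"
    keep = valid.mean(axis=0) >= min_nonmissing

    counts_a = _allele_count_columns(sub_a)
    counts_b = _allele_count_columns(sub_b)
    pooled_counts = counts_a + counts_b
    n_alleles_site = (pooled_counts > 0).sum(axis=1)
    if mode == "biallelic":
        keep &= n_alleles_site <= 2

    if drop_singletons:
        # an allele is a singleton when exactly one isolate of the pooled
        # pair carries it (with any copy number)
        carriers = np.zeros_like(pooled_counts)
        for b, i in _ALLELE_IDX.items():
            carried = (pooled == b)
            for code, (x, y) in IUPAC_ALLELES.items():
                if b in (x, y):
                    carried |= pooled == code
            carriers[:, i] = carried.sum(axis=0)
        major = pooled_counts.argmax(axis=1)
        is_minor = pooled_counts > 0
        is_minor[np.arange(is_minor.shape[0]), major] = False
        singleton = (is_minor & (carriers == 1)).any(axis=1)
        keep &= ~singleton

    poly_a = (counts_a > 0).sum(axis=1) >= 2
    poly_b = (counts_b > 0).sum(axis=1) >= 2
    mono_a = (counts_a > 0).sum(axis=1) == 1
    mono_b = (counts_b > 0).sum(axis=1) == 1
    allele_a = counts_a.argmax(axis=1)
    allele_b = counts_b.argmax(axis=1)

    shared = keep & poly_a & poly_b
    fixed = keep & mono_a & mono_b & (allele_a != allele_b)
    private_a = keep & poly_a & ~poly_b
    private_b = keep & poly_b & ~poly_a

    return PolymorphismPartition(labels[0], labels[1], int(shared.sum()),
                                 int(fixed.sum()), int(private_a.sum()),
                                 int(private_b.sum()), int(keep.sum()))


def shared_fraction(partition: PolymorphismPartition) -> float:
    """Shared polymorphisms as a percentage of all classified sites."""
    denom = (partition.shared + partition.fixed + partition.private_a
             + partition.private_b)
    if denom == 0:
        raise ValueError("no classified sites: shared fraction undefined")
    return 100.0 * partition.shared / denom


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (ties by average rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, _ = sstats.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# brute-force oracles (kept next to the implementations they check; used
# by the test suite for oracle-equivalence on small matrices)


def pi_bruteforce(matrix: GenotypeMatrix, members: Sequence[str],
                  invariant_callable_sites: int = 0,
                  min_group_coverage: float = 0.80) -> float:
    """Double loop over allele-copy pairs; O(sites x copies^2)."""
    sub = matrix.subset(list(members))
    total = 0.0
    qualifying = 0
    for j in range(sub.n_sites):
        col = sub.calls[:, j]
        present = [c for c in col if c != "N"]
        if len(present) / len(members) < min_group_coverage:
            continue
        qualifying += 1
        copies: list[str] = []
        for c in present:
            if c in IUPAC_ALLELES:
                copies.extend(IUPAC_ALLELES[c])
            else:
                copies.extend([c, c])
        if len(copies) < 2:
            continue
        diffs = sum(a != b for a, b in combinations(copies, 2))
        total += diffs / (len(copies) * (len(copies) - 1) / 2)
    denom = qualifying + invariant_callable_sites
    return total / denom if denom else float("nan")
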