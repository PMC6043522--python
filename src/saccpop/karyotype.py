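"""Aneuploidy and gene copy-number calling from coverage frames.

Copy values are computed in 1000-bp non-overlapping frames as
(mean frame depth) / (genome-wide median frame depth), so 1.0 means the
basal copy number.  A chromosome's raw value Vo is the median of its
frame values, and is adjusted for the isolate's total DNA content per
cell (flow-cytometry value D, haploid reference = 1) as

    Va = D x (Vo - 1)

so that, e.g., one extra chromosome in a diploid (Vo = 1.5, D = 2)
gives Va = 1.0.  Va is then discretised into copy-number deltas; gene
copy values are discretised against empirical cohort tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from saccpop.synthgen import GeneInterval

#: Printed default tail cut-offs of the cohort gene-CNV distribution.
DEFAULT_TAILS = (0.34, 0.73, 1.2, 1.74)


@dataclass(frozen=True)
class TailThresholds:
    """Empirical percentile cut-offs (1%, 5% left; 5%, 1% right)."""

    left1: float
    left5: float
    right5: float
    right1: float

    def __post_init__(self):
        if not (self.left1 < self.left5 < self.right5 < self.right1):
            raise ValueError("tail thresholds must be strictly increasing")

    @classmethod
    def defaults(cls) -> "TailThresholds":
        return cls(*DEFAULT_TAILS)


@dataclass(frozen=True)
class ChromosomeCall:
    chrom: str
    vo: float
    va: float
    delta: float          # in {-1, -0.5, 0, +0.5, +1, +2}
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# coverage frames


def frame_values(pileup: pd.DataFrame, frame: int = 1000) -> pd.DataFrame:
    """Normalized per-frame copy values from a per-site depth table.

    Frames are non-overlapping, 0-based; a trailing partial frame is
    averaged over its own length.  Value = mean frame depth / genome
    median frame depth.  Scaling all depths by a constant leaves the
    values unchanged.
    """
    df = pileup[["chrom", "pos", "depth"]].copy()
    df["start"] = ((df["pos"] - 1) // frame) * frame
    means = (df.groupby(["chrom", "start"], sort=False, observed=True)["depth"]
             .mean().reset_index(name="mean_depth"))
    median = float(means["mean_depth"].median())
    if median == 0:
        raise ValueError("genome-wide median frame depth is zero")
    means["value"] = means["mean_depth"] / median
    return means[["chrom", "start", "value"]]


def chromosome_vo(frames: pd.DataFrame, chrom: str) -> float:
    """Median frame value of one chromosome."""
    vals = frames.loc[frames["chrom"] == chrom, "value"].to_numpy()
    if vals.size == 0:
        raise ValueError(f"no frames for chromosome {chrom}")
    return float(np.median(vals))


def adjust_va(D: float, vo: float) -> float:
    """Flow-cytometry adjustment: Va = D x (Vo - 1)."""
    if D <= 0:
        raise ValueError("relative DNA content D must be positive")
    return D * (vo - 1.0)


def classify_chromosome(va: float) -> tuple[float, bool]:
    """Discrete copy-number delta for an adjusted value Va.

    Returns (delta, ambiguous).  Va < -0.7 -> -1; -0.6..0.5 -> 0;
    0.6..1.6 -> +1; 1.7..2.6 -> +2.  Values in the gaps between bins
    snap to the nearest bin boundary and values above 2.6 to +2, both
    with the ambiguous flag raised.
    """
    if np.isnan(va):
        raise ValueError("Va is NaN")
    if va < -0.7:
        return -1.0, False
    if -0.6 <= va <= 0.5:
        return 0.0, False
    if 0.6 <= va <= 1.6:
        return 1.0, False
    if 1.7 <= va <= 2.6:
        return 2.0, False
    if va > 2.6:
        return 2.0, True
    # gap value: [-0.7, -0.6), (0.5, 0.6) or (1.6, 1.7)
    edges = [(-0.7, -1.0), (-0.6, 0.0), (0.5, 0.0), (0.6, 1.0),
             (1.6, 1.0), (1.7, 2.0)]
    nearest = min(edges, key=lambda e: abs(va - e[0]))
    return nearest[1], True


def call_chromosome(frames: pd.DataFrame, chrom: str, D: float,
                    ) -> ChromosomeCall:
    vo = chromosome_vo(frames, chrom)
    va = adjust_va(D, vo)
    delta, ambiguous = classify_chromosome(va)
    return ChromosomeCall(chrom, vo, va, delta, ambiguous)


def call_isolate(frames: pd.DataFrame, chroms: Sequence[str], D: float,
                 min_partial_frames: int = 50) -> list[ChromosomeCall]:
    """Whole-chromosome calls plus partial (+/-0.5) calls.

    A chromosome whose whole-chromosome delta is 0 but which contains a
    contiguous run of at least ``min_partial_frames`` frames whose
    run-median Va falls in a nonzero bin receives a partial call of
    +/-0.5 over that run.
    """
    calls = []
    for chrom in chroms:
        call = call_chromosome(frames, chrom, D)
        if call.delta == 0.0:
            partials = detect_partial(frames, chrom, D, min_partial_frames)
            if partials:
                # a single net partial call per chromosome; sign of first run
                call = ChromosomeCall(chrom, call.vo, call.va,
                                      0.5 * np.sign(partials[0][2]),
                                      call.ambiguous)
        calls.append(call)
    return calls


def detect_partial(frames: pd.DataFrame, chrom: str, D: float,
                   min_frames: int = 50) -> list[tuple[int, int, float]]:
    """Contiguous runs of frames deviating into a nonzero Va bin.

    Returns (start_frame_index, end_frame_index_exclusive, run_delta)
    for every maximal run of >= ``min_frames`` frames whose per-frame Va
    is in a nonzero bin and whose run-median Va confirms the bin.
    """
    sub = frames.loc[frames["chrom"] == chrom].sort_values("start")
    va = D * (sub["value"].to_numpy() - 1.0)
    state = np.zeros(va.size, dtype=int)
    state[va >= 0.6] = 1
    state[va <= -0.7] = -1
    runs = []
    i = 0
    while i < va.size:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < va.size and state[j] == state[i]:
            j += 1
        if j - i >= min_frames:
            run_delta, _ = classify_chromosome(float(np.median(va[i:j])))
            if run_delta != 0:
                runs.append((i, j, run_delta))
        i = j
    return runs


def aneuploidy_pattern(deltas: Mapping[str, float],
                       chrom_order: Sequence[str] | None = None) -> str:
    """Canonical pattern key: nonzero deltas joined in chromosome order;
    a euploid isolate yields the empty pattern ''."""
    order = list(chrom_order) if chrom_order is not None else sorted(deltas)
    parts = []
    for chrom in order:
        d = deltas.get(chrom, 0.0)
        if d != 0:
            label = f"{d:+g}"
            parts.append(f"{chrom}:{label}")
    return ";".join(parts)


def count_patterns(patterns: Iterable[str]) -> int:
    """Distinct non-empty aneuploidy patterns in a cohort."""
    return len({p for p in patterns if p})


# ---------------------------------------------------------------------------
# gene CNV


def gene_value(frames: pd.DataFrame, gene: GeneInterval,
               frame: int = 1000) -> float:
    """Median per-base copy value over the ORF.

    Every base inherits the value of its frame; the even-count median
    takes the midpoint of the two central values.
    """
    if gene.end - gene.start < 1:
        raise ValueError("gene interval shorter than 1 bp")
    sub = frames.loc[frames["chrom"] == gene.chrom]
    values, weights = [], []
    for start, value in zip(sub["start"], sub["value"]):
        lo = max(start, gene.start)
        hi = min(start + frame, gene.end)
        if hi > lo:
            values.append(value)
            weights.append(hi - lo)
    if not values:
        raise ValueError(f"gene {gene.name} not covered by frames")
    return float(np.median(np.repeat(values, weights)))


def gene_cnv_table(frames: pd.DataFrame, genes: Sequence[GeneInterval],
                   frame: int = 1000) -> pd.DataFrame:
    rows = [{"gene": g.name, "chrom": g.chrom,
             "value": gene_value(frames, g, frame)} for g in genes]
    return pd.DataFrame(rows)


def fit_tails(values: Iterable[float]) -> TailThresholds:
    """Empirical 1/5/95/99 percentiles of the cohort gene-value pool."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 100:
        raise ValueError("need at least 100 values to fit tails")
    left1, left5, right5, right1 = np.percentile(arr, [1, 5, 95, 99])
    if not (left1 < left5 < right5 < right1):
        raise ValueError("degenerate value distribution: tails not separable")
    return TailThresholds(float(left1), float(left5), float(right5),
                          float(right1))


def discretize(value: float, thresholds: TailThresholds | None = None) -> float:
    """Discrete CNV level of a gene value.

    0 below the 1% left tail (complete deletion), 0.5 up to the 5% left
    tail (partial deletion), 1 through the 5% right tail (normal), 2 up
    to the 1% right tail (two-fold duplication), 3 above it (three or
    more fold; the open top bin is coded by its minimum fold value).
    """
    t = thresholds if thresholds is not None else TailThresholds.defaults()
    if np.isnan(value):
        raise ValueError("CNV value is NaN")
    if value < t.left1:
        return 0.0
    if value < t.left5:
        return 0.5
    if value <= t.right5:
        return 1.0
    if value <= t.right1:
        return 2.0
    return 3.0


def cnv_group_test(values_a: Sequence[float], values_b: Sequence[float],
                   method: str = "wilcoxon",
                   alpha: float = 0.01) -> tuple[float, bool]:
    """Between-group test of one gene's copy values.

    Wilcoxon rank-sum by default, Student's t as an alternative;
    significance is declared at P < ``alpha`` (default 0.01).  A fully
    tied dataset returns P = 1 (not significant).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, False
    if method == "wilcoxon":
        _, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
    elif method == "ttest":
        _, p = sstats.ttest_ind(a, b)
    else:
        raise ValueError("method must be 'wilcoxon' or 'ttest'")
    return float(p), bool(p < alpha)


def cohort_cnv_levels(values: pd.DataFrame,
                      thresholds: TailThresholds | None = None) -> pd.DataFrame:
    """Add discrete levels to a long-format (isolate, gene, value) table.

    With ``thresholds=None`` the cut-offs are fitted from the pooled
    cohort values when there are enough of them, else the printed
    defaults are used.
    """
    if thresholds is None:
        try:
            thresholds = fit_tails(values["value"])
        except ValueError:
            thresholds = TailThresholds.defaults()
    out = values.copy()
    out["level"] = [discretize(v, thresholds) for v in out["value"]]
    return out
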