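"""Coverage frames, chromosome copy calls, gene CNV discretization."""

import numpy as np
import pandas as pd
import pytest

from saccpop import karyotype as kt
from saccpop.synthgen import GeneInterval


def make_pileup(depths_by_chrom):
    frames = []
    for chrom, depths in depths_by_chrom.items():
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.arange(1, len(depths) + 1),
            "depth": np.asarray(depths)}))
    return pd.concat(frames, ignore_index=True)


def make_frames(values_by_chrom, frame=1000):
    rows = []
    for chrom, values in values_by_chrom.items():
        for i, v in enumerate(values):
            rows.append({"chrom": chrom, "start": i * frame, "value": v})
    return pd.DataFrame(rows)


class TestFrameValues:
    def test_uniform_depth_gives_unit_values(self):
        p = make_pileup({"chrI": [40] * 5000})
        f = kt.frame_values(p)
        assert np.allclose(f["value"], 1.0)
        assert len(f) == 5

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        depths = rng.poisson(50, size=8000)
        f1 = kt.frame_values(make_pileup({"chrI": depths}))
        f2 = kt.frame_values(make_pileup({"chrI": depths * 7}))
        assert np.allclose(f1["value"], f2["value"])

    def test_partial_tail_window_uses_own_length(self):
        p = make_pileup({"chrI": [10] * 2400})    # last window 400 bp
        f = kt.frame_values(p)
        assert len(f) == 3
        assert np.allclose(f["value"], 1.0)

    def test_zero_median_rejected(self):
        p = make_pileup({"chrI": [0] * 3000})
        with pytest.raises(ValueError):
            kt.frame_values(p)

    def test_triploid_chromosome_value(self):
        rng = np.random.default_rng(1)
        p = make_pileup({"chrI": rng.poisson(75, 20_000),
                         "chrII": rng.poisson(50, 40_000)})
        f = kt.frame_values(p)
        vo = kt.chromosome_vo(f, "chrI")
        assert abs(vo - 1.5) < 0.05


class TestChromosomeCalls:
    def test_vo_median(self):
        f = make_frames({"chrI": [1.0, 1.0, 1.0]})
        assert kt.chromosome_vo(f, "chrI") == 1.0
        f = make_frames({"chrI": [1.4, 1.5, 1.6]})
        assert kt.chromosome_vo(f, "chrI") == 1.5

    def test_vo_robust_to_outlier_frame(self):
        f = make_frames({"chrI": [1.0] * 99 + [10.0]})
        assert kt.chromosome_vo(f, "chrI") == 1.0

    @pytest.mark.parametrize("D,vo,expected", [
        (2.0, 1.5, 1.0), (1.0, 1.0, 0.0), (2.0, 0.6, -0.8)])
    def test_va_equation(self, D, vo, expected):
        assert kt.adjust_va(D, vo) == pytest.approx(expected)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            kt.adjust_va(0.0, 1.0)

    @pytest.mark.parametrize("va,delta,ambiguous", [
        (1.0, 1.0, False),     # one extra copy
        (-0.8, -1.0, False),   # one copy missing
        (0.0, 0.0, False),
        (2.0, 2.0, False),
        (1.65, 1.0, True),     # gap between printed bins
        (3.4, 2.0, True),      # above the printed range
    ])
    def test_classification_bins(self, va, delta, ambiguous):
        assert kt.classify_chromosome(va) == (delta, ambiguous)

    def test_gap_midpoint_snaps_to_a_neighbor_with_flag(self):
        # 0.55 is equidistant from the 0 and +1 bins: either boundary is
        # acceptable but the ambiguity must be flagged
        delta, ambiguous = kt.classify_chromosome(0.55)
        assert delta in (0.0, 1.0) and ambiguous

    def test_classification_is_monotone(self):
        grid = np.linspace(-2.0, 3.5, 1101)
        deltas = [kt.classify_chromosome(v)[0] for v in grid]
        assert all(b >= a for a, b in zip(deltas, deltas[1:]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            kt.classify_chromosome(float("nan"))


class TestPartialCalls:
    def test_uniform_chromosome_no_partial(self):
        f = make_frames({"chrI": [1.0] * 120})
        assert kt.detect_partial(f, "chrI", D=2.0) == []

    def test_planted_segmental_duplication_found(self):
        values = [1.0] * 30 + [1.5] * 60 + [1.0] * 30
        f = make_frames({"chrI": values})
        runs = kt.detect_partial(f, "chrI", D=2.0)
        assert len(runs) == 1
        start, end, delta = runs[0]
        assert (start, end, delta) == (30, 90, 1.0)
        calls = kt.call_isolate(f, ["chrI"], D=2.0)
        assert calls[0].delta == 0.5

    def test_two_separated_runs(self):
        values = ([1.0] * 10 + [1.5] * 55 + [1.0] * 10
                  + [0.6] * 55 + [1.0] * 10)
        f = make_frames({"chrI": values})
        runs = kt.detect_partial(f, "chrI", D=2.0)
        assert len(runs) == 2
        assert runs[0][2] > 0 and runs[1][2] < 0

    def test_short_run_ignored(self):
        values = [1.0] * 50 + [1.5] * 20 + [1.0] * 50
        f = make_frames({"chrI": values})
        assert kt.detect_partial(f, "chrI", D=2.0) == []


class TestPatterns:
    def test_euploid_is_empty_pattern(self):
        assert kt.aneuploidy_pattern({"chrI": 0.0, "chrII": 0.0}) == ""

    def test_canonical_form(self):
        p = kt.aneuploidy_pattern({"chrI": 1.0, "chrIII": 1.0, "chrII": 0.0},
                                  chrom_order=["chrI", "chrII", "chrIII"])
        assert p == "chrI:+1;chrIII:+1"

    def test_distinct_pattern_count(self):
        patterns = ["", "chrI:+1", "chrI:+1", "chrI:+1;chrIII:+1", ""]
        assert kt.count_patterns(patterns) == 2


class TestGeneValue:
    def test_gene_inside_one_frame(self):
        f = make_frames({"chrI": [1.0, 2.0, 1.0]})
        g = GeneInterval("g", "chrI", 1100, 1900)
        assert kt.gene_value(f, g) == 2.0

    def test_per_base_median_majority_frame(self):
        f = make_frames({"chrI": [1.0, 2.0]})
        g = GeneInterval("g", "chrI", 400, 1400)   # 600 bp at 1.0, 400 at 2.0
        assert kt.gene_value(f, g) == 1.0

    def test_even_split_takes_midpoint(self):
        f = make_frames({"chrI": [1.0, 2.0]})
        g = GeneInterval("g", "chrI", 500, 1500)   # 500 bp each
        assert kt.gene_value(f, g) == 1.5

    def test_empty_gene_rejected(self):
        f = make_frames({"chrI": [1.0]})
        with pytest.raises(ValueError):
            kt.gene_value(f, GeneInterval("g", "chrI", 100, 100))


class TestTails:
    def test_uniform_percentiles(self):
        rng = np.random.default_rng(2)
        t = kt.fit_tails(rng.uniform(size=100_000))
        assert t.left1 == pytest.approx(0.01, abs=0.005)
        assert t.left5 == pytest.approx(0.05, abs=0.005)
        assert t.right5 == pytest.approx(0.95, abs=0.005)
        assert t.right1 == pytest.approx(0.99, abs=0.005)

    def test_defaults_mode(self):
        t = kt.TailThresholds.defaults()
        assert (t.left1, t.left5, t.right5, t.right1) == (0.34, 0.73, 1.2, 1.74)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            kt.TailThresholds(0.5, 0.4, 1.2, 1.7)
        with pytest.raises(ValueError):
            kt.fit_tails([1.0] * 200)


class TestDiscretize:
    @pytest.mark.parametrize("value,level", [
        (0.2, 0.0),    # below 1% left tail: complete deletion
        (0.5, 0.5),    # partial deletion
        (1.0, 1.0),    # normal
        (1.5, 2.0),    # two-fold duplication
        (2.0, 3.0),    # above 1% right tail: >= three-fold
    ])
    def test_default_bins(self, value, level):
        assert kt.discretize(value) == level

    def test_monotone_in_value(self):
        grid = np.linspace(0, 3, 301)
        levels = [kt.discretize(v) for v in grid]
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            kt.discretize(float("nan"))


class TestGroupTest:
    def test_identical_groups_not_significant(self):
        p, sig = kt.cnv_group_test([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0])
        assert not sig

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        a = 1.0 + rng.normal(0, 0.02, 10)
        b = 2.0 + rng.normal(0, 0.02, 10)
        p, sig = kt.cnv_group_test(a, b)
        assert sig and p < 0.01
        pt, sigt = kt.cnv_group_test(a, b, method="ttest")
        assert sigt

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1, 0.3, 8)
        b = rng.normal(1.3, 0.3, 8)
        assert kt.cnv_group_test(a, b)[0] == pytest.approx(
            kt.cnv_group_test(b, a)[0])

    def test_all_tied_returns_one(self):
        p, sig = kt.cnv_group_test([1.0] * 5, [1.0] * 5)
        assert p == 1.0 and not sig


class TestRecoveryFromPileups:
    def test_planted_aneuploidy_and_gene_cnv_recovered(self, small_cohort,
                                                       small_pileups):
        spec = small_cohort.spec
        chroms = [c for c, _ in spec.chromosomes]
        correct = total = 0
        for iid, truth in small_cohort.truths.items():
            frames = kt.frame_values(small_pileups[iid])
            calls = kt.call_isolate(frames, chroms, truth.flow_D)
            for c in calls:
                total += 1
                if c.delta == truth.chrom_delta(c.chrom):
                    correct += 1
        assert correct / total >= 0.95

    def test_amplified_genes_discretized_high(self, small_cohort,
                                              small_pileups):
        found = checked = 0
        for iid, truth in small_cohort.truths.items():
            if not truth.gene_factors:
                continue
            frames = kt.frame_values(small_pileups[iid])
            gv = kt.gene_cnv_table(frames, list(small_cohort.spec.genes))
            for gene, factor in truth.gene_factors.items():
                value = gv.loc[gv.gene == gene, "value"].iloc[0]
                level = kt.discretize(value)
                checked += 1
                if factor >= 2 and level >= 2:
                    found += 1
                elif factor == 0 and level == 0:
                    found += 1
        assert checked > 0 and found / checked >= 0.95
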