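"""Filter cascade: annotation/frequency filter, quality vote, stage counts."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from lsdpanel.filters import (
    FilterConfig,
    apply_filter1,
    apply_filter2,
    cohort_nra_frequency,
    implied_fp_rate,
    run_cascade,
)
from lsdpanel.variants import AnnotatedVariant, CohortCallTable, SiteQuality

CFG = FilterConfig()


def _variant(**kw):
    defaults = dict(
        sample_id="S01", caller_id="caller_a", chrom="chr1", pos=101,
        ref="A", alt="T", gene="GLB1", region_class="exonic",
        function_class="nonsynonymous", pop_af=None,
        quality=SiteQuality(depth=40, nra_fraction=0.45, mqv_ref=30.0, mqv_alt=28.0),
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestCohortFrequency:
    def _table(self, n_samples, carrier_samples, pos=101):
        samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
        variants = [_variant(sample_id=s, pos=pos) for s in carrier_samples]
        return CohortCallTable(variants=variants, samples=samples)

    def test_three_of_84(self):
        table = self._table(84, ["S001", "S002", "S003"])
        f = cohort_nra_frequency(table, _variant().site_key)
        assert math.isclose(f, 3 / 84)

    def test_absent_variant(self):
        table = self._table(10, [])
        assert cohort_nra_frequency(table, _variant().site_key) == 0.0

    def test_universal_variant(self):
        samples = [f"S{i:03d}" for i in range(1, 49)]
        table = self._table(48, samples)
        assert cohort_nra_frequency(table, _variant().site_key) == 1.0

    def test_duplicate_caller_counts_sample_once(self):
        samples = ["S001", "S002"]
        variants = [
            _variant(sample_id="S001", caller_id="caller_a"),
            _variant(sample_id="S001", caller_id="caller_b"),
        ]
        table = CohortCallTable(variants=variants, samples=samples)
        assert cohort_nra_frequency(table, _variant().site_key) == 0.5


class TestFilter1:
    def test_common_database_variant_fails_af(self):
        d = apply_filter1(_variant(pop_af=0.05), cohort_freq=0.01)
        assert not d.af_rare and d.region_ok and d.class_ok and d.cohort_rare
        assert not d.passed

    def test_novel_stopgain_passes(self):
        d = apply_filter1(_variant(pop_af=None, function_class="stopgain"),
                          cohort_freq=0.012)
        assert d.passed

    def test_synonymous_fails_class(self):
        d = apply_filter1(_variant(pop_af=0.0, function_class="synonymous"),
                          cohort_freq=0.0)
        assert not d.class_ok and not d.passed

    def test_intronic_fails_region(self):
        d = apply_filter1(_variant(region_class="intronic"), cohort_freq=0.0)
        assert not d.region_ok and not d.passed

    def test_cohort_frequency_boundary(self):
        assert apply_filter1(_variant(), cohort_freq=0.04).cohort_rare
        assert not apply_filter1(_variant(), cohort_freq=0.0401).cohort_rare


class TestFilter2:
    def test_all_conditions_cleared(self):
        d = apply_filter2(SiteQuality(depth=25, nra_fraction=0.40,
                                      mqv_ref=20, mqv_alt=18))
        assert d.votes == 4 and d.passed()

    def test_three_of_four_passes(self):
        d = apply_filter2(SiteQuality(depth=15, nra_fraction=0.35,
                                      mqv_ref=16, mqv_alt=16))
        assert not d.depth_ok and d.votes == 3 and d.passed()

    def test_every_condition_violated(self):
        d = apply_filter2(SiteQuality(depth=10, nra_fraction=0.25,
                                      mqv_ref=10, mqv_alt=20))
        assert d.votes == 0 and not d.passed()

    def test_borderline_flag_when_all_metrics_near_thresholds(self):
        d = apply_filter2(SiteQuality(depth=21, nra_fraction=0.31,
                                      mqv_ref=15, mqv_alt=15))
        assert d.passed() and d.borderline

    def test_comfortable_metrics_not_borderline(self):
        d = apply_filter2(SiteQuality(depth=200, nra_fraction=0.48,
                                      mqv_ref=30, mqv_alt=29))
        assert not d.borderline

    def test_missing_metric_counts_as_unsatisfied(self):
        d = apply_filter2(SiteQuality(depth=None, nra_fraction=0.4,
                                      mqv_ref=20, mqv_alt=20))
        assert not d.depth_ok and d.missing_conditions == 1 and d.votes == 3

    def test_vote_oracle_equivalence(self):
        """Over all 16 condition patterns the pass rule equals >= 3 true."""
        ok = {
            "depth": (25, 10), "nra": (0.40, 0.20),
            "mqv": ((20.0, 18.0), (10.0, 12.0)),
        }
        for pattern in itertools.product([True, False], repeat=4):
            d_ok, n_ok, m_ok, diff_ok = pattern
            mqv_ref, mqv_alt = ok["mqv"][0 if m_ok else 1]
            # mqv/diff interact through the same two metrics: pick values
            # realizing each of the four (mqv_ok, diff_ok) combinations.
            if m_ok and not diff_ok:
                mqv_ref, mqv_alt = 30.0, 16.0
            if not m_ok and diff_ok:
                mqv_ref, mqv_alt = 10.0, 12.0
            if not m_ok and not diff_ok:
                mqv_ref, mqv_alt = 5.0, 20.0
            q = SiteQuality(
                depth=ok["depth"][0 if d_ok else 1],
                nra_fraction=ok["nra"][0 if n_ok else 1],
                mqv_ref=mqv_ref, mqv_alt=mqv_alt,
            )
            d = apply_filter2(q)
            assert (d.depth_ok, d.nra_ok, d.mqv_ok, d.diff_ok) == pattern
            assert d.passed() == (sum(pattern) >= 3)
            assert d.passed(min_votes=4) == (sum(pattern) == 4)


quality_strategy = st.builds(
    SiteQuality,
    depth=st.one_of(st.none(), st.integers(min_value=0, max_value=500)),
    nra_fraction=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    mqv_ref=st.one_of(st.none(), st.floats(0, 60, allow_nan=False)),
    mqv_alt=st.one_of(st.none(), st.floats(0, 60, allow_nan=False)),
)


class TestFilter2Properties:
    @settings(max_examples=200, derandomize=True)
    @given(q=quality_strategy, bump=st.integers(min_value=1, max_value=50))
    def test_raising_min_depth_never_rescues(self, q, bump):
        base = FilterConfig()
        strict = FilterConfig(min_depth=base.min_depth + bump)
        if not apply_filter2(q, base).passed(base.min_votes):
            assert not apply_filter2(q, strict).passed(strict.min_votes)

    @settings(max_examples=200, derandomize=True)
    @given(q=quality_strategy)
    def test_votes_bounded_and_consistent(self, q):
        d = apply_filter2(q)
        assert 0 <= d.votes <= 4
        assert d.votes == sum((d.depth_ok, d.nra_ok, d.mqv_ok, d.diff_ok))
        assert d.passed(4) <= d.passed(3)  # stricter rule passes fewer


class TestCascade:
    def test_empty_table(self):
        table = CohortCallTable(variants=[], samples=["S01"])
        survivors, report, frame = run_cascade(table)
        assert (report.n_input, report.n_after_filter1, report.n_after_filter2) == (0, 0, 0)
        assert len(survivors) == 0 and frame.empty

    def test_filter1_pass_filter2_fail_boundary(self):
        bad_q = SiteQuality(depth=5, nra_fraction=0.1, mqv_ref=5, mqv_alt=20)
        variants = [_variant(sample_id=f"S{i:02d}", pos=100 + i, quality=bad_q)
                    for i in range(1, 6)]
        table = CohortCallTable(variants=variants,
                                samples=[f"S{i:02d}" for i in range(1, 31)])
        _, report, _ = run_cascade(table)
        assert report.n_after_filter1 == report.n_input == 5
        assert report.n_after_filter2 == 0

    def test_matches_per_variant_brute_force(self, cohort):
        """Cascade survivors equal independent per-variant evaluation."""
        table = cohort.calls_a
        survivors, report, _ = run_cascade(table, CFG)
        expected = []
        for v in table.variants:
            f = cohort_nra_frequency(table, v.site_key)
            if not apply_filter1(v, f, CFG).passed:
                continue
            if apply_filter2(v.quality, CFG).passed(CFG.min_votes):
                expected.append(v.sample_key)
        assert sorted(v.sample_key for v in survivors.variants) == sorted(expected)
        assert report.n_input >= report.n_after_filter1 >= report.n_after_filter2

    def test_containment_and_monotonicity_on_randomized_variants(self):
        """Filter-2 survivors within Filter-1 survivors within input, and
        raising min_votes only shrinks the survivor set (1000 variants)."""
        import numpy as np

        rng = np.random.default_rng(7)
        samples = [f"S{i:02d}" for i in range(1, 41)]
        regions = sorted(("exonic", "splicing", "intronic", "utr"))
        classes = sorted(("nonsynonymous", "synonymous", "stopgain", "other"))
        variants = []
        for i in range(1000):
            q = SiteQuality(
                depth=int(rng.integers(0, 60)),
                nra_fraction=float(rng.uniform(0, 1)),
                mqv_ref=float(rng.uniform(0, 40)),
                mqv_alt=float(rng.uniform(0, 40)),
            )
            variants.append(_variant(
                sample_id=samples[int(rng.integers(40))],
                pos=1000 + i,
                region_class=regions[int(rng.integers(4))],
                function_class=classes[int(rng.integers(4))],
                pop_af=None if rng.random() < 0.5 else float(rng.uniform(0, 0.2)),
                quality=q,
            ))
        table = CohortCallTable(variants=variants, samples=samples)
        surv3, report, frame = run_cascade(table, FilterConfig(min_votes=3))
        surv4, _, _ = run_cascade(table, FilterConfig(min_votes=4))
        keys3 = {v.sample_key for v in surv3.variants}
        keys4 = {v.sample_key for v in surv4.variants}
        f1_keys = {
            (r.sample, r.chrom, r.pos, r.ref, r.alt)
            for r in frame[frame["filter1_pass"]].itertuples(index=False)
        }
        all_keys = {v.sample_key for v in table.variants}
        assert keys3 <= f1_keys <= all_keys
        assert keys4 <= keys3


class TestImpliedFpRate:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(219, 77, 65), (100, 100, 0), (10, 0, 100), (3, 1, 67)],
    )
    def test_values(self, before, after, expected):
        assert implied_fp_rate(before, after) == expected

    def test_zero_input_is_an_error(self):
        with pytest.raises(ValueError):
            implied_fp_rate(0, 0)
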