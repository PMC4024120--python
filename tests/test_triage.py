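"""Zygosity bands, pathogenicity criteria, per-sample diagnosis roll-up."""

import pytest
from hypothesis import given, settings, strategies as st

from lsdpanel.triage import (
    FamilyGenotypes,
    assess_pathogenicity,
    classify_zygosity,
    diagnose_sample,
)
from lsdpanel.variants import AnnotatedVariant, CohortCallTable, SiteQuality


def _q(nra, depth=100):
    return SiteQuality(depth=depth, nra_fraction=nra, mqv_ref=30.0, mqv_alt=29.0)


def _variant(pos=101, sample="S01", **kw):
    defaults = dict(
        sample_id=sample, caller_id="caller_a", chrom="chr1", pos=pos,
        ref="A", alt="T", gene="GLB1", region_class="exonic",
        function_class="nonsynonymous", pop_af=None, quality=_q(0.45),
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestZygosity:
    @pytest.mark.parametrize(
        "f,state",
        [
            (0.40, "heterozygous"),
            (0.30, "heterozygous"),
            (0.50, "heterozygous"),
            (0.85, "homozygous"),
            (0.70, "homozygous"),
            (1.00, "homozygous"),
            (0.60, "ambiguous"),
            (0.10, "low_fraction"),
            (0.29, "low_fraction"),
        ],
    )
    def test_band_assignment(self, f, state):
        assert classify_zygosity(_q(f)).state == state

    def test_hemizygous_on_x_in_male(self):
        call = classify_zygosity(_q(0.95), target_is_x=True, sample_sex="male")
        assert call.state == "hemizygous"

    def test_x_target_female_stays_homozygous(self):
        call = classify_zygosity(_q(0.95), target_is_x=True, sample_sex="female")
        assert call.state == "homozygous"

    def test_missing_fraction_is_an_error(self):
        with pytest.raises(ValueError):
            classify_zygosity(SiteQuality(depth=50))

    @settings(max_examples=300, derandomize=True)
    @given(f=st.floats(0, 1, allow_nan=False))
    def test_bands_partition_unit_interval(self, f):
        state = classify_zygosity(_q(f)).state
        assert state in {"heterozygous", "homozygous", "ambiguous", "low_fraction"}


def _cohort(variants, n_samples=30):
    samples = sorted({v.sample_id for v in variants} |
                     {f"X{i:02d}" for i in range(n_samples)})
    return CohortCallTable(variants=variants, samples=samples)


class TestPathogenicity:
    def test_all_criteria_met_is_likely_pathogenic(self):
        v = _variant(function_class="stopgain")
        second = _variant(pos=222)
        cohort = _cohort([v, second])
        family = FamilyGenotypes(entries={
            v.sample_key: ("present_het", "absent"),
            second.sample_key: ("absent", "present_het"),
        })
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        a = assess_pathogenicity(v, [v, second], cohort, family=family, zygosity=zyg)
        assert a.c1_truncating_or_splicing and a.c2_second_allele
        assert a.c3_cosegregation and a.c4_absent_elsewhere and a.c5_rare
        assert a.tier == "likely_pathogenic"

    def test_common_lone_missense_is_likely_benign(self):
        carriers = [_variant(sample=f"S{i:02d}", pop_af=0.2) for i in range(1, 11)]
        v = carriers[0]
        cohort = _cohort(carriers)
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        a = assess_pathogenicity(v, [v], cohort, zygosity=zyg)
        assert not (a.c2_second_allele or a.c4_absent_elsewhere or a.c5_rare)
        assert a.tier == "likely_benign"

    def test_synonymous_flagged_for_review_not_pathogenic(self):
        v = _variant(function_class="synonymous")
        cohort = _cohort([v])
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        a = assess_pathogenicity(v, [v], cohort, zygosity=zyg)
        assert not a.c1_truncating_or_splicing
        assert "c6" not in a.evaluable
        assert a.review_flag

    def test_missense_majority_prediction_rule(self):
        v = _variant()
        cohort = _cohort([v])
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        dele = assess_pathogenicity(
            v, [v], cohort, zygosity=zyg,
            predictions={v.site_key: ["deleterious", "deleterious", "benign"]},
        )
        ben = assess_pathogenicity(
            v, [v], cohort, zygosity=zyg,
            predictions={v.site_key: ["benign", "benign", "deleterious"]},
        )
        assert dele.c6_missense_predicted and not ben.c6_missense_predicted

    def test_homozygous_state_counts_as_second_allele(self):
        v = _variant(quality=_q(0.9))
        cohort = _cohort([v])
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        a = assess_pathogenicity(v, [v], cohort, zygosity=zyg)
        assert a.c2_second_allele

    def test_monotone_in_criteria(self):
        """Adding a satisfied criterion never lowers the tier."""
        tiers = {"likely_benign": 0, "uncertain": 1, "likely_pathogenic": 2}
        v = _variant(function_class="stopgain")
        cohort_unique = _cohort([v])
        extra = _variant(sample="S09", pos=101)
        cohort_shared = _cohort([_variant(), extra])
        zyg = classify_zygosity(v.quality, key=v.sample_key)
        weaker = assess_pathogenicity(v, [v], cohort_shared, zygosity=zyg)
        stronger = assess_pathogenicity(v, [v], cohort_unique, zygosity=zyg)
        assert tiers[stronger.tier] >= tiers[weaker.tier]


class TestDiagnoseSample:
    def _assessed(self, variants, cohort=None, predictions=None):
        cohort = cohort or _cohort(variants)
        out = []
        for v in variants:
            zyg = classify_zygosity(v.quality, key=v.sample_key)
            same_gene = [o for o in variants
                         if o.sample_id == v.sample_id and o.gene == v.gene]
            a = assess_pathogenicity(v, same_gene, cohort,
                                     predictions=predictions, zygosity=zyg)
            out.append((v, a, zyg))
        return out

    def test_two_het_pathogenic_in_one_gene_diagnosed(self):
        vs = [
            _variant(pos=101, function_class="stopgain"),
            _variant(pos=222, function_class="frameshift_indel", ref="AT", alt="A"),
        ]
        rec = diagnose_sample("S01", self._assessed(vs))
        assert rec.status == "diagnosed" and rec.gene == "GLB1"
        assert len(rec.supporting) == 2

    def test_single_het_pathogenic_is_carrier(self):
        vs = [_variant(function_class="stopgain")]
        rec = diagnose_sample("S01", self._assessed(vs))
        assert rec.status == "carrier" and rec.gene == "GLB1"

    def test_homozygous_pathogenic_is_diagnosed(self):
        vs = [_variant(function_class="stopgain", quality=_q(0.9))]
        rec = diagnose_sample("S01", self._assessed(vs))
        assert rec.status == "diagnosed"

    def test_no_qualifying_variants_undiagnosed(self):
        vs = [_variant(pop_af=0.3, function_class="synonymous")]
        rec = diagnose_sample("S01", self._assessed(vs))
        assert rec.status == "undiagnosed" and rec.gene is None

    def test_order_invariance(self):
        vs = [
            _variant(pos=101, function_class="stopgain"),
            _variant(pos=222, gene="CLN3", function_class="stopgain"),
            _variant(pos=333, function_class="frameshift_indel", ref="GT", alt="G"),
        ]
        a = self._assessed(vs)
        r1 = diagnose_sample("S01", a)
        r2 = diagnose_sample("S01", list(reversed(a)))
        assert (r1.status, r1.gene) == (r2.status, r2.gene)
        assert sorted(r1.supporting) == sorted(r2.supporting)

    def test_proven_cis_pair_demoted_to_carrier(self):
        vs = [
            _variant(pos=101, function_class="stopgain"),
            _variant(pos=222, function_class="stopgain"),
        ]
        family = FamilyGenotypes(entries={
            vs[0].sample_key: ("present_het", "absent"),
            vs[1].sample_key: ("present_het", "absent"),
        })
        rec = diagnose_sample("S01", self._assessed(vs), family=family)
        assert rec.status == "carrier"

    def test_trans_pair_stays_diagnosed(self):
        vs = [
            _variant(pos=101, function_class="stopgain"),
            _variant(pos=222, function_class="stopgain"),
        ]
        family = FamilyGenotypes(entries={
            vs[0].sample_key: ("present_het", "absent"),
            vs[1].sample_key: ("absent", "present_het"),
        })
        rec = diagnose_sample("S01", self._assessed(vs), family=family)
        assert rec.status == "diagnosed"

    def test_hemizygous_counts_two_under_x_linked(self):
        v = _variant(gene="IDS", function_class="stopgain", quality=_q(0.95))
        zyg = classify_zygosity(v.quality, target_is_x=True, sample_sex="male",
                                key=v.sample_key)
        a = assess_pathogenicity(v, [v], _cohort([v]), zygosity=zyg)
        rec = diagnose_sample("S01", [(v, a, zyg)], inheritance={"IDS": "XL"})
        assert rec.status == "diagnosed"
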