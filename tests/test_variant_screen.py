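"""Filter cascade, HGVS-type classification, consensus and co-segregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poromech.datamodel import (
    DELETERIOUS_BY_TYPE,
    Pedigree,
    PedigreeMember,
    VariantRecord,
    VariantType,
)
from poromech.fixtures import spectrum_mutations
from oracle_helpers import cascade_oracle as _cascade_oracle
from oracle_helpers import random_variants as _random_variants
from poromech.variant_screen import (
    ClassificationError,
    FilterConfig,
    classify_mutation_type,
    consensus_read_pair,
    cosegregation_check,
    is_benign_polymorphism,
    is_predicted_deleterious,
    screen_cascade,
    summarize_mutation_spectrum,
)


class TestConsensusReadPair:
    def test_identical_reads_are_idempotent(self):
        bases, quals = consensus_read_pair("ACGT", [30, 31, 32, 33],
                                           "ACGT", [20, 35, 10, 33])
        assert bases == "ACGT"
        assert quals == [30, 35, 32, 33]

    def test_large_quality_gap_takes_higher_base(self):
        bases, quals = consensus_read_pair("A", [35], "C", [12])
        assert bases == "A" and quals == [35]

    def test_small_quality_gap_masks_to_n(self):
        bases, quals = consensus_read_pair("A", [30], "C", [28])
        assert bases == "N" and quals == [2]

    def test_tails_pass_through(self):
        bases, quals = consensus_read_pair(
            "AACC", [30] * 4, "CCGG", [40] * 4, offset=2
        )
        assert bases == "AACCGG"
        assert quals == [30, 30, 40, 40, 40, 40]

    def test_disjoint_reads_error(self):
        with pytest.raises(ValueError):
            consensus_read_pair("ACGT", [30] * 4, "ACGT", [30] * 4, offset=4)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_output_base_always_from_an_input(self, data):
        n = data.draw(st.integers(2, 12))
        alphabet = "ACGT"
        r1 = "".join(data.draw(st.sampled_from(alphabet)) for _ in range(n))
        r2 = "".join(data.draw(st.sampled_from(alphabet)) for _ in range(n))
        q1 = [data.draw(st.integers(2, 41)) for _ in range(n)]
        q2 = [data.draw(st.integers(2, 41)) for _ in range(n)]
        bases, _ = consensus_read_pair(r1, q1, r2, q2)
        for i, b in enumerate(bases):
            assert b in (r1[i], r2[i], "N")


class TestClassifyMutationType:
    @pytest.mark.parametrize(
        "cdna, protein, large, expected",
        [
            ("c.371+2T>A", None, False, VariantType.splicing),
            ("c.684+1G>A", None, False, VariantType.splicing),
            ("c.746T>C", "p.Phe249Ser", False, VariantType.missense),
            ("c.302C>G", "p.Pro101Arg", False, VariantType.missense),
            ("c.395delT", "p.Leu132ArgfsTer26", False,
             VariantType.frameshift_indel),
            ("c.395delT", None, False, VariantType.frameshift_indel),
            ("c.2T>C", "p.Met1?", False, VariantType.start_codon),
            ("c.1A>G", None, False, VariantType.start_codon),
            ("c.412C>T", "p.Arg138Ter", False, VariantType.nonsense),
            ("c.100_102del", None, False, VariantType.inframe_indel),
            ("c.810dupC", None, False, VariantType.frameshift_indel),
            ("c.700_701insT", None, False, VariantType.frameshift_indel),
            ("c.100_105delinsGGG", None, False, VariantType.inframe_indel),
            ("c.100_105delinsGG", None, False, VariantType.frameshift_indel),
            ("c.300G>A", "p.=", False, VariantType.synonymous),
            ("c.300G>A", "p.Lys100Lys", False, VariantType.synonymous),
            ("c.(?_-1)_(283+1_284-1)del", None, True,
             VariantType.large_deletion),
            # non-canonical intronic offset is not a splice call
            ("c.100+5G>A", None, False, VariantType.other),
            ("c.300G>A", None, False, VariantType.other),
        ],
    )
    def test_classification(self, cdna, protein, large, expected):
        assert classify_mutation_type(cdna, protein, large) is expected

    def test_unparseable_raises_with_token(self):
        with pytest.raises(ClassificationError, match="c.bogus"):
            classify_mutation_type("c.bogus")

    def test_precedence_splicing_over_protein(self):
        # an intronic +2 change stays splicing even with a protein note
        assert classify_mutation_type(
            "c.371+2T>A", "p.Val124Glyfs"
        ) is VariantType.splicing


def _variant(**kw):
    defaults = dict(sample_id="S", gene="MVK", cdna_hgvs="c.746T>C",
                    protein_hgvs="p.Phe249Ser")
    defaults.update(kw)
    return VariantRecord(**defaults)


class TestFilterRules:
    def test_common_dbsnp_variant_is_benign(self):
        v = _variant(dbsnp_id="rs1", ref_maf=0.05)
        assert is_benign_polymorphism(v, FilterConfig())

    def test_maf_boundary_is_inclusive(self):
        cfg = FilterConfig()
        assert is_benign_polymorphism(_variant(dbsnp_id="rs1", ref_maf=0.01), cfg)
        assert not is_benign_polymorphism(
            _variant(dbsnp_id="rs1", ref_maf=0.009), cfg
        )

    def test_novel_variant_not_benign(self):
        assert not is_benign_polymorphism(_variant(), FilterConfig())

    def test_dbsnp_without_maf_not_benign(self):
        assert not is_benign_polymorphism(
            _variant(dbsnp_id="rs1"), FilterConfig()
        )

    def test_score_rule_or_semantics(self):
        cfg = FilterConfig()
        assert is_predicted_deleterious(
            _variant(sift=0.01, pp2=0.2, mt=0.1), cfg
        )
        assert is_predicted_deleterious(_variant(pp2=0.9), cfg)
        assert not is_predicted_deleterious(_variant(), cfg)

    def test_all_three_boundaries_strict(self):
        v = _variant(sift=0.05, pp2=0.85, mt=0.85)
        assert not is_predicted_deleterious(v, FilterConfig())


class TestScreenCascade:
    def test_benign_snp_excluded_with_reason(self):
        v = _variant(dbsnp_id="rs1", ref_maf=0.2)
        candidates, log = screen_cascade([v], {}, FilterConfig())
        assert candidates == []
        assert log[0]["reason"] == "population frequency"

    def test_novel_deleterious_missense_retained(self):
        v = _variant(sift=0.02)
        candidates, _ = screen_cascade([v], {}, FilterConfig())
        assert candidates == [v]

    def test_matches_brute_force_oracle_on_1000_random_variants(self):
        rng = np.random.default_rng(7)
        variants, controls = _random_variants(rng, 1000)
        cfg = FilterConfig()
        got, _ = screen_cascade(
            [VariantRecord(**{**v.__dict__, "vtype": None}) for v in variants],
            controls, cfg,
        )
        expected = _cascade_oracle(variants, controls, cfg)
        assert [(v.sample_id, v.mutation_key) for v in got] == [
            (v.sample_id, v.mutation_key) for v in expected
        ]

    def test_monotone_in_maf_threshold(self):
        rng = np.random.default_rng(8)
        variants, controls = _random_variants(rng, 300)
        lo, _ = screen_cascade(list(variants), controls,
                               FilterConfig(maf_threshold=0.01))
        hi, _ = screen_cascade(list(variants), controls,
                               FilterConfig(maf_threshold=0.05))
        lo_keys = {(v.sample_id, v.mutation_key) for v in lo}
        hi_keys = {(v.sample_id, v.mutation_key) for v in hi}
        assert lo_keys <= hi_keys

    def test_lowering_score_thresholds_never_removes(self):
        rng = np.random.default_rng(9)
        variants, controls = _random_variants(rng, 300)
        strict, _ = screen_cascade(list(variants), controls, FilterConfig())
        permissive, _ = screen_cascade(
            list(variants), controls,
            FilterConfig(sift_threshold=0.5, pp2_threshold=0.5,
                         mt_threshold=0.5),
        )
        strict_keys = {(v.sample_id, v.mutation_key) for v in strict}
        permissive_keys = {(v.sample_id, v.mutation_key) for v in permissive}
        assert strict_keys <= permissive_keys


def _family(age_of_carrier=45.0, carrier_affected=True):
    members = [
        PedigreeMember("gf", "1", True),
        PedigreeMember("gm", "2", False),
        PedigreeMember("kid", "2", carrier_affected, father_id="gf",
                       mother_id="gm", age_at_exam=age_of_carrier),
    ]
    genotypes = {"c.746T>C": {"gf": True, "gm": False, "kid": True}}
    return Pedigree("FAM", members, genotypes)


class TestCosegregation:
    def test_perfect_cosegregation(self):
        ok, violators = cosegregation_check(_family(), "c.746T>C", "strict")
        assert ok and violators == []

    def test_unaffected_adult_carrier_violates_strict(self):
        ped = _family(carrier_affected=False)
        ok, violators = cosegregation_check(ped, "c.746T>C", "strict")
        assert not ok and violators == ["kid"]

    def test_young_unaffected_carrier_passes_age_aware(self):
        # a 30-year-old unaffected carrier is still within the risk window
        ped = _family(age_of_carrier=30.0, carrier_affected=False)
        ok, _ = cosegregation_check(ped, "c.746T>C", "age_aware",
                                    onset_age=30.0)
        assert ok

    def test_no_genotypes_is_error(self):
        ped = _family()
        with pytest.raises(ValueError, match="no genotyped"):
            cosegregation_check(ped, "c.999G>A")


class TestMutationSpectrum:
    def test_empty_input_counts_zero_percent_missing(self):
        df = summarize_mutation_spectrum([])
        assert (df["count"] == 0).all()
        assert df["percent"].isna().all()

    def test_study_spectrum_counts_and_nonsense_percent(self):
        records = [
            VariantRecord(
                sample_id="X", gene=g, cdna_hgvs=c, protein_hgvs=p,
                vtype=classify_mutation_type(c, p, large_deletion=ld),
            )
            for g, c, p, ld in spectrum_mutations()
        ]
        df = summarize_mutation_spectrum(records).set_index("vtype")
        assert df["count"].sum() == 51
        assert df.loc["nonsense", "count"] == 5
        assert df.loc["nonsense", "percent"] == 10

    def test_counts_partition_distinct_mutations(self):
        records = [
            _variant(cdna_hgvs="c.746T>C"),
            _variant(sample_id="S2", cdna_hgvs="c.746T>C"),  # same mutation
            _variant(cdna_hgvs="c.412C>T", protein_hgvs="p.Arg138Ter"),
        ]
        df = summarize_mutation_spectrum(records)
        assert df["count"].sum() == 2  # distinct mutations, not carriers
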