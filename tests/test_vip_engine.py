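import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genoprio.errors import ConfigError
from genoprio.io_formats import RunConfig, read_vcf
from genoprio.io_formats.records import HET, HOM_ALT, HOM_REF, MISSING
from genoprio.vip_engine import (
    ALL_CRITERIA,
    CALLS,
    IMPLEMENTED_CRITERIA,
    TrioContext,
    classify_vcf,
    combine_criteria,
    detect_de_novo,
    evaluate_record,
    eval_clinvar_criteria,
    eval_frequency_criteria,
    eval_pvs1,
    eval_structural_criteria,
    validate_trio,
)

from .acmg_oracle import oracle_call
from .conftest import make_aa, make_variant

TRIO = TrioContext("PROBAND", "FATHER", "MOTHER")


class TestPvs1:
    def test_frameshift_high_pli(self, hand_store, config):
        flag, why = eval_pvs1(
            make_variant(exonic_func="frameshift"), hand_store, config
        )
        assert flag and "pLI" in why

    def test_frameshift_low_pli(self, hand_store, config):
        flag, _ = eval_pvs1(
            make_variant(gene="LOWPLI", exonic_func="frameshift"), hand_store, config
        )
        assert not flag

    def test_nonsynonymous_in_haploinsufficient_gene(self, hand_store, config):
        flag, _ = eval_pvs1(
            make_variant(gene="HIGENE", exonic_func="nonsynonymous"),
            hand_store, config,
        )
        assert not flag

    def test_haploinsufficiency_without_pli(self, hand_store, config):
        flag, why = eval_pvs1(
            make_variant(gene="HIGENE", exonic_func="stopgain"), hand_store, config
        )
        assert flag and "haploinsufficient" in why

    def test_splicing_counts_as_null(self, hand_store, config):
        flag, _ = eval_pvs1(
            make_variant(func_class="splicing", exonic_func=None), hand_store, config
        )
        assert flag

    def test_missing_constraint_is_note_not_error(self, hand_store, config):
        flag, note = eval_pvs1(
            make_variant(gene="NOCONSTRAINT", exonic_func="frameshift"),
            hand_store, config,
        )
        assert not flag and note == "no constraint data"

    def test_pli_cutoff_configurable(self, hand_store):
        config = RunConfig(pli_cutoff=0.05)
        flag, _ = eval_pvs1(
            make_variant(gene="LOWPLI", exonic_func="frameshift"), hand_store, config
        )
        assert flag


class TestFrequencyCriteria:
    def flags(self, pop_af, config=None):
        result = eval_frequency_criteria(
            make_variant(pop_af=pop_af), config or RunConfig()
        )
        return {c for c, (flag, _) in result.items() if flag}

    def test_flt4_analogue_pm2_fails(self):
        # MAF 5e-4 against the stringent 1e-5 cutoff: not rare enough
        assert self.flags(5e-4) == set()

    def test_null_af_is_absent_from_controls(self):
        assert self.flags(None) == {"PM2"}

    def test_ba1_band(self):
        assert self.flags(0.06) == {"BA1"}

    def test_bs1_band(self):
        assert self.flags(0.02) == {"BS1"}

    def test_pm2_band(self):
        assert self.flags(1e-6) == {"PM2"}

    def test_custom_cutoff(self):
        assert self.flags(5e-4, RunConfig(pm2_maf_cutoff=1e-3)) == {"PM2"}

    @given(st.one_of(st.none(), st.floats(min_value=0, max_value=1)))
    def test_at_most_one_band_fires(self, pop_af):
        assert len(self.flags(pop_af)) <= 1


class TestClinvarCriteria:
    def flags(self, store, **kwargs):
        result = eval_clinvar_criteria(make_variant(**kwargs), store)
        return {c for c, (flag, _) in result.items() if flag}

    def test_ps1_exact_protein_match(self, hand_store):
        assert self.flags(
            hand_store, aa_change=make_aa(aa_ref="R", aa_pos=100, aa_alt="Q")
        ) == {"PS1"}

    def test_pm5_different_alt_same_residue(self, hand_store):
        assert self.flags(
            hand_store, aa_change=make_aa(aa_ref="R", aa_pos=100, aa_alt="L")
        ) == {"PM5"}

    def test_missing_aa_disables_ps1_pm5(self, hand_store):
        assert self.flags(hand_store, aa_change=None) == set()

    def test_pp5_exact_genomic_pathogenic(self, hand_store):
        # no aa_change on the variant, so only the genomic-key match fires
        assert self.flags(
            hand_store, chrom="chr1", pos=5000, ref="C", alt="T"
        ) == {"PP5"}

    def test_bp6_exact_genomic_benign(self, hand_store):
        assert self.flags(
            hand_store, chrom="chr1", pos=6000, ref="G", alt="A"
        ) == {"BP6"}

    def test_conflicting_records_neither_flag(self, hand_store):
        assert self.flags(
            hand_store, chrom="chr1", pos=7000, ref="A", alt="G"
        ) == set()

    def test_zero_star_record_ignored(self, hand_store):
        assert self.flags(
            hand_store, chrom="chr1", pos=8000, ref="T", alt="C"
        ) == set()


class TestStructuralCriteria:
    def flags(self, store, **kwargs):
        result = eval_structural_criteria(make_variant(**kwargs), store)
        return {c for c, (flag, _) in result.items() if flag}

    def test_pm1_hotspot_containment(self, hand_store):
        assert self.flags(hand_store, aa_change=make_aa(aa_pos=50)) == {"PM1"}

    def test_pm1_outside_hotspot(self, hand_store):
        assert self.flags(hand_store, aa_change=make_aa(aa_pos=310)) == set()

    def test_synonymous_bp7_only(self, hand_store):
        assert self.flags(hand_store, exonic_func="synonymous") == {"BP7"}

    def test_stoploss_pm4(self, hand_store):
        assert self.flags(hand_store, exonic_func="stoploss") == {"PM4"}

    def test_nonframeshift_in_repeat_domain_pm4_bp3(self, hand_store):
        assert self.flags(
            hand_store, exonic_func="nonframeshift", aa_change=make_aa(aa_pos=230)
        ) == {"PM4", "BP3"}

    def test_nonframeshift_outside_repeat_pm4_only(self, hand_store):
        assert self.flags(
            hand_store, exonic_func="nonframeshift", aa_change=make_aa(aa_pos=310)
        ) == {"PM4"}


GENOTYPE_SPACE = (HOM_REF, HET, HOM_ALT, MISSING)


def de_novo_oracle(child, father, mother):
    """Brute-force restatement: allele in child, both parents confidently
    reference, nothing missing."""
    if MISSING in (child, father, mother):
        return False
    return child in (HET, HOM_ALT) and father == HOM_REF and mother == HOM_REF


class TestDeNovo:
    def test_truth_table_64_combinations(self):
        for child, father, mother in itertools.product(GENOTYPE_SPACE, repeat=3):
            variant = make_variant(
                genotypes={"PROBAND": child, "FATHER": father, "MOTHER": mother}
            )
            assert detect_de_novo(variant, TRIO) == de_novo_oracle(
                child, father, mother
            ), (child, father, mother)

    def test_classic_de_novo(self):
        variant = make_variant(
            genotypes={"PROBAND": HET, "FATHER": HOM_REF, "MOTHER": HOM_REF}
        )
        assert detect_de_novo(variant, TRIO)

    def test_missing_father_vetoes(self):
        variant = make_variant(
            genotypes={"PROBAND": HET, "FATHER": MISSING, "MOTHER": HOM_REF}
        )
        assert not detect_de_novo(variant, TRIO)

    def test_hom_ref_child_not_de_novo(self):
        variant = make_variant(
            genotypes={"PROBAND": HOM_REF, "FATHER": HOM_REF, "MOTHER": HOM_REF}
        )
        assert not detect_de_novo(variant, TRIO)

    def test_absent_trio_sample_is_config_error(self):
        with pytest.raises(ConfigError, match="absent"):
            validate_trio(TRIO, ["PROBAND", "FATHER"])


class TestCombineCriteria:
    def make_flags(self, *true):
        return {c: c in true for c in ALL_CRITERIA}

    def test_pvs1_alone_is_uncertain(self):
        # the frameshift-that-failed-PM2 scenario: a lone PVS1 is a VUS
        assert combine_criteria(self.make_flags("PVS1")) == "uncertain"

    def test_pvs1_plus_ps2_pathogenic(self):
        assert combine_criteria(self.make_flags("PVS1", "PS2")) == "pathogenic"

    def test_pvs1_plus_pm2_likely_pathogenic(self):
        assert (
            combine_criteria(self.make_flags("PVS1", "PM2")) == "likely_pathogenic"
        )

    def test_ba1_alone_benign(self):
        assert combine_criteria(self.make_flags("BA1")) == "benign"

    def test_bs1_bp7_likely_benign(self):
        assert combine_criteria(self.make_flags("BS1", "BP7")) == "likely_benign"

    def test_conflict_resolves_to_uncertain(self):
        assert combine_criteria(self.make_flags("PVS1", "PS1", "BA1")) == "uncertain"

    def test_no_flags_uncertain(self):
        assert combine_criteria(self.make_flags()) == "uncertain"

    def test_exhaustive_oracle_equivalence_implemented(self):
        """Full truth table over the 13 implemented criteria."""
        for bits in itertools.product([False, True], repeat=len(IMPLEMENTED_CRITERIA)):
            flags = dict(zip(IMPLEMENTED_CRITERIA, bits))
            assert combine_criteria(flags) == oracle_call(flags), flags

    def test_exactly_five_labels_reachable(self):
        seen = set()
        for bits in itertools.product([False, True], repeat=len(IMPLEMENTED_CRITERIA)):
            seen.add(combine_criteria(dict(zip(IMPLEMENTED_CRITERIA, bits))))
        assert seen == set(CALLS)

    def test_random_oracle_equivalence_all_28(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            bits = rng.random(len(ALL_CRITERIA)) < 0.25
            flags = dict(zip(ALL_CRITERIA, map(bool, bits)))
            assert combine_criteria(flags) == oracle_call(flags), flags

    @given(
        flags=st.sets(st.sampled_from(ALL_CRITERIA)),
        extra=st.sampled_from(
            ("PVS1", "PS1", "PS2", "PS3", "PS4", "PM1", "PM2", "PM3", "PM4",
             "PM5", "PM6", "PP1", "PP2", "PP3", "PP4", "PP5")
        ),
    )
    @settings(max_examples=300)
    def test_pathogenic_side_monotone(self, flags, extra):
        ordinal = {c: i for i, c in enumerate(CALLS)}
        before = combine_criteria({c: c in flags for c in ALL_CRITERIA})
        after = combine_criteria({c: c in (flags | {extra}) for c in ALL_CRITERIA})
        assert ordinal[after] >= ordinal[before]

    @given(
        flags=st.sets(st.sampled_from(ALL_CRITERIA)),
        extra=st.sampled_from(
            ("BA1", "BS1", "BS2", "BS3", "BS4", "BP1", "BP2", "BP3", "BP4",
             "BP5", "BP6", "BP7")
        ),
    )
    @settings(max_examples=300)
    def test_benign_side_monotone(self, flags, extra):
        ordinal = {c: i for i, c in enumerate(CALLS)}
        before = combine_criteria({c: c in flags for c in ALL_CRITERIA})
        after = combine_criteria({c: c in (flags | {extra}) for c in ALL_CRITERIA})
        assert ordinal[after] <= ordinal[before]


class TestEvaluateRecord:
    def test_flt4_analogue_end_to_end(self, hand_store, config):
        """Frameshift in a constrained gene: common → VUS, absent → LP."""
        common = make_variant(exonic_func="frameshift", pop_af=5e-4)
        assessment = evaluate_record(common, hand_store, config)
        assert assessment.flags["PVS1"] and not assessment.flags["PM2"]
        assert assessment.call == "uncertain"

        absent = make_variant(exonic_func="frameshift", pop_af=None)
        assessment = evaluate_record(absent, hand_store, config)
        assert assessment.flags["PM2"]
        assert assessment.call == "likely_pathogenic"

    def test_every_true_flag_has_justification(self, hand_store, config):
        variant = make_variant(
            exonic_func="frameshift",
            pop_af=None,
            aa_change=make_aa(aa_ref="R", aa_pos=100, aa_alt="Q"),
            genotypes={"PROBAND": HET, "FATHER": HOM_REF, "MOTHER": HOM_REF},
        )
        assessment = evaluate_record(variant, hand_store, config, trio=TRIO)
        for criterion in assessment.true_criteria():
            assert assessment.justifications[criterion], criterion

    def test_no_trio_de_novo_is_null(self, hand_store, config):
        assessment = evaluate_record(make_variant(), hand_store, config)
        assert assessment.de_novo is None
        assert assessment.flags["PS2"] is False

    def test_ps2_configurable_off(self, hand_store):
        config = RunConfig(ps2_from_de_novo=False)
        variant = make_variant(
            genotypes={"PROBAND": HET, "FATHER": HOM_REF, "MOTHER": HOM_REF}
        )
        assessment = evaluate_record(variant, hand_store, config, trio=TRIO)
        assert assessment.de_novo is True
        assert assessment.flags["PS2"] is False

    def test_external_flags_accepted_by_combiner(self, hand_store, config):
        variant = make_variant(exonic_func="frameshift", pop_af=None)
        assessment = evaluate_record(
            variant, hand_store, config, external_flags={"PS3": True}
        )
        assert assessment.flags["PS3"]
        assert assessment.call == "pathogenic"  # PVS1 + PS3

    def test_call_consistent_with_combiner(self, hand_store, config):
        variant = make_variant(exonic_func="synonymous", pop_af=0.02)
        assessment = evaluate_record(variant, hand_store, config)
        assert assessment.call == combine_criteria(assessment.flags)
        assert assessment.call == "likely_benign"  # BS1 + BP7


class TestClassifyVcf:
    @pytest.fixture()
    def trio_records(self):
        return [
            make_variant(  # de novo P/LP
                pos=100, exonic_func="frameshift", pop_af=None,
                genotypes={"PROBAND": HET, "FATHER": HOM_REF, "MOTHER": HOM_REF},
            ),
            make_variant(  # inherited benign
                pos=200, exonic_func="synonymous", pop_af=0.3,
                genotypes={"PROBAND": HET, "FATHER": HET, "MOTHER": HOM_REF},
            ),
            make_variant(  # VUS
                pos=300, exonic_func="nonsynonymous", pop_af=1e-3,
                genotypes={"PROBAND": HOM_REF, "FATHER": HET, "MOTHER": HOM_REF},
            ),
        ]

    def test_three_files_with_trio(self, hand_store, config, tmp_path, trio_records):
        _, files = classify_vcf(
            trio_records, hand_store, config, trio=TRIO, out_prefix=tmp_path / "x"
        )
        assert set(files) == {"denovo", "plp", "all"}
        assert all(path.exists() for path in files.values())

    def test_subset_relations(self, hand_store, config, tmp_path, trio_records):
        _, files = classify_vcf(
            trio_records, hand_store, config, trio=TRIO, out_prefix=tmp_path / "x"
        )
        keys = {
            kind: {r.key for r in read_vcf(path)} for kind, path in files.items()
        }
        assert keys["denovo"] <= keys["all"]
        assert keys["plp"] <= keys["all"]
        assert len(keys["all"]) == 3

    def test_plp_file_holds_only_plp(self, hand_store, config, tmp_path, trio_records):
        assessments, files = classify_vcf(
            trio_records, hand_store, config, trio=TRIO, out_prefix=tmp_path / "x"
        )
        by_key = {
            rec.key: a for rec, a in zip(trio_records, assessments)
        }
        for record in read_vcf(files["plp"]):
            assert by_key[record.key].call in ("pathogenic", "likely_pathogenic")

    def test_no_trio_two_files(self, hand_store, config, tmp_path, trio_records):
        _, files = classify_vcf(
            trio_records, hand_store, config, out_prefix=tmp_path / "x"
        )
        assert set(files) == {"plp", "all"}

    def test_info_annotations_written(self, hand_store, config, tmp_path, trio_records):
        _, files = classify_vcf(
            trio_records, hand_store, config, trio=TRIO, out_prefix=tmp_path / "x"
        )
        text = files["all"].read_text()
        assert "ACMG_CALL=" in text
        assert "ACMG_CRITERIA=" in text
        assert "ACMG_JUSTIFICATION=" in text
        assert "DENOVO" in text
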