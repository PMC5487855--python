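from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exofam.filtering import (
    FilterConfig,
    FunnelReport,
    effect_filter,
    find_mononucleotide_runs,
    find_tandem_repeats,
    frequency_filter,
    homopolymer_indel_filter,
    qc_filter,
    repeat_adjacent,
    run_filter_cascade,
)
from exofam.io_formats.models import (
    AnnotationRecord,
    Effect,
    FormatError,
    ToolCall,
)
from exofam.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_homopolymer_contexts,
    trio_pedigree,
)

from _oracles import scan_adjacent_repeat
from conftest import make_variant

CALLS = [ToolCall.TOLERATED] * 10


def ann(variant, effect=Effect.EXONIC_NONSYNONYMOUS, **freqs):
    return AnnotationRecord(
        variant_key=variant.key,
        gene="G",
        effect=effect,
        db_frequencies={k: v for k, v in freqs.items()},
        tool_calls=list(CALLS),
    )


class TestQcFilter:
    def test_strand_bias_removed(self, trio):
        v = make_variant(trio, qc_flags=frozenset({"strand_bias"}))
        assert qc_filter([v]) == []

    def test_clean_variant_retained(self, trio):
        v = make_variant(trio)
        assert qc_filter([v]) == [v]

    def test_all_flagged_input_empties(self, trio):
        flags = [
            "low_base_quality",
            "low_mapping_quality",
            "strand_bias",
            "aberrant_read_position",
            "ref_alt_quality_discrepancy",
        ]
        vs = [
            make_variant(trio, pos=1000 + i, qc_flags=frozenset({f}))
            for i, f in enumerate(flags)
        ]
        assert qc_filter(vs) == []


class TestHomopolymerFilter:
    W = FilterConfig().flank_window

    def _ctx(self, right_of_deleted: str) -> str:
        # deletion removes the base at index W+1; pad with a repeat-free tail
        left = "GACTGCATGC"[: self.W]
        tail = "GTCAGCATGGACTT"
        s = left + "CG" + right_of_deleted + tail
        return s[: 2 * self.W + 1]

    def test_deletion_next_to_six_run_excluded(self, trio):
        v = make_variant(trio, ref="CG", alt="C", pos=500)
        ctx = self._ctx("AAAAAA")
        assert homopolymer_indel_filter([v], {v.key: ctx}) == []

    def test_deletion_next_to_five_run_retained(self, trio):
        v = make_variant(trio, ref="CG", alt="C", pos=500)
        ctx = self._ctx("AAAAA")
        assert homopolymer_indel_filter([v], {v.key: ctx}) == [v]

    def test_snv_inside_run_retained(self, trio):
        v = make_variant(trio, ref="A", alt="G", pos=500)
        # SNVs pass without consulting the provider at all
        assert homopolymer_indel_filter([v], None) == [v]

    def test_dinucleotide_repeat_excluded(self, trio):
        v = make_variant(trio, ref="CG", alt="C", pos=500)
        ctx = self._ctx("ATATATAT")
        assert homopolymer_indel_filter([v], {v.key: ctx}) == []

    def test_short_context_errors(self, trio):
        v = make_variant(trio, ref="CG", alt="C", pos=500)
        with pytest.raises(FormatError, match="flank_window"):
            homopolymer_indel_filter([v], {v.key: "ACGT"})

    def test_missing_context_errors(self, trio):
        v = make_variant(trio, ref="CG", alt="C", pos=500)
        with pytest.raises(FormatError, match="context"):
            homopolymer_indel_filter([v], {})

    def test_generated_labels_match_brute_force_oracle(self):
        config = FilterConfig()
        w = config.flank_window
        for case in generate_homopolymer_contexts(60, seed=5):
            oracle = scan_adjacent_repeat(
                case.context,
                w + 1,
                w + 2,
                min_run=config.homopolymer_min_run,
                min_copies=config.repeat_min_copies,
                max_unit=config.repeat_max_unit,
                tol=config.adjacency_tol,
            )
            detected = repeat_adjacent(case.context, w + 1, 1, config)
            assert detected == oracle
            assert detected == case.expected_flag, case

    @given(st.text(alphabet="ACGT", min_size=21, max_size=21))
    @settings(max_examples=200, deadline=None)
    def test_detector_matches_oracle_on_random_contexts(self, ctx):
        config = FilterConfig()
        w = config.flank_window
        assert repeat_adjacent(ctx, w + 1, 1, config) == scan_adjacent_repeat(
            ctx, w + 1, w + 2, tol=config.adjacency_tol
        )


class TestScanners:
    def test_runs(self):
        assert find_mononucleotide_runs("GGAAAAAATT", 6) == [(2, 8)]
        assert find_mononucleotide_runs("GGAAAAATT", 6) == []

    def test_tandem(self):
        # (AT)x4 at offset 2
        reps = find_tandem_repeats("GCATATATATGC")
        assert (2, 10) in reps
        assert find_tandem_repeats("GCATATGC") == []  # only 2 copies

    def test_mono_unit_excluded_from_tandem_rule(self):
        assert find_tandem_repeats("AAAAAA") == []


class TestFrequencyFilter:
    def test_printed_rare_variant_passes_monogenic(self, trio):
        v = make_variant(trio)
        a = ann(v, exac=0.0005, esp=0.0006, kg=None)
        assert frequency_filter([v], [a]) == [v]

    def test_two_percent_fails_monogenic_passes_polygenic(self, trio):
        v = make_variant(trio)
        a = ann(v, exac=0.02)
        assert frequency_filter([v], [a], FilterConfig(mode="monogenic")) == []
        assert frequency_filter(
            [v], [a], FilterConfig(mode="polygenic_pharmacologic")
        ) == [v]

    def test_absent_from_all_databases_passes(self, trio):
        v = make_variant(trio)
        a = ann(v, exac=None, esp=None, kg=None)
        assert frequency_filter([v], [a]) == [v]

    def test_exactly_at_threshold_passes(self, trio):
        v = make_variant(trio)
        a = ann(v, exac=0.01)
        assert frequency_filter([v], [a]) == [v]

    @given(
        st.lists(
            st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, freqs):
        trio = trio_pedigree()
        v = make_variant(trio)
        a = ann(v, exac=freqs[0], esp=freqs[1], kg=freqs[2])
        at_1pct = frequency_filter([v], [a], FilterConfig(mode="monogenic"))
        at_10pct = frequency_filter(
            [v], [a], FilterConfig(mode="polygenic_pharmacologic")
        )
        assert set(v.key for v in at_1pct) <= set(v.key for v in at_10pct)


class TestEffectFilter:
    @pytest.mark.parametrize(
        "effect,kept",
        [
            (Effect.EXONIC_NONSYNONYMOUS, True),
            (Effect.EXONIC_SYNONYMOUS, False),
            (Effect.SPLICING, False),
            (Effect.OTHER, False),
        ],
    )
    def test_default_retains_amino_acid_changing_only(self, trio, effect, kept):
        v = make_variant(trio)
        result = effect_filter([v], [ann(v, effect=effect)])
        assert (result == [v]) is kept

    def test_splicing_configurable(self, trio):
        v = make_variant(trio)
        cfg = FilterConfig(
            retained_effects=frozenset(
                {Effect.EXONIC_NONSYNONYMOUS, Effect.SPLICING}
            )
        )
        assert effect_filter([v], [ann(v, effect=Effect.SPLICING)], cfg) == [v]


class TestCascade:
    def test_planted_variant_survives_all_stages(self):
        cohort = generate_cohort(CohortSpec(n_background_variants=200, seed=2))
        survivors, _ = run_filter_cascade(
            cohort.variants, cohort.annotations, FilterConfig(), cohort.contexts
        )
        assert cohort.truth.variant_key in {v.key for v in survivors}

    def test_cascade_equals_sequential_stage_application(self):
        cohort = generate_cohort(CohortSpec(n_background_variants=200, seed=9))
        config = FilterConfig()
        survivors, report = run_filter_cascade(
            cohort.variants, cohort.annotations, config, cohort.contexts
        )
        # oracle: apply the four operators independently in order
        manual = qc_filter(cohort.variants, config)
        manual = homopolymer_indel_filter(manual, cohort.contexts, config)
        manual = frequency_filter(manual, cohort.annotations, config)
        manual = effect_filter(manual, cohort.annotations, config)
        assert [v.key for v in survivors] == [v.key for v in manual]

    def test_funnel_monotone_and_chained(self):
        cohort = generate_cohort(CohortSpec(n_background_variants=150, seed=4))
        _, report = run_filter_cascade(
            cohort.variants, cohort.annotations, FilterConfig(), cohort.contexts
        )
        for prev, cur in zip(report.stages, report.stages[1:]):
            assert cur.variants_in == prev.variants_out
        for s in report.stages:
            assert s.variants_out <= s.variants_in

    def test_cascade_output_is_stage_intersection(self):
        cohort = generate_cohort(CohortSpec(n_background_variants=150, seed=6))
        config = FilterConfig()
        survivors, _ = run_filter_cascade(
            cohort.variants, cohort.annotations, config, cohort.contexts
        )
        passing = (
            {v.key for v in qc_filter(cohort.variants, config)}
            & {
                v.key
                for v in homopolymer_indel_filter(
                    cohort.variants, cohort.contexts, config
                )
            }
            & {
                v.key
                for v in frequency_filter(
                    cohort.variants, cohort.annotations, config
                )
            }
            & {
                v.key
                for v in effect_filter(
                    cohort.variants, cohort.annotations, config
                )
            }
        )
        assert {v.key for v in survivors} == passing

    def test_funnel_report_rejects_growth(self):
        report = FunnelReport()
        report.add_stage("a", 10, 5)
        with pytest.raises(ValueError, match="chain"):
            report.add_stage("b", 7, 3)
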