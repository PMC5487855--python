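from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from exofam.assays import (
    calcium_from_standard_curve,
    compare_groups,
    delta_delta_ct,
    normalize_luciferase,
    pool_size_linearity,
    sem,
)
from exofam.io_formats.models import FormatError
from exofam.synthetic import AssaySpec, generate_assay_table


def qpcr_table(control_dct: float, treated_dct: float) -> pd.DataFrame:
    rows = []
    for group, dct in (("control", control_dct), ("treated", treated_dct)):
        for rep in (1, 2, 3):
            rows.append(("qpcr", group, rep, "reference", 15.0))
            rows.append(("qpcr", group, rep, "target", 15.0 + dct))
    return pd.DataFrame(
        rows, columns=["assay", "group", "replicate", "target", "value"]
    )


class TestDeltaDeltaCt:
    def test_knockdown_scale(self):
        # ddCt of 0.862 corresponds to fold 2^-0.862 ~ 0.55 (45% knockdown)
        table = qpcr_table(4.0, 4.862)
        results = {r.group: r for r in delta_delta_ct(table, "reference", "control")}
        expected_fold = 2.0 ** (-0.862)
        assert results["treated"].fold_change == pytest.approx(expected_fold)
        assert results["treated"].percent_knockdown == pytest.approx(
            (1 - expected_fold) * 100
        )
        assert round(results["treated"].percent_knockdown) == 45

    def test_zero_ddct_gives_fold_one(self):
        results = {r.group: r for r in delta_delta_ct(qpcr_table(2.0, 2.0), "reference", "control")}
        assert results["treated"].fold_change == 1.0
        assert results["control"].fold_change == 1.0

    def test_minus_one_ddct_doubles(self):
        results = {r.group: r for r in delta_delta_ct(qpcr_table(3.0, 2.0), "reference", "control")}
        assert results["treated"].fold_change == pytest.approx(2.0)

    def test_control_fold_is_exactly_one(self):
        table = qpcr_table(1.3, 0.4)
        results = {r.group: r for r in delta_delta_ct(table, "reference", "control")}
        assert results["control"].fold_change == 1.0
        assert results["control"].delta_delta_ct == 0.0

    def test_missing_reference_names_group(self):
        table = qpcr_table(1.0, 2.0)
        table = table[
            ~((table["group"] == "treated") & (table["target"] == "reference"))
        ]
        with pytest.raises(FormatError, match="treated"):
            delta_delta_ct(table, "reference", "control")

    @pytest.mark.parametrize("shift", [-5.0, 1.7, 10.0])
    def test_plate_shift_invariance(self, shift):
        base = qpcr_table(4.0, 4.9)
        shifted = base.copy()
        shifted["value"] = shifted["value"] + shift
        r_base = {r.group: r for r in delta_delta_ct(base, "reference", "control")}
        r_shift = {r.group: r for r in delta_delta_ct(shifted, "reference", "control")}
        for g in r_base:
            assert r_base[g].fold_change == pytest.approx(r_shift[g].fold_change)

    def test_generator_inversion_at_zero_noise(self):
        spec = AssaySpec(
            assay="qpcr", groups=(("control", 1.0), ("treated", 0.55))
        )
        table = generate_assay_table(spec)
        results = {r.group: r for r in delta_delta_ct(table, "reference", "control")}
        assert results["treated"].fold_change == pytest.approx(0.55)


class TestLuciferase:
    def _table(self, pairs):
        rows = []
        for group, rep, firefly, renilla in pairs:
            rows.append(("luciferase", group, rep, "firefly", firefly))
            rows.append(("luciferase", group, rep, "renilla", renilla))
        return pd.DataFrame(
            rows, columns=["assay", "group", "replicate", "target", "value"]
        )

    def test_firefly_doubling_doubles_ratio(self):
        t = self._table([("a", 1, 100.0, 50.0), ("a", 2, 200.0, 50.0)])
        ratios, _ = normalize_luciferase(t)
        by_rep = dict(zip(ratios["replicate"], ratios["ratio"]))
        assert by_rep[2] == pytest.approx(2 * by_rep[1])

    def test_zero_renilla_errors(self):
        t = self._table([("a", 1, 100.0, 0.0)])
        with pytest.raises(FormatError, match="zero"):
            normalize_luciferase(t)

    def test_unpaired_well_errors(self):
        t = self._table([("a", 1, 100.0, 50.0)])
        t = t[t["target"] != "renilla"]
        with pytest.raises(FormatError, match="paired"):
            normalize_luciferase(t)

    def test_unit_effect_gives_unit_ratio_and_fold(self):
        spec = AssaySpec(
            assay="luciferase", groups=(("empty", 1.0), ("full", 1.0))
        )
        _, summaries = normalize_luciferase(generate_assay_table(spec))
        for s in summaries:
            assert s.mean_ratio == pytest.approx(1.0)
            assert s.fold_activation == pytest.approx(1.0)

    def test_generator_inversion_fold_activation(self):
        spec = AssaySpec(
            assay="luciferase", groups=(("empty", 1.0), ("over", 3.5))
        )
        _, summaries = normalize_luciferase(
            generate_assay_table(spec), control_group="empty"
        )
        by_group = {s.group: s for s in summaries}
        assert by_group["over"].fold_activation == pytest.approx(3.5)


class TestCalcium:
    STANDARDS = [(0.0, 0.05), (5.0, 0.25), (10.0, 0.45), (25.0, 1.05)]

    def test_noiseless_standards_recovered_exactly(self):
        calib, _ = calcium_from_standard_curve(self.STANDARDS, [])
        assert calib.slope == pytest.approx(0.04)
        assert calib.intercept == pytest.approx(0.05)
        assert calib.r_squared == pytest.approx(1.0)

    def test_per_embryo_division(self):
        calib, samples = calcium_from_standard_curve(
            self.STANDARDS, [("pool", 0.45)], n_embryos_per_pool=20
        )
        (s,) = samples
        assert s.pool_concentration == pytest.approx(10.0)
        assert s.per_embryo == pytest.approx(0.5)
        assert not s.extrapolated

    def test_extrapolation_flagged_and_warned(self, caplog):
        with caplog.at_level("WARNING"):
            _, samples = calcium_from_standard_curve(
                self.STANDARDS, [("hot", 9.99)]
            )
        assert samples[0].extrapolated
        assert any("outside standard range" in r.message for r in caplog.records)

    def test_doubling_standard_readings_halves_inference(self):
        # with a zero-intercept curve, scaling readings scales concentrations
        standards = [(0.0, 0.0), (5.0, 0.2), (10.0, 0.4), (25.0, 1.0)]
        doubled = [(c, 2 * y) for c, y in standards]
        _, orig = calcium_from_standard_curve(standards, [("s", 0.4)])
        _, scaled = calcium_from_standard_curve(doubled, [("s", 0.4)])
        assert scaled[0].pool_concentration == pytest.approx(
            orig[0].pool_concentration / 2
        )

    def test_too_few_standards_errors(self):
        with pytest.raises(FormatError, match="3 standard"):
            calcium_from_standard_curve(self.STANDARDS[:2], [])

    def test_pool_size_linearity(self):
        sizes = [5, 10, 20, 40]
        totals = [2.5, 5.0, 10.0, 20.0]
        fit = pool_size_linearity(sizes, totals)
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_generator_noiseless_line(self):
        spec = AssaySpec(assay="calcium", groups=(("low", 2.0), ("high", 25.0)))
        table = generate_assay_table(spec)
        std = table[table["group"] == "standard"]
        standards = [(float(t), float(v)) for t, v in zip(std["target"], std["value"])]
        calib, samples = calcium_from_standard_curve(
            standards,
            [
                (g, float(v))
                for g, v in zip(
                    table[table["group"] != "standard"]["group"],
                    table[table["group"] != "standard"]["value"],
                )
            ],
        )
        assert calib.r_squared == pytest.approx(1.0)
        for s in samples:
            expected = 2.0 if s.label == "low" else 25.0
            assert s.pool_concentration == pytest.approx(expected)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.p_value == 1.0
        assert res.stars == ""

    def test_separated_groups_significant(self):
        res = compare_groups(
            [0.0, 0.01, -0.01], [10.0, 10.01, 9.99]
        )
        assert res.p_value < 0.01
        assert res.stars == "**"

    def test_sem_matches_definition(self):
        values = [1.0, 2.0, 4.0]
        assert sem(values) == pytest.approx(
            np.std(values, ddof=1) / math.sqrt(3)
        )
        res = compare_groups(values, [1.0, 1.0, 2.0])
        assert res.sem_a == pytest.approx(sem(values))

    def test_permutation_matches_exhaustive_enumeration(self):
        a = [1.0, 2.0, 3.0]
        b = [4.0, 5.0, 9.0]
        res = compare_groups(a, b, method="permutation", n_permutations=20000, seed=0)
        # exact oracle: all C(6,3) assignments of the pooled values
        pooled = a + b
        observed = abs(np.mean(a) - np.mean(b))
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            total += 1
            if abs(np.mean(ga) - np.mean(gb)) >= observed - 1e-12:
                hits += 1
        exact = hits / total
        mc_err = 3 * math.sqrt(exact * (1 - exact) / 20000)
        assert abs(res.p_value - exact) <= mc_err + 1e-4

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [3.0, 4.0], method="bogus")


class TestEffectRecovery:
    def test_qpcr_effect_recovered_within_three_sem(self):
        estimates = []
        for seed in range(60):
            spec = AssaySpec(
                assay="qpcr",
                groups=(("control", 1.0), ("treated", 0.55)),
                noise_sd=0.05,
                seed=seed,
            )
            table = generate_assay_table(spec)
            results = {
                r.group: r for r in delta_delta_ct(table, "reference", "control")
            }
            estimates.append(results["treated"].fold_change)
        assert abs(np.mean(estimates) - 0.55) <= 3 * sem(estimates)
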