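import numpy as np
import pandas as pd
import pytest

from oxprof import panel
from oxprof.control import ControlModel, fit_control_regression, prediction_interval
from oxprof.errors import DataError
from oxprof.profiling import (
    build_profiles,
    call_decreased,
    complex_calls,
    conditional_profile,
    recovery_metrics,
    severity_stack,
    summarize_case,
)
from oxprof.synthetic import GroupSpec, simulate_cohort
from tests.conftest import make_config
from tests.test_control import table_from_xy


def _profiles_frame(records):
    """Build a minimal profiles frame from per-neuron complex flags."""
    rows = []
    for i, rec in enumerate(records):
        flags = {f"dec_complex_{c}": rec.get(c, False) for c in panel.COMPLEXES}
        rows.append(
            {
                "neuron_id": f"n{i}",
                "case_id": rec.get("case_id", "case01"),
                "group": rec.get("group", "PD"),
                "age": 70.0,
                **{f"dec_{s}": flags[f"dec_complex_{panel.complex_of(s)}"]
                   for s in panel.SUBUNITS},
                **flags,
                "n_complexes_decreased": sum(flags.values()),
            }
        )
    return pd.DataFrame(rows)


class TestCallDecreased:
    def test_on_line_is_false(self, five_point_xy):
        x, y, _ = five_point_xy
        fit = fit_control_regression(table_from_xy(x, y), "NDUFB8")
        v = np.exp(np.array([2.0]))
        i = np.exp(fit.predict(2.0))
        assert not call_decreased(fit, i, v)[0]

    def test_far_below_is_true(self, five_point_xy):
        x, y, _ = five_point_xy
        fit = fit_control_regression(table_from_xy(x, y), "NDUFB8")
        y0 = fit.predict(fit.x_mean) - 10 * fit.s_resid
        assert call_decreased(fit, np.exp(y0), np.exp(fit.x_mean))[0]

    def test_exactly_on_limit_is_not_decreased(self, five_point_xy):
        x, y, _ = five_point_xy
        fit = fit_control_regression(table_from_xy(x, y), "NDUFB8")
        lo, _ = prediction_interval(fit, 2.0, 0.80)
        assert not call_decreased(fit, np.exp(lo), np.exp(2.0))[0]

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_coverage_on_fresh_controls(self, seed):
        train, _ = simulate_cohort(
            make_config(seed, groups=[GroupSpec("control", 20, 100, 0)])
        )
        fit = fit_control_regression(train, "NDUFB8")
        rng = np.random.default_rng(seed + 7)
        x = rng.normal(5.0, 0.5, 2000)
        y = x + rng.normal(0.0, 0.25, 2000)
        frac = call_decreased(fit, np.exp(y), np.exp(x), 0.80).mean()
        assert 0.08 <= frac <= 0.12

    def test_non_positive_rejected(self, five_point_xy):
        x, y, _ = five_point_xy
        fit = fit_control_regression(table_from_xy(x, y), "NDUFB8")
        with pytest.raises(DataError):
            call_decreased(fit, np.array([0.0]), np.array([1.0]))


class TestComplexCalls:
    def test_all_false(self):
        flags = {s: False for s in panel.SUBUNITS}
        calls = complex_calls(flags)
        assert not any(calls.values())

    def test_representative_rule(self):
        # NDUFB8 true but NDUFA13 false -> complex I false
        flags = {s: False for s in panel.SUBUNITS}
        flags["NDUFB8"] = True
        assert not complex_calls(flags)["CI"]

    def test_full_deficiency_category_5(self):
        flags = {s: False for s in panel.SUBUNITS}
        for rep in panel.REPRESENTATIVE_SUBUNITS.values():
            flags[rep] = True
        calls = complex_calls(flags)
        assert sum(calls.values()) == 5

    def test_missing_representative(self):
        with pytest.raises(DataError):
            complex_calls({"NDUFB8": True})


class TestSummarizeCase:
    def test_single_flag_25pct(self):
        profiles = _profiles_frame(
            [{"CI": True}, {}, {}, {}]
        )
        summary = summarize_case(profiles)
        assert summary.loc[0, "pct_NDUFA13"] == pytest.approx(25.0)
        assert summary.loc[0, "n_neurons"] == 4

    def test_category_hand_count(self):
        profiles = _profiles_frame(
            [
                {},
                {},
                {"CI": True},
                {c: True for c in panel.COMPLEXES},
            ]
        )
        s = summarize_case(profiles).iloc[0]
        assert s["pct_category_0"] == pytest.approx(50.0)
        assert s["pct_category_1"] == pytest.approx(25.0)
        assert s["pct_category_5"] == pytest.approx(25.0)
        for k in (2, 3, 4):
            assert s[f"pct_category_{k}"] == 0.0

    def test_category_percentages_sum_to_100(self):
        cfg = make_config(
            51,
            groups=[GroupSpec("PD", 3, 30, 5,
                              deficit_fraction={"CI": 0.4, "CV": 0.3}),
                    GroupSpec("control", 5, 40, 0)],
            deficits={"CI": 1.0, "CV": 1.0},
        )
        table, _ = simulate_cohort(cfg)
        model = ControlModel.fit(table[table.group == "control"])
        profiles, _ = build_profiles(table, model)
        summary = summarize_case(profiles)
        cat_cols = [f"pct_category_{k}" for k in range(6)]
        np.testing.assert_allclose(summary[cat_cols].sum(axis=1), 100.0, atol=1e-9)

    def test_binomial_oracle_half_flagged(self):
        cfg = make_config(
            52,
            groups=[GroupSpec("PD", 1, 200, 0, deficit_fraction={"CI": 0.5}),
                    GroupSpec("control", 5, 60, 0)],
            deficits={"CI": 1.0},  # 4 * s
        )
        table, _ = simulate_cohort(cfg)
        model = ControlModel.fit(table[table.group == "control"])
        profiles, _ = build_profiles(table, model)
        s = summarize_case(profiles)
        pd_row = s.loc[s["group"] == "PD"].iloc[0]
        assert 40.0 <= pd_row["pct_NDUFA13"] <= 60.0

    def test_permutation_invariance(self):
        profiles = _profiles_frame(
            [{"CI": True}, {"CIV": True}, {}, {"CI": True, "CV": True}]
        )
        s1 = summarize_case(profiles)
        s2 = summarize_case(profiles.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            s1.sort_values("case_id").reset_index(drop=True),
            s2.sort_values("case_id").reset_index(drop=True),
        )


class TestConditionalProfile:
    def test_no_anchor_decreased_gives_empty_stratum(self):
        profiles = _profiles_frame([{}, {}, {}])
        cond = conditional_profile(profiles, "CI")
        assert (cond["stratum"] == "normal").all()

    def test_toy_enumeration(self):
        # 6 neurons: 3 CI-decreased of which 2 also CIV; 3 CI-normal of
        # which 1 CIV.
        profiles = _profiles_frame(
            [
                {"CI": True, "CIV": True},
                {"CI": True, "CIV": True},
                {"CI": True},
                {"CIV": True},
                {},
                {},
            ]
        )
        cond = conditional_profile(profiles, "CI")
        dec = cond.loc[cond["stratum"] == "decreased"].iloc[0]
        norm = cond.loc[cond["stratum"] == "normal"].iloc[0]
        assert dec["pct_CIV"] == pytest.approx(100.0 * 2 / 3)
        assert dec["pct_CI"] == pytest.approx(100.0)
        assert norm["pct_CIV"] == pytest.approx(100.0 * 1 / 3)
        assert norm["pct_CI"] == pytest.approx(0.0)

    def test_independent_complexes_match_marginal(self):
        pi = {"CI": 0.5, "CII": 0.3}
        cfg = make_config(
            53,
            groups=[GroupSpec("PD", 1, 400, 0, deficit_fraction=pi),
                    GroupSpec("control", 5, 80, 0)],
            deficits={"CI": 1.2, "CII": 1.2},
        )
        table, _ = simulate_cohort(cfg)
        model = ControlModel.fit(table[table.group == "control"])
        profiles, _ = build_profiles(table, model)
        cond = conditional_profile(profiles.loc[profiles.group == "PD"], "CI")
        dec = cond.loc[cond["stratum"] == "decreased"].iloc[0]
        norm = cond.loc[cond["stratum"] == "normal"].iloc[0]
        # CII rate should be similar in both strata (independent labels);
        # binomial 3-sigma with n >= 100 per stratum
        n_min = min(dec["n_neurons"], norm["n_neurons"])
        tol = 3 * 100 * np.sqrt(0.5 * 0.5 / n_min) * 2
        assert abs(dec["pct_CII"] - norm["pct_CII"]) < tol

    def test_bad_anchor(self):
        with pytest.raises(DataError):
            conditional_profile(_profiles_frame([{}]), "CVI")


class TestSeverityStack:
    def test_all_normal_group(self):
        stack = severity_stack(_profiles_frame([{}, {}, {}]))
        cat0 = stack.loc[stack["category"] == 0].iloc[0]
        assert cat0["pct_neurons"] == pytest.approx(100.0)
        assert stack["pct_neurons"].sum() == pytest.approx(100.0)

    def test_three_neuron_hand_count(self):
        stack = severity_stack(
            _profiles_frame([{}, {"CI": True}, {c: True for c in panel.COMPLEXES}])
        )
        by_cat = stack.set_index("category")
        for k in (0, 1, 5):
            assert by_cat.loc[k, "pct_neurons"] == pytest.approx(100.0 / 3)
        # in category 1, all flags are CI
        assert by_cat.loc[1, "share_CI"] == pytest.approx(100.0)
        # in category 5, each complex contributes 20%
        for c in panel.COMPLEXES:
            assert by_cat.loc[5, f"share_{c}"] == pytest.approx(20.0)

    def test_polg_like_config_category5_exceeds_4(self):
        pis = {c: 0.85 for c in panel.COMPLEXES}
        cfg = make_config(
            54,
            groups=[GroupSpec("POLG", 2, 150, 0, deficit_fraction=pis),
                    GroupSpec("control", 5, 80, 0)],
            deficits={c: 1.5 for c in panel.COMPLEXES},
        )
        table, _ = simulate_cohort(cfg)
        model = ControlModel.fit(table[table.group == "control"])
        profiles, _ = build_profiles(table, model)
        stack = severity_stack(profiles.loc[profiles.group == "POLG"])
        by_cat = stack.set_index("category")
        assert by_cat.loc[5, "pct_neurons"] > by_cat.loc[4, "pct_neurons"]


class TestMonotonicity:
    def test_adding_flag_never_decreases_category(self):
        base = {s: False for s in panel.SUBUNITS}
        rng = np.random.default_rng(0)
        for _ in range(50):
            flags = {s: bool(rng.random() < 0.4) for s in panel.SUBUNITS}
            cat = sum(complex_calls(flags).values())
            off = [s for s in panel.SUBUNITS if not flags[s]]
            if not off:
                continue
            s_on = off[rng.integers(len(off))]
            flags2 = dict(flags)
            flags2[s_on] = True
            assert sum(complex_calls(flags2).values()) >= cat


class TestLabelRecovery:
    @pytest.mark.parametrize("seed", [61, 62, 63])
    def test_recall_and_false_flag_rate(self, seed):
        """delta = 4*s: recall >= 0.90, false flags <= 0.15, n >= 300."""
        s = 0.25
        pis = {"CI": 0.4, "CIV": 0.3}
        cfg = make_config(
            seed,
            groups=[GroupSpec("PD", 8, 50, 0, deficit_fraction=pis),
                    GroupSpec("control", 10, 45, 0)],
            deficits={"CI": 4 * s, "CIV": 4 * s},
        )
        table, truth = simulate_cohort(cfg)
        model = ControlModel.fit(table[table.group == "control"])
        profiles, _ = build_profiles(table, model)
        pd_profiles = profiles.loc[profiles.group == "PD"]
        assert len(pd_profiles) >= 300
        metrics = recovery_metrics(pd_profiles, truth).set_index("complex")
        for cplx in ("CI", "CIV"):
            assert metrics.loc[cplx, "recall"] >= 0.90
            assert metrics.loc[cplx, "false_flag_rate"] <= 0.15
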