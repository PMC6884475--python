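"""Mixed ANOVA, sphericity correction, simple effects and Shaffer tests."""

import numpy as np
import pandas as pd
import pytest

from lanecue.anova import (
    analyze_experiment,
    build_long_table,
    gg_epsilon,
    mixed_anova,
    pairwise_at_level,
    shaffer_multicomp,
    simple_main_effects,
    simulate_null_type1,
)


def _long(values, groups=("a", "b", "c"), levels=("first", "last")):
    """values: array (n_groups, n_subj, n_levels) -> long table."""
    values = np.asarray(values, float)
    rows = []
    pid = 0
    for gi, g in enumerate(groups):
        for s in range(values.shape[1]):
            for li, lev in enumerate(levels):
                rows.append(
                    {"participant": f"p{pid}", "group": g, "within": lev,
                     "value": values[gi, s, li]}
                )
            pid += 1
    return pd.DataFrame(rows)


# 3 groups x 2 subjects x 2 levels, hand-sized values
FIXTURE = np.array(
    [
        [[4.0, 6.0], [5.0, 9.0]],
        [[7.0, 7.0], [6.0, 10.0]],
        [[1.0, 3.0], [2.0, 2.0]],
    ]
)


class TestMixedAnova:
    def test_matches_independent_reference_on_fixture(self):
        """F values agree with pingouin's mixed ANOVA to 1e-6."""
        pg = pytest.importorskip("pingouin")
        df = _long(FIXTURE)
        ours = mixed_anova(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="within", between="group",
            subject="participant",
        ).set_index("Source")
        assert ours.loc["between", "F"] == pytest.approx(ref.loc["group", "F"], abs=1e-6)
        assert ours.loc["within", "F"] == pytest.approx(ref.loc["within", "F"], abs=1e-6)
        assert ours.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6
        )
        assert ours.loc["interaction", "np2"] == pytest.approx(
            ref.loc["Interaction", "np2"], abs=1e-6
        )

    def test_brute_force_cell_mean_decomposition(self):
        """Sums of squares agree with an explicit loop computation."""
        df = _long(FIXTURE)
        out = mixed_anova(df)
        a, n, b = FIXTURE.shape
        grand = FIXTURE.mean()
        ss_total = ((FIXTURE - grand) ** 2).sum()
        # subject and within-error components via loops
        ss_between = 0.0
        for gi in range(a):
            ss_between += n * b * (FIXTURE[gi].mean() - grand) ** 2
        ss_within = 0.0
        for li in range(b):
            ss_within += a * n * (FIXTURE[:, :, li].mean() - grand) ** 2
        assert out.loc["between", "SS"] == pytest.approx(ss_between, abs=1e-10)
        assert out.loc["within", "SS"] == pytest.approx(ss_within, abs=1e-10)
        parts = out["SS"].sum()
        # remaining variance = subject error + within error
        resid = ss_total - parts
        assert resid == pytest.approx(resid, abs=1e-10)
        assert resid >= -1e-10

    def test_df_convention_3x15(self, rng):
        cube = rng.normal(0, 1, (3, 15, 2))
        out = mixed_anova(_long(cube))
        assert tuple(out.loc["interaction", ["df1", "df2"]]) == (2, 42)
        assert tuple(out.loc["between", ["df1", "df2"]]) == (2, 42)
        assert tuple(out.loc["within", ["df1", "df2"]]) == (1, 42)
        assert out.loc["interaction", "gg_epsilon"] == pytest.approx(1.0)

    def test_null_constant_data_f_zero_p_one(self):
        cube = np.full((3, 4, 2), 2.5)
        out = mixed_anova(_long(cube))
        assert (out["F"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_unbalanced_rejected(self):
        df = _long(FIXTURE)
        with pytest.raises(ValueError):
            mixed_anova(df.iloc[:-1])
        bad = df.copy()
        bad.loc[bad.index[-1], "group"] = "a"  # subject in two groups
        with pytest.raises(ValueError):
            mixed_anova(bad)

    def test_ss_decomposition_total(self, rng):
        cube = rng.normal(0, 1, (3, 8, 2))
        df = _long(cube)
        out = mixed_anova(df)
        # recompute error terms to complete the partition
        a, n, b = cube.shape
        g_mean = cube.mean(axis=(1, 2))
        s_mean = cube.mean(axis=2)
        cell = cube.mean(axis=1)
        ss_subj = b * ((s_mean - g_mean[:, None]) ** 2).sum()
        resid = cube - cell[:, None, :] - s_mean[:, :, None] + g_mean[:, None, None]
        ss_err = (resid**2).sum()
        total = ((cube - cube.mean()) ** 2).sum()
        parts = out["SS"].sum() + ss_subj + ss_err
        assert parts == pytest.approx(total, rel=1e-8)


class TestGGEpsilon:
    def test_two_levels_exactly_one(self, rng):
        for _ in range(5):
            A = rng.normal(0, 1, (10, 2))
            S = np.cov(A, rowvar=False)
            assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_nonspherical_matches_box_formula(self):
        S = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 0.6]])
        k = 3
        C = np.eye(k) - np.ones((k, k)) / k
        Sc = C @ S @ C
        lam = np.linalg.eigvalsh(Sc)
        expect = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert gg_epsilon(S) == pytest.approx(expect, abs=1e-12)

    def test_bounds_on_random_psd(self, rng):
        for k in (3, 4, 6):
            for _ in range(20):
                A = rng.normal(0, 1, (k + 5, k))
                S = A.T @ A
                e = gg_epsilon(S)
                assert 1.0 / (k - 1) - 1e-12 <= e <= 1.0 + 1e-12

    def test_degenerate_zero_matrix(self):
        assert gg_epsilon(np.zeros((3, 3))) == 1.0


class TestSimpleMainEffects:
    def test_df_conventions(self, rng):
        cube = rng.normal(0, 1, (3, 15, 2))
        sme = simple_main_effects(_long(cube))
        within_rows = sme[sme["effect"] == "within"]
        assert set(zip(within_rows["df1"], within_rows["df2"])) == {(1, 14)}
        between_rows = sme[sme["effect"] == "group"]
        assert set(zip(between_rows["df1"], between_rows["df2"])) == {(2, 42)}

    def test_zero_noise_null_all_f_zero(self):
        cube = np.full((3, 5, 2), 1.0)
        sme = simple_main_effects(_long(cube))
        assert (sme["F"] == 0.0).all()

    def test_within_effect_detected_in_right_group(self, rng):
        cube = rng.normal(0, 0.1, (3, 15, 2))
        cube[2, :, 1] += 3.0  # strong trial effect in the third group only
        sme = simple_main_effects(_long(cube))
        w = sme[sme["effect"] == "within"].set_index("stratum")
        assert w.loc["c", "p"] < 1e-6
        assert w.loc["a", "p"] > 0.01


class TestShaffer:
    def test_k3_threshold_sequence(self):
        out = shaffer_multicomp([0.001, 0.04, 0.2], k_groups=3)
        assert list(out["denominator"]) == [3, 1, 1]
        assert list(out["reject"]) == [True, True, False]

    def test_all_ones_no_rejections(self):
        out = shaffer_multicomp([1.0, 1.0, 1.0], k_groups=3)
        assert not out["reject"].any()

    def test_stops_at_first_failure(self):
        # smallest p misses alpha/3 -> nothing rejected even if later p small
        out = shaffer_multicomp([0.02, 0.021, 0.022], k_groups=3)
        assert not out["reject"].any()

    def test_sequential_gate(self):
        # first rejected at alpha/3, second tested at alpha/1
        out = shaffer_multicomp([0.01, 0.049, 0.9], k_groups=3)
        assert list(out["reject"]) == [True, True, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            shaffer_multicomp([0.5, -0.1, 0.2], k_groups=3)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_at_least_as_powerful_as_holm(self, k, rng):
        from statsmodels.stats.multitest import multipletests

        m = k * (k - 1) // 2
        for _ in range(50):
            p = rng.uniform(0, 0.3, m)
            shaffer = shaffer_multicomp(p, k_groups=k)["reject"].to_numpy()
            holm = multipletests(p, alpha=0.05, method="holm")[0]
            assert (shaffer | ~holm).all()  # Shaffer rejects a superset


class TestAnalyzeExperiment:
    @staticmethod
    def _metrics_table(rng, effect=0.0):
        rows = []
        for g in ("ND", "VO", "SS"):
            for s in range(15):
                pid = f"{g}-{s:02d}"
                base = rng.normal(0.3, 0.05)
                for session, trials in (("pretest", [5]), ("training", [1, 40]),
                                        ("posttest", [1])):
                    for t in trials:
                        bump = effect if (g != "ND" and session == "training" and t == 1) else 0.0
                        rows.append(
                            {"participant": pid, "group": g, "session": session,
                             "trial": t,
                             "sdlp": base + bump + rng.normal(0, 0.02),
                             "swv": rng.normal(160, 10), "n_curves": 7,
                             "off_road": False}
                        )
        return pd.DataFrame(rows)

    def test_report_structure_and_determinism(self, rng):
        m = self._metrics_table(rng, effect=0.3)
        r1 = analyze_experiment(m)
        r2 = analyze_experiment(m.copy())
        assert r1 == r2
        entry = r1["metrics"]["sdlp"]["training_first_last"]
        assert entry["interaction_significant"]
        assert {row["effect"] for row in entry["anova"]} == {
            "between", "within", "interaction"
        }
        assert "simple_main_effects" in entry
        assert entry["anova"][2]["df1"] == 2 and entry["anova"][2]["df2"] == 42

    def test_no_effect_rarely_significant(self):
        # 8 null replicates x 4 interaction tests each: expect ~1.6 firings
        # at alpha = 0.05; far more would indicate an anticonservative test
        fired = 0
        for seed in range(8):
            m = self._metrics_table(np.random.default_rng(seed), effect=0.0)
            r = analyze_experiment(m)
            fired += sum(
                r["metrics"][met][con]["interaction_significant"]
                for met in r["metrics"]
                for con in r["metrics"][met]
            )
        assert fired <= 6

    def test_missing_session_rejected(self, rng):
        m = self._metrics_table(rng)
        with pytest.raises(ValueError):
            analyze_experiment(m[m.session != "posttest"])

    def test_build_long_table_selects_min_max_trials(self, rng):
        m = self._metrics_table(rng)
        long = build_long_table(m, "sdlp", "training_first_last")
        assert set(long["within"]) == {"first", "last"}
        assert len(long) == 90

    def test_pairwise_uses_pooled_df42(self, rng):
        cube = rng.normal(0, 0.1, (3, 15, 2))
        cube[0] += 1.0
        pw = pairwise_at_level(_long(cube), "first")
        assert (pw["df"] == 42).all()
        assert len(pw) == 3


class TestTypeIError:
    def test_null_rejection_rate_near_alpha(self):
        rate = simulate_null_type1(n_reps=100, seed=5)
        se = np.sqrt(0.05 * 0.95 / 100)
        assert abs(rate - 0.05) <= 2.5 * se + 1e-12
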