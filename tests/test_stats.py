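import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from facemix.stats import (
    PowerSpec,
    aggregate_cell_means,
    bonferroni_threshold,
    dprime,
    paired_t,
    partial_eta_sq,
    power_t,
    repetition_trend,
    rm_anova_2x2,
    sample_size_t,
)

CELLS = ["self_full", "self_partial", "other_full", "other_partial"]


def brute_force_rm_anova(y: np.ndarray) -> dict[str, float]:
    """Textbook sums-of-squares decomposition of the 2x2 within design.

    ``y`` has shape (n, 2, 2): participants x face x control.  Each effect's F
    is SS_effect / (SS_effect_x_subject / (n - 1)).
    """
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    face = y.mean(axis=(0, 2))
    ctrl = y.mean(axis=(0, 1))
    cell = y.mean(axis=0)

    ss_face = 2 * n * np.sum((face - grand) ** 2)
    ss_ctrl = 2 * n * np.sum((ctrl - grand) ** 2)
    ss_inter = n * np.sum((cell - face[:, None] - ctrl[None, :] + grand) ** 2)

    subj_face = y.mean(axis=2)  # (n, 2)
    ss_face_err = 2 * np.sum((subj_face - subj[:, None] - face[None, :] + grand) ** 2)
    subj_ctrl = y.mean(axis=1)
    ss_ctrl_err = 2 * np.sum((subj_ctrl - subj[:, None] - ctrl[None, :] + grand) ** 2)
    ss_inter_err = np.sum(
        (
            y
            - subj_face[:, :, None]
            - subj_ctrl[:, None, :]
            - cell[None]
            + subj[:, None, None]
            + face[None, :, None]
            + ctrl[None, None, :]
            - grand
        )
        ** 2
    )
    return {
        "face": ss_face / (ss_face_err / (n - 1)),
        "control": ss_ctrl / (ss_ctrl_err / (n - 1)),
        "interaction": ss_inter / (ss_inter_err / (n - 1)),
    }


def _cells_frame(y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "self_full": y[:, 0, 0],
            "self_partial": y[:, 0, 1],
            "other_full": y[:, 1, 0],
            "other_partial": y[:, 1, 1],
        }
    )


class TestAggregateCellMeans:
    def _table(self, values):
        rows = []
        for p in ("p0", "p1"):
            for face in ("self", "other"):
                for control in ("full", "partial"):
                    for rep, v in enumerate(values, start=1):
                        rows.append(
                            {"participant": p, "face": face, "control": control,
                             "repetition": rep, "agency_rating": v}
                        )
        return pd.DataFrame(rows)

    def test_identical_repetitions(self):
        cells = aggregate_cell_means(self._table([7.0] * 5), "agency_rating")
        assert (cells.to_numpy() == 7.0).all()

    def test_mean_of_one_to_five(self):
        cells = aggregate_cell_means(self._table([1, 2, 3, 4, 5]), "agency_rating")
        assert (cells.to_numpy() == 3.0).all()

    def test_missing_cell_named_in_error(self):
        table = self._table([1.0])
        table = table[~((table.participant == "p1") & (table.face == "other") & (table.control == "partial"))]
        with pytest.raises(ValueError, match="p1.*other.*partial"):
            aggregate_cell_means(table, "agency_rating")


class TestRmAnova:
    def test_hand_worked_table_matches_brute_force(self):
        y = np.array(
            [
                [[72.0, 55.0], [80.0, 61.0]],
                [[65.0, 47.0], [71.0, 56.0]],
                [[70.0, 52.0], [77.0, 60.0]],
                [[60.0, 50.0], [69.0, 57.0]],
            ]
        )
        oracle = brute_force_rm_anova(y)
        effects = {e.effect: e for e in rm_anova_2x2(_cells_frame(y))}
        for name in ("face", "control", "interaction"):
            assert effects[name].F == pytest.approx(oracle[name], abs=1e-10)
            assert effects[name].df1 == 1
            assert effects[name].df2 == 3

    def test_random_tables_match_brute_force_and_squared_t(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            y = rng.normal(50, 10, size=(n, 2, 2))
            oracle = brute_force_rm_anova(y)
            effects = {e.effect: e for e in rm_anova_2x2(_cells_frame(y))}
            for name, F in oracle.items():
                assert effects[name].F == pytest.approx(F, rel=1e-10, abs=1e-10)
            # face F equals the squared paired t on the face contrast
            face_contrast_x = y[:, 0, :].mean(axis=1)
            face_contrast_y = y[:, 1, :].mean(axis=1)
            t, df, _, _ = paired_t(face_contrast_x, face_contrast_y)
            assert effects["face"].F == pytest.approx(t**2, rel=1e-10)
            assert effects["face"].df2 == df

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.normal(50, 12, size=(10, 2, 2))
        long = []
        for i in range(10):
            for j, face in enumerate(("self", "other")):
                for k, control in enumerate(("full", "partial")):
                    long.append({"subject": i, "face": face, "control": control, "y": y[i, j, k]})
        long = pd.DataFrame(long)
        effects = {e.effect: e for e in rm_anova_2x2(_cells_frame(y))}
        res = pg.rm_anova(data=long, dv="y", within=["face", "control"], subject="subject", detailed=True)
        by_src = {row.Source.lower(): row for row in res.itertuples()}
        assert effects["face"].F == pytest.approx(by_src["face"].F, rel=1e-9)
        assert effects["control"].F == pytest.approx(by_src["control"].F, rel=1e-9)
        inter_key = [k for k in by_src if "*" in k][0]
        assert effects["interaction"].F == pytest.approx(by_src[inter_key].F, rel=1e-9)

    def test_relabeling_and_location_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(8, 2, 2))
        base = {e.effect: e.F for e in rm_anova_2x2(_cells_frame(y))}
        swapped = {e.effect: e.F for e in rm_anova_2x2(_cells_frame(y[:, ::-1, :]))}
        assert swapped["face"] == pytest.approx(base["face"], rel=1e-12)
        assert swapped["interaction"] == pytest.approx(base["interaction"], rel=1e-12)
        shifted = {e.effect: e.F for e in rm_anova_2x2(_cells_frame(y + 123.4))}
        for name, F in base.items():
            assert shifted[name] == pytest.approx(F, rel=1e-9)

    def test_zero_error_variance_reports_infinite_f(self):
        y = np.zeros((5, 2, 2))
        y[:, 1, :] = 10.0  # perfectly consistent face effect
        with pytest.warns(UserWarning, match="zero error variance"):
            effects = {e.effect: e for e in rm_anova_2x2(_cells_frame(y))}
        assert np.isinf(effects["face"].F)
        assert effects["face"].eta_p2 == 1.0

    def test_type_one_error_calibration(self):
        """Under the null each effect rejects at alpha = 0.05 in 5% +- 1%."""
        rng = np.random.default_rng(42)
        M, n = 10_000, 20
        y = rng.normal(size=(M, n, 4))
        crit = sps.f.isf(0.05, 1, n - 1)
        for w in ([1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1]):
            scores = y @ (0.5 * np.array(w, dtype=float))
            F = n * scores.mean(axis=1) ** 2 / scores.var(axis=1, ddof=1)
            rate = float(np.mean(F > crit))
            assert rate == pytest.approx(0.05, abs=0.01)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F,expected",
        [(11.419, 0.375), (74.310, 0.796), (40.813, 0.682), (14.761, 0.437), (5.555, 0.226)],
    )
    def test_partial_eta_squared_from_reported_f(self, F, expected):
        assert partial_eta_sq(F, 1, 19) == pytest.approx(expected, abs=5e-4)

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 1, 19) == 0.0

    def test_monotone_in_f(self):
        vals = [partial_eta_sq(F, 1, 19) for F in (0.1, 1, 5, 20, 100)]
        assert vals == sorted(vals)


class TestPairedT:
    def test_identical_samples(self):
        t, df, p, d = paired_t(np.arange(5.0), np.arange(5.0))
        assert (t, p, d) == (0.0, 1.0, 0.0)
        assert df == 4

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))

    def test_hand_computed_fixture(self):
        diffs = np.array([2.0, 1.0, 3.0, 2.0, 2.0])
        t, df, p, d_z = paired_t(diffs, np.zeros(5))
        expected_t = diffs.mean() / diffs.std(ddof=1) * np.sqrt(5)
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert d_z == pytest.approx(diffs.mean() / diffs.std(ddof=1), rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(expected_t, 4), rel=1e-12)

    def test_one_tailed_halves_the_p_for_positive_t(self):
        x = np.array([3.0, 4.0, 5.5, 4.5, 6.0])
        y = np.zeros(5)
        _, _, p2, _ = paired_t(x, y, tails=2)
        _, _, p1, _ = paired_t(x, y, tails=1)
        assert p1 == pytest.approx(p2 / 2, rel=1e-12)


def test_bonferroni_threshold_examples():
    assert bonferroni_threshold(0.05, 2) == pytest.approx(0.025)
    assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)


class TestDprime:
    def test_chance_performance_is_zero(self):
        assert dprime(0.5, 0.5) == pytest.approx(0.0)

    def test_unit_quantiles(self):
        # hit/fa of Phi(1)/Phi(-1): z-scores +1 and -1, d' = 2
        assert dprime(0.8413, 0.1587) == pytest.approx(2.00, abs=5e-3)

    def test_extreme_rates_with_correction(self):
        got = dprime(1.0, 0.0, n_trials=20)
        expected = sps.norm.ppf(39 / 40) - sps.norm.ppf(1 / 40)
        assert got == pytest.approx(expected, rel=1e-12)
        assert np.isfinite(got)

    def test_extreme_rates_without_correction_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            dprime(1.0, 0.2)


class TestPower:
    def test_reported_sample_size_reproduced(self):
        """d = 0.617, one-tailed alpha .05, power .8 -> n = 18 (paired form)."""
        spec = PowerSpec(d=0.617, alpha=0.05, power_target=0.8, tails=1, design="paired")
        assert sample_size_t(spec) == 18

    def test_minimality_contract(self):
        spec = PowerSpec(d=0.617, alpha=0.05, power_target=0.8, tails=1, design="paired")
        n = sample_size_t(spec)
        assert power_t(n, spec) >= 0.8
        assert power_t(n - 1, spec) < 0.8

    def test_independent_design_needs_many_more(self):
        spec = PowerSpec(d=0.617, alpha=0.05, power_target=0.8, tails=1, design="independent")
        assert sample_size_t(spec) > 30  # per group; the paired form gives 18

    def test_large_effect_matches_monte_carlo(self):
        """d = 3 needs n <= 5; noncentral-t power matches simulation to 0.01."""
        spec = PowerSpec(d=3.0, alpha=0.05, power_target=0.8, tails=1, design="paired")
        n = sample_size_t(spec)
        assert n <= 5
        rng = np.random.default_rng(0)
        M = 100_000
        x = rng.normal(3.0, 1.0, size=(M, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        mc_power = float(np.mean(t > sps.t.isf(0.05, n - 1)))
        assert mc_power == pytest.approx(power_t(n, spec), abs=0.01)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            sample_size_t(PowerSpec(d=0.0))


class TestRepetitionTrend:
    def _table(self, value_fn, n_participants=6, reps=5):
        rows = []
        for p in range(n_participants):
            for face in ("self", "other"):
                for control in ("full", "partial"):
                    for rep in range(1, reps + 1):
                        rows.append(
                            {"participant": f"p{p}", "face": face, "control": control,
                             "repetition": rep, "agency_rating": value_fn(p, rep)}
                        )
        return pd.DataFrame(rows)

    def test_constant_values_give_zero_slope_and_t(self):
        res = repetition_trend(self._table(lambda p, rep: 50.0), "agency_rating")
        np.testing.assert_allclose(res["mean_slope"], 0.0, atol=1e-12)
        assert (res["t"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_linear_values_give_unit_slope(self):
        res = repetition_trend(self._table(lambda p, rep: float(rep)), "agency_rating")
        np.testing.assert_allclose(res["mean_slope"], 1.0, rtol=1e-9)

    def test_null_data_rejects_at_nominal_rate(self):
        """|t| exceeds the critical value in about 5% of null simulations."""
        rng = np.random.default_rng(3)
        rejections = trials = 0
        for _ in range(200):
            res = repetition_trend(
                self._table(lambda p, rep: float(rng.normal(50, 10))), "agency_rating"
            )
            crit = sps.t.isf(0.025, res["df"].iloc[0])
            rejections += int((res["t"].abs() > crit).sum())
            trials += len(res)
        assert rejections / trials == pytest.approx(0.05, abs=0.025)
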