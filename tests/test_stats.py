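"""Box-Cox, type-III F interaction models, follow-ups and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conflictdemog import (
    bh_adjust,
    boxcox_fit,
    boxcox_transform,
    fit_interaction_model,
    per_temperature_models,
)
from conflictdemog.stats import apply_bh


def _toy_table(rng, n_per_cell=30, interaction=0.0, system_effect=0.0, noise=1.0):
    rows = []
    for T in (20.0, 24.0, 28.0):
        for system in ("monogamy", "polyandry"):
            is_poly = float(system == "polyandry")
            mu = 10.0 + 0.2 * T + system_effect * is_poly + interaction * (T - 24.0) * is_poly
            y = mu + noise * rng.standard_normal(n_per_cell)
            for v in y:
                rows.append({"temperature": T, "mating_system": system, "y": v})
    return pd.DataFrame(rows)


class TestBoxCox:
    def test_lognormal_sample_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(2.0, 0.6, size=800))
        fit = boxcox_fit(y)
        assert abs(fit.lambda_) <= 0.15

    def test_normal_sample_lambda_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(12.0, 3.0, size=4000)
        y = y[y > 0]
        fit = boxcox_fit(y)
        assert abs(fit.lambda_ - 1.0) <= 0.25

    def test_matches_scipy_mle_on_grid(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 3.0, size=500) + 0.1
        fit = boxcox_fit(y)
        _, lam_mle = sps.boxcox(y)
        assert abs(fit.lambda_ - lam_mle) <= 0.05  # grid step is 0.05

    def test_lambda_one_is_affine_shift(self):
        from conflictdemog.stats import BoxCoxFit

        fit = BoxCoxFit(lambda_=1.0, shift=0.0, loglik_profile=())
        y = np.array([1.0, 5.0, 9.0])
        assert np.allclose(boxcox_transform(y, fit), y - 1.0)

    def test_shift_makes_zero_responses_legal(self):
        y = np.array([0.0, 3.0, 10.0])
        fit = boxcox_fit(y)
        assert fit.shift == 1.0
        assert np.all(np.isfinite(boxcox_transform(y, fit)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            boxcox_fit([1.0, np.nan])


class TestInteractionModel:
    def test_balanced_design_type3_equals_sequential(self):
        """In a balanced design with centred orthogonal columns, the
        type-III (drop-one) F equals the sequential (add-one) F."""
        rng = np.random.default_rng(3)
        df = _toy_table(rng, interaction=0.3)
        res = fit_interaction_model(df, "y")
        # sequential brute force: add interaction last
        y = df["y"].to_numpy()
        temp = df["temperature"].to_numpy() - df["temperature"].mean()
        poly = (df["mating_system"] == "polyandry").astype(float).to_numpy()
        X_red = np.column_stack([np.ones(len(y)), temp, poly])
        X_full = np.column_stack([X_red, temp * poly])

        def sse(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        df_den = len(y) - X_full.shape[1]
        F_seq = (sse(X_red) - sse(X_full)) / (sse(X_full) / df_den)
        t = res.term("temperature:mating_system")
        assert t.F == pytest.approx(F_seq, rel=1e-10)
        assert t.df_den == df_den

    def test_interaction_slope_recovered_with_ci_coverage(self):
        """Known interaction slope is recovered; 95% CI covers it at about
        the nominal rate across replicates."""
        rng = np.random.default_rng(4)
        slope = 0.25
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = _toy_table(rng, n_per_cell=20, interaction=slope)
            t = fit_interaction_model(df, "y").term("temperature:mating_system")
            if t.ci_low <= slope <= t.ci_high:
                hits += 1
        # nominal 0.95; 3 sigma band for 200 draws
        assert hits / n_rep == pytest.approx(0.95, abs=3 * np.sqrt(0.95 * 0.05 / n_rep))

    def test_main_system_excluded_by_flag(self):
        rng = np.random.default_rng(5)
        df = _toy_table(rng)
        res = fit_interaction_model(df, "y", include_main_system=False)
        names = [t.term for t in res.terms]
        assert "mating_system" not in names
        assert "temperature:mating_system" in names

    def test_quadratic_factor_coding_runs_and_tests_two_df(self):
        rng = np.random.default_rng(6)
        df = _toy_table(rng)
        res = fit_interaction_model(df, "y", temperature_as="factor_quadratic")
        assert res.term("temperature").df_num == 2
        assert res.term("temperature:mating_system").df_num == 2

    def test_single_level_inputs_rejected(self):
        rng = np.random.default_rng(7)
        df = _toy_table(rng)
        with pytest.raises(ValueError):
            fit_interaction_model(df[df.mating_system == "monogamy"], "y")


class TestPerTemperatureModels:
    def test_three_temperatures_three_rows(self):
        rng = np.random.default_rng(8)
        df = _toy_table(rng)
        out = per_temperature_models(df, "y")
        assert [m.stratum for m in out] == ["20", "24", "28"]

    def test_estimates_match_two_group_least_squares(self):
        rng = np.random.default_rng(9)
        df = _toy_table(rng, system_effect=-1.0)
        for m in per_temperature_models(df, "y"):
            cell = df[df.temperature == float(m.stratum)]
            diff = (
                cell[cell.mating_system == "polyandry"]["y"].mean()
                - cell[cell.mating_system == "monogamy"]["y"].mean()
            )
            assert m.term("mating_system").estimate == pytest.approx(diff, rel=1e-10)

    def test_effect_at_single_temperature_detected_there(self):
        """Power check: an effect present only at 24 degC is significant
        there and (almost) never elsewhere."""
        rng = np.random.default_rng(10)
        sig = {20.0: 0, 24.0: 0, 28.0: 0}
        n_rep = 100
        for _ in range(n_rep):
            rows = []
            for T in (20.0, 24.0, 28.0):
                for system in ("monogamy", "polyandry"):
                    shift = -2.0 if (T == 24.0 and system == "polyandry") else 0.0
                    for v in rng.standard_normal(25) + shift:
                        rows.append({"temperature": T, "mating_system": system, "y": v})
            for m in per_temperature_models(pd.DataFrame(rows), "y"):
                if m.term("mating_system").p < 0.05:
                    sig[float(m.stratum)] += 1
        assert sig[24.0] == n_rep  # d = 2 at n = 25/group: essentially always
        assert sig[20.0] / n_rep < 0.15
        assert sig[28.0] / n_rep < 0.15

    def test_stratum_with_one_level_skipped_with_warning(self):
        rng = np.random.default_rng(11)
        df = _toy_table(rng)
        df = df[~((df.temperature == 20.0) & (df.mating_system == "polyandry"))]
        with pytest.warns(UserWarning, match="20"):
            out = per_temperature_models(df, "y")
        assert [m.stratum for m in out] == ["24", "28"]


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == [0.42]

    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def _brute_force(self, p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adj = [None] * m
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            adj[i] = val
            prev = val
        return adj

    def test_matches_brute_force_and_statsmodels_on_random_inputs(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 15)).tolist()
            mine = bh_adjust(p)
            assert mine == pytest.approx(self._brute_force(p), rel=1e-12)
            _, sm_adj, *_ = multipletests(p, method="fdr_bh")
            assert mine == pytest.approx(list(sm_adj), rel=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_order_invariance_and_monotonicity(self, p):
        """BH is invariant to input order up to the position mapping, and
        adjusted p is non-decreasing in the rank of the raw p."""
        adj = bh_adjust(p)
        perm = list(reversed(range(len(p))))
        adj_perm = bh_adjust([p[i] for i in perm])
        assert adj == pytest.approx([adj_perm[perm.index(i)] for i in range(len(p))])
        order = np.argsort(p, kind="mergesort")
        ranked = np.array(adj)[order]
        assert np.all(np.diff(ranked) >= -1e-12)
        assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))


def test_apply_bh_fills_adjusted_across_family():
    rng = np.random.default_rng(13)
    df = _toy_table(rng)
    results = [fit_interaction_model(df, "y") for _ in range(2)]
    apply_bh(results)
    for res in results:
        for t in res.terms:
            assert t.p_adj is not None and t.p_adj >= t.p - 1e-12
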