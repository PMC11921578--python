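"""OLS interaction models, effect sizes, diagnostics, correlation matrices."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from fepbias import (
    ALL_TERMS,
    SimulationConfig,
    correlation_matrix,
    fit_model,
    generate_participants,
    semipartial_r2,
)
from fepbias.cohort import sample_lq1
from fepbias.regression import diagnostics_from_fit, prepare_model_frame


@pytest.fixture(scope="module")
def model_frame():
    """A 424-row complete-case table with the published model's 13 terms."""
    cfg = SimulationConfig(
        n_participants=500,
        seed=31,
        sex_proportions={"female": 0.5, "male": 0.5, "undisclosed": 0.0},
    )
    p = generate_participants(cfg)
    from fepbias import score_participants

    scored = score_participants(p)
    scored["lq1"] = sample_lq1(p, cfg, np.random.default_rng(77))
    return prepare_model_frame(scored).head(424)


@pytest.fixture(scope="module")
def fitted(model_frame):
    return fit_model(model_frame, "lq1")


class TestFit:
    def test_exact_fit_recovers_line(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"x": x, "y": 2 + 3 * x})
        res = fit_model(data, "y", terms=("x",))
        coef = res.coefficients.set_index("term")
        assert coef.loc["intercept", "estimate"] == pytest.approx(2.0)
        assert coef.loc["x", "estimate"] == pytest.approx(3.0)
        assert res.r2 == pytest.approx(1.0)

    def test_thirteen_term_model_df(self, fitted):
        assert fitted.df_model == 13
        assert fitted.df_resid == 424 - 14 == 410

    def test_fit_statistic_identities(self, fitted):
        r2, n = fitted.r2, fitted.n
        assert fitted.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 14), abs=1e-10)
        assert fitted.f_stat == pytest.approx(
            (r2 / 13) / ((1 - r2) / fitted.df_resid), abs=1e-8
        )

    def test_ci_and_p_agree(self, fitted):
        coef = fitted.coefficients
        excludes_zero = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)
        assert (excludes_zero == (coef["p"] < 0.05)).all()

    def test_dropping_terms_never_raises_r2(self, fitted, model_frame):
        for drop in ("age", "imagination:sex_male"):
            reduced = fit_model(
                model_frame, "lq1", terms=tuple(t for t in ALL_TERMS if t != drop)
            )
            assert reduced.r2 <= fitted.r2 + 1e-12

    def test_monte_carlo_coefficient_recovery(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.0 + 0.5 * x1 - 0.25 * x2 + rng.normal(scale=0.1, size=n)
        res = fit_model(pd.DataFrame({"y": y, "x1": x1, "x2": x2}), "y", terms=("x1", "x2"))
        coef = res.coefficients.set_index("term")
        for term, truth in [("intercept", 1.0), ("x1", 0.5), ("x2", -0.25)]:
            assert abs(coef.loc[term, "estimate"] - truth) <= 3 * coef.loc[term, "se"]

    def test_rank_deficient_design_names_terms(self, model_frame):
        data = model_frame.copy()
        data["ehi_copy"] = data["ehi_score"]
        with pytest.raises(np.linalg.LinAlgError, match="ehi"):
            fit_model(data, "lq1", terms=("ehi_score", "ehi_copy"))

    def test_undisclosed_rows_rejected_before_fit(self):
        df = pd.DataFrame({"sex": ["female", "undisclosed"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            prepare_model_frame(df)


class TestSemipartialR2:
    def test_single_predictor_sr2_equals_r2(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = fit_model(pd.DataFrame({"x": x, "y": y}), "y", terms=("x",))
        assert semipartial_r2(res, "x") == pytest.approx(res.r2, abs=1e-10)

    def test_orthogonal_predictors_sum_to_r2(self):
        rng = np.random.default_rng(3)
        # QR of [1 | random] gives columns orthogonal to each other and to
        # the intercept; drop the constant column itself
        q, _ = np.linalg.qr(np.column_stack([np.ones(60), rng.normal(size=(60, 4))]))
        x = q[:, 1:]
        y = x @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=60)
        data = pd.DataFrame(x, columns=list("abcd"))
        data["y"] = y
        res = fit_model(data, "y", terms=tuple("abcd"))
        total = sum(semipartial_r2(res, t) for t in "abcd")
        assert total == pytest.approx(res.r2, abs=1e-8)

    def test_t_formula_equals_refit_delta_r2(self, fitted, model_frame):
        for term in ("ehi_score", "attention_switching", "imagination:sex_male"):
            reduced = fit_model(
                model_frame, "lq1", terms=tuple(t for t in ALL_TERMS if t != term)
            )
            delta = fitted.r2 - reduced.r2
            assert semipartial_r2(fitted, term) == pytest.approx(delta, abs=1e-10)

    def test_unknown_term_rejected(self, fitted):
        with pytest.raises(KeyError):
            semipartial_r2(fitted, "shoe_size")


class TestDiagnostics:
    def test_durbin_watson_hand_values(self):
        exog = np.ones((4, 1))
        d = diagnostics_from_fit(np.array([1.0, -1.0, 1.0, -1.0]), exog)
        assert d["durbin_watson"] == pytest.approx(3.0)
        d = diagnostics_from_fit(np.array([1.0, 1.0, 1.0]), np.ones((3, 1)))
        assert d["durbin_watson"] == pytest.approx(0.0)

    def test_reported_on_fitted_model(self, fitted):
        d = fitted.diagnostics
        assert set(d) == {"durbin_watson", "breusch_pagan_p", "shapiro_wilk_p"}
        assert 0 < d["durbin_watson"] < 4
        assert 0 <= d["breusch_pagan_p"] <= 1

    def test_breusch_pagan_null_calibration(self):
        """Under homoscedastic errors the BP p-value is uniform."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=(150, 2))
            y = x @ [1.0, 2.0] + rng.normal(size=150)
            res = fit_model(
                pd.DataFrame({"y": y, "a": x[:, 0], "b": x[:, 1]}), "y", terms=("a", "b")
            )
            pvals.append(res.diagnostics["breusch_pagan_p"])
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestCorrelations:
    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"] + 3
        mats = correlation_matrix(df, ["x", "y"])["all"]
        assert mats["r"].loc["x", "x"] == 1.0
        assert mats["r"].loc["x", "y"] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        mats = correlation_matrix(df, ["x", "y"])["all"]
        assert mats["r"].loc["x", "y"] == pytest.approx(0.6)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [2.0, 1.0, 4.0, 3.0]})
        mats = correlation_matrix(df, ["x", "y"])["all"]
        assert np.isnan(mats["r"].loc["x", "y"])

    def test_by_sex_split(self, model_frame):
        mats = correlation_matrix(model_frame, ["age", "ehi_score"], group="by_sex")
        assert set(mats) == {"female", "male"}
        for m in mats.values():
            r = m["r"]
            assert np.allclose(r, r.T, equal_nan=True)
            assert np.allclose(np.diag(r), 1.0)
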