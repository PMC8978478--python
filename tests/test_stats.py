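import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from potholes import (
    GeneticSpec,
    fdr_bh,
    fit_linear,
    generate_covariates,
    linked_molehill_counts,
    run_global_suite,
    run_tract_suite,
    toy_template,
)

from _oracles import brute_bh, ols_normal_equations


def long_counts(wide: dict, n: int, rng) -> pd.DataFrame:
    """Build a long count table with the given (polarity, threshold) columns."""
    rows = []
    for (polarity, threshold), values in wide.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject": f"s{i:04d}",
                    "polarity": polarity,
                    "min_volume_mm3": threshold,
                    "count": v,
                }
            )
    return pd.DataFrame(rows)


def random_counts(n, rng, thresholds=(25.0, 50.0, 100.0, 200.0)):
    wide = {}
    for polarity in ("pothole", "molehill"):
        base = rng.poisson(20, size=n)
        for j, t in enumerate(thresholds):
            wide[(polarity, t)] = np.maximum(base - rng.poisson(5 * j, size=n), 0)
    return long_counts(wide, n, rng)


class TestFitLinear:
    def test_exact_linear_relation(self):
        x = pd.Series(np.arange(10.0), name="x")
        res = fit_linear(2.0 * x, x)
        assert res.beta == pytest.approx(2.0)
        assert res.delta_r2 == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n = 40
        exposure = pd.Series(rng.normal(size=n), name="x")
        cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        y = pd.Series(1.0 + 0.8 * exposure + 0.3 * cov.c1 + rng.normal(size=n))
        res = fit_linear(y, exposure, cov)
        X = np.column_stack([np.ones(n), exposure, cov.c1, cov.c2])
        beta, se, p, r2 = ols_normal_equations(y.to_numpy(), X)
        assert res.beta == pytest.approx(beta[1], rel=1e-10)
        assert res.se == pytest.approx(se[1], rel=1e-10)
        assert res.p_value == pytest.approx(p[1], rel=1e-8)
        X_red = np.column_stack([np.ones(n), cov.c1, cov.c2])
        _, _, _, r2_red = ols_normal_equations(y.to_numpy(), X_red)
        assert res.delta_r2 == pytest.approx(r2 - r2_red, abs=1e-12)

    def test_null_exposure_rarely_significant(self):
        """Permuted exposure: the |beta| stays within 3 SE nearly always."""
        rng = np.random.default_rng(8)
        hits = 0
        n, reps = 500, 100
        for _ in range(reps):
            y = pd.Series(rng.poisson(20, size=n).astype(float))
            x = pd.Series(rng.normal(size=n), name="x")
            res = fit_linear(y, x)
            hits += abs(res.beta) > 3 * res.se
        assert hits <= 5  # ~0.27% expected rate, generous bound

    def test_listwise_deletion(self):
        x = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8], name="x")
        y = 3.0 * x
        y.iloc[2] = np.nan
        res = fit_linear(y, x)
        assert res.n == 7
        assert res.beta == pytest.approx(3.0)

    def test_degenerate_constant_outcome_reports_null(self):
        x = pd.Series(np.arange(8.0), name="x")
        res = fit_linear(pd.Series(np.zeros(8)), x)
        assert res.beta == 0.0 and res.p_value == 1.0 and res.delta_r2 == 0.0

    def test_errors(self):
        x = pd.Series(np.ones(10), name="x")
        with pytest.raises(ValueError, match="constant"):
            fit_linear(pd.Series(np.arange(10.0)), x)
        with pytest.raises(ValueError, match="too small"):
            fit_linear(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0], name="x"))
        cov = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="duplicated"):
            fit_linear(
                pd.Series(np.arange(10.0)),
                pd.Series(np.arange(10.0), name="x"),
                cov,
            )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear(
                pd.Series(np.random.default_rng(0).normal(size=10)),
                pd.Series(np.arange(10.0), name="x"),
                pd.DataFrame({"c": 2 * np.arange(10.0)}),
            )


class TestFdrBH:
    def test_hand_worked_example(self):
        # p*m/rank with cumulative minimum: [.001,.02,.03,.04] -> [.004,.04,.04,.04]
        q = fdr_bh([0.001, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.004, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert fdr_bh([0.37]) == pytest.approx([0.37])
        assert fdr_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(fdr_bh(p), brute_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bh_definition_property(self, p):
        assert np.allclose(fdr_bh(p), brute_bh(p), atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(10)
        p = rng.random(25)
        assert np.all(fdr_bh(p) >= p - 1e-15)

    def test_invalid_p_rejected(self):
        for bad in ([1.2], [-0.1], [np.nan], []):
            with pytest.raises(ValueError):
                fdr_bh(bad)


@pytest.fixture(scope="module")
def cohort_tables():
    rng = np.random.default_rng(11)
    n = 200
    counts = random_counts(n, rng)
    covariates = generate_covariates(n, seed=12)
    scores = pd.Series(rng.standard_normal(n), index=covariates.index, name="prs")
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return counts, covariates, scores


class TestSuites:

    def test_prs_suite_has_eight_fdr_corrected_rows(self, cohort_tables):
        counts, covariates, scores = cohort_tables
        out = run_global_suite(counts, covariates, scores=scores, suite="prs")
        assert len(out) == 8
        assert set(out.exposure) == {"prs"}
        assert np.allclose(np.sort(out.q), np.sort(brute_bh(out.p.to_numpy())))
        assert (out.n == 200).all()

    def test_descriptive_suite_has_sixteen_rows(self, cohort_tables):
        counts, covariates, _ = cohort_tables
        out = run_global_suite(counts, covariates, suite="descriptive")
        assert len(out) == 16
        assert set(out.exposure) == {"sex", "age"}

    def test_extra_covariate_sensitivity_changes_fit(self, cohort_tables):
        counts, covariates, scores = cohort_tables
        base = run_global_suite(counts, covariates, scores=scores, suite="prs")
        adj = run_global_suite(
            counts, covariates, scores=scores, suite="prs",
            extra_covariates=("maternal_education",),
        )
        assert len(adj) == 8
        assert not np.allclose(base.p.to_numpy(), adj.p.to_numpy())

    def test_prs_suite_requires_scores(self, cohort_tables):
        counts, covariates, _ = cohort_tables
        with pytest.raises(ValueError, match="score"):
            run_global_suite(counts, covariates, suite="prs")

    def test_recovers_planted_prs_effect(self):
        """Molehill counts Poisson-linked to the score yield a positive,
        significant scaled beta for the molehill outcomes."""
        rng = np.random.default_rng(13)
        n = 2000
        covariates = generate_covariates(n, seed=14)
        scores = pd.Series(rng.standard_normal(n), index=covariates.index)
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        gspec = GeneticSpec(base_rate_lambda0=26.0, target_delta_r2=0.03)
        wide = {}
        for t in (25.0, 50.0, 100.0, 200.0):
            wide[("molehill", t)] = linked_molehill_counts(
                scores.to_numpy(), gspec, rng
            )
            wide[("pothole", t)] = rng.poisson(20, size=n)
        counts = long_counts(wide, n, rng)
        out = run_global_suite(counts, covariates, scores=scores, suite="prs")
        mole = out[out.polarity == "molehill"]
        assert (mole.beta > 0).all()
        assert (mole.q < 0.05).all()

    def test_tract_suite_shape_and_handedness(self):
        rng = np.random.default_rng(15)
        n = 150
        _, atlas = toy_template((16, 16, 16))
        covariates = generate_covariates(n, seed=16)
        scores = pd.Series(rng.standard_normal(n), index=covariates.index)
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        rows = []
        for i in range(n):
            for lab in [0] + atlas.label_ids:
                rows.append(
                    {
                        "subject": f"s{i:04d}",
                        "label": lab,
                        "polarity": "molehill",
                        "min_volume_mm3": 25.0,
                        "count": rng.poisson(3),
                    }
                )
        tract_counts = pd.DataFrame(rows)
        out = run_tract_suite(tract_counts, covariates, scores, atlas)
        assert len(out) == 17
        lat = out.merge(atlas.names, on="label")
        assert (
            lat.loc[lat.laterality != "midline", "handedness_adjusted"]
        ).all()
        assert not (
            lat.loc[lat.laterality == "midline", "handedness_adjusted"]
        ).any()
        assert np.all(out.q.to_numpy() >= out.p.to_numpy() - 1e-15)

        with pytest.raises(ValueError, match="handedness"):
            run_tract_suite(
                tract_counts, covariates.drop(columns="handedness"), scores, atlas
            )
        # override proceeds without the adjustment
        out2 = run_tract_suite(
            tract_counts, covariates.drop(columns="handedness"), scores, atlas,
            allow_missing_handedness=True,
        )
        assert not out2.handedness_adjusted.any()
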