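"""Preprocessing, model-group selection, LRT/bootstrap, FDR, descriptives."""

import numpy as np
import pandas as pd
import pytest

from resilnet import design
from resilnet.cohort import CohortConfig, TrueParameters, generate_baseline, generate_longitudinal
from resilnet.inference import (
    BootstrapResult,
    ModelSpec,
    bh_fdr,
    common_resilience_terms,
    descriptives,
    enumerate_models,
    fit_lmm,
    lrt_test,
    parametric_bootstrap_p,
    preprocess,
    run_resilience_analysis,
    select_retained,
    vif,
)
from resilnet.lmm import LmmError, LmmFit


def brute_force_bh(pvals, q):
    """Independent BH oracle: maximize k over all candidates directly."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestPreprocess:
    def test_adas_inversion_and_outcome_scaling(self, small_study):
        cohort, visits, data, _ = small_study
        expected = -visits["adas_cog"].to_numpy()
        expected = (expected - expected.mean()) / expected.std(ddof=1)
        np.testing.assert_allclose(data["adas_cog_z"].to_numpy(), expected, atol=1e-12)

    def test_wmhv_log_ratio_transform(self):
        assert design.wmhv_predictor([0.5], [1.0])[0] == pytest.approx(np.log(0.5))
        with pytest.raises(ValueError, match="1 row"):
            design.wmhv_predictor([0.5, -1.0], [1.0, 1.0])

    def test_single_visit_subject_dropped_and_logged(self, small_study):
        cohort, visits, *_ = small_study
        clipped = pd.concat(
            [visits[visits["subject_id"] != "S0001"],
             visits[visits["subject_id"] == "S0001"].head(1)]
        )
        data, info = preprocess(cohort, clipped)
        assert info["dropped_subjects"] == ["S0001"]
        assert "S0001" not in set(data["subject_id"])

    def test_constant_column_rejected(self, small_study):
        cohort, visits, *_ = small_study
        bad = cohort.copy()
        bad["sne"] = 250.0
        with pytest.raises(ValueError, match="constant"):
            preprocess(bad, visits)

    def test_unknown_visit_subject_rejected(self, small_study):
        cohort, visits, *_ = small_study
        bad = visits.copy()
        bad.loc[bad.index[0], "subject_id"] = "GHOST"
        with pytest.raises(ValueError, match="unknown"):
            preprocess(cohort, bad)


class TestModelGroup:
    def test_sixteen_member_lattice(self):
        specs = enumerate_models("mmse")
        assert len(specs) == 16
        sets = {s.resilience for s in specs}
        assert frozenset() in sets
        assert frozenset(design.RESILIENCE_TERMS) in sets
        assert len(sets) == 16

    def test_marginality_children_always_present(self):
        for spec in enumerate_models("cdr_sob"):
            for term in spec.resilience:
                factors = design.term_factors(term)
                if len(factors) == 3:  # T*RES*PATH
                    path = factors[2]
                    assert f"T*{path}" in spec.terms
                    assert f"RES*{path}" in spec.terms

    def test_base_terms_identical_across_group(self):
        specs = enumerate_models("adas_cog")
        bases = {tuple(t for t in s.terms if t in design.BASE_TERMS) for s in specs}
        assert len(bases) == 1

    def test_unknown_resilience_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("mmse", frozenset({"T*T"}))


def fake_fit(caic, resilience=frozenset()):
    f = LmmFit(
        workspace=None, y=None, criterion="ML", gamma=np.zeros(2),
        beta=np.zeros(1), cov_beta=np.eye(1), sigma2_e=1.0, loglik=0.0,
        converged=True, spec=ModelSpec("mmse", frozenset(resilience)),
    )
    f.extra["caic"] = caic
    return f


class TestSelection:
    def test_delta_caic_strictly_less_than_two(self):
        fits = [fake_fit(100.0), fake_fit(101.5, {"T*RES"}), fake_fit(103.0, {"T*RES*TAU"})]
        best, retained = select_retained(fits)
        assert best is fits[0]
        assert retained == [fits[0], fits[1]]

        best, retained = select_retained([fake_fit(100.0), fake_fit(102.0, {"T*RES"})])
        assert len(retained) == 1

    def test_single_model_retained(self):
        f = fake_fit(50.0, {"T*RES"})
        best, retained = select_retained([f])
        assert best is f and retained == [f]

    def test_tie_breaks_to_fewer_resilience_terms(self):
        a = fake_fit(100.0, {"T*RES", "T*RES*AV45"})
        b = fake_fit(100.0, {"T*RES"})
        best, _ = select_retained([a, b])
        assert best is b

    def test_common_terms_intersection(self):
        fits = [
            fake_fit(0, {"T*RES", "T*RES*AV45"}),
            fake_fit(1, {"T*RES*AV45"}),
        ]
        assert common_resilience_terms(fits) == ["T*RES*AV45"]
        assert common_resilience_terms([fits[0]]) == ["T*RES", "T*RES*AV45"]
        disjoint = [fake_fit(0, {"T*RES"}), fake_fit(1, {"T*RES*TAU"})]
        assert common_resilience_terms(disjoint) == []


class TestLrt:
    def test_statistic_and_refit_guard(self, small_study):
        *_, data, _ = small_study
        full = fit_lmm(ModelSpec("cdr_sob", frozenset({"T*RES*AV45"})), data)
        reduced = fit_lmm(ModelSpec("cdr_sob", frozenset()), data)
        chi2, df, p = lrt_test(full, reduced)
        assert df == 1
        assert chi2 >= 0
        assert 0 <= p <= 1

    def test_requires_ml(self, small_study):
        *_, data, _ = small_study
        full = fit_lmm(ModelSpec("mmse", frozenset({"T*RES"})), data, criterion="REML")
        reduced = fit_lmm(ModelSpec("mmse", frozenset()), data, criterion="REML")
        with pytest.raises(LmmError, match="ML"):
            lrt_test(full, reduced)

    def test_non_nested_rejected(self, small_study):
        *_, data, _ = small_study
        a = fit_lmm(ModelSpec("mmse", frozenset({"T*RES"})), data)
        b = fit_lmm(ModelSpec("mmse", frozenset({"T*RES*TAU"})), data)
        with pytest.raises(LmmError, match="nested"):
            lrt_test(a, b)

    def test_affine_outcome_rescaling_invariance(self, small_study):
        *_, data, _ = small_study
        full_s = ModelSpec("mmse", frozenset({"T*RES"}))
        red_s = ModelSpec("mmse", frozenset())
        chi2_a, *_ = lrt_test(fit_lmm(full_s, data), fit_lmm(red_s, data))
        scaled = data.copy()
        scaled["mmse_z"] = 3.7 * scaled["mmse_z"] - 1.2
        chi2_b, *_ = lrt_test(fit_lmm(full_s, scaled), fit_lmm(red_s, scaled))
        assert chi2_b == pytest.approx(chi2_a, abs=1e-4)

    def test_asymptotic_type_one_error(self):
        """Null rejection rate of the chi-square LRT near nominal 5%."""
        cfg = CohortConfig(n_subjects=60, visit_months=(0, 12, 24, 36))
        null = TrueParameters(betas={"T": -0.3, "AV45": -0.2})
        full_s = ModelSpec("cdr_sob", frozenset({"T*RES*AV45"}))
        red_s = ModelSpec("cdr_sob", frozenset())
        rejections = 0
        n_rep = 200
        for s in range(n_rep):
            cohort = generate_baseline(cfg, seed=1000 + s)
            visits = generate_longitudinal(cohort, null, outcomes=("cdr_sob",), seed=2000 + s,
                                           visit_months=cfg.visit_months)
            data, _ = preprocess(cohort, visits)
            _, _, p = lrt_test(fit_lmm(full_s, data), fit_lmm(red_s, data))
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestBootstrap:
    def test_p_uses_plus_one_estimator_and_is_seeded(self, small_study):
        *_, data, _ = small_study
        full_s = ModelSpec("mmse", frozenset({"T*RES"}))
        red_s = ModelSpec("mmse", frozenset())
        res = parametric_bootstrap_p(full_s, red_s, data, B=49, seed=11)
        assert isinstance(res, BootstrapResult)
        assert res.p == pytest.approx((1 + res.n_exceed) / (res.n_effective + 1))
        assert 0 < res.p <= 1
        res2 = parametric_bootstrap_p(full_s, red_s, data, B=49, seed=11)
        assert res.p == res2.p and res.n_exceed == res2.n_exceed

    def test_invalid_b(self, small_study):
        *_, data, _ = small_study
        with pytest.raises(ValueError):
            parametric_bootstrap_p(
                ModelSpec("mmse", frozenset({"T*RES"})),
                ModelSpec("mmse", frozenset()), data, B=0, seed=1,
            )


class TestBhFdr:
    def test_worked_example(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.2]
        reject = bh_fdr(p, q=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, True, False])
        np.testing.assert_array_equal(reject, brute_force_bh(p, 0.05))

    def test_boundaries(self):
        np.testing.assert_array_equal(bh_fdr([0.01], 0.05), [True])
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()

    def test_matches_brute_force_and_monotone_in_q(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 12))
            r1 = bh_fdr(p, 0.05)
            np.testing.assert_array_equal(r1, brute_force_bh(p, 0.05))
            r2 = bh_fdr(p, 0.10)
            assert (r2 | ~r1).all()  # rejections grow with q

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestVif:
    def test_orthogonal_columns_are_one(self):
        from scipy.linalg import helmert

        X = np.column_stack([np.ones(8), helmert(8)[:3].T])
        v = vif(X, names=["1", "a", "b", "c"])
        assert np.allclose(v.values, 1.0, atol=1e-8)
        assert "1" not in v.index

    def test_near_collinear_explodes(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, x + rng.normal(0, 1e-3, 100)])
        assert vif(X).max() > 10

    def test_matches_independent_regression(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        X[:, 2] += 0.7 * X[:, 1]
        v = vif(X, names=["1", "a", "b", "c"])
        others = X[:, [0, 1, 3]]
        coef, *_ = np.linalg.lstsq(others, X[:, 2], rcond=None)
        resid = X[:, 2] - others @ coef
        r2 = 1 - resid.var() / X[:, 2].var()
        assert v["b"] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError):
            vif(np.column_stack([x, 2 * x]))


def cohort_with_counts(gender_cn, gender_mci, apoe_cn, apoe_mci):
    """Cohort reproducing exact 2x2 tables: (n_pos, n_neg) per group."""
    rows = []
    rng = np.random.default_rng(0)
    for status, (g1, g0), (a1, a0) in [
        ("CN", gender_cn, apoe_cn), ("MCI", gender_mci, apoe_mci)
    ]:
        n = g1 + g0
        gender = [1] * g1 + [0] * g0
        apoe = [1] * a1 + [0] * a0
        for i in range(n):
            rows.append({
                "subject_id": f"{status}{i}", "status": status,
                "gender": gender[i], "apoe4": apoe[i],
                "age": rng.normal(72, 6), "education": rng.normal(16, 2),
                "sne": rng.normal(250, 17), "av45": rng.normal(1.2, 0.2),
                "tau": rng.normal(80, 20), "wmhv": rng.normal(0.5, 0.1),
                "tiv": 1400.0,
            })
    return pd.DataFrame(rows)


class TestDescriptives:
    def test_gender_table_chi_squared(self):
        cohort = cohort_with_counts((18, 16), (16, 35), (25, 9), (16, 35))
        table = descriptives(cohort)
        p_gender = table.set_index("variable").loc["gender", "p_value"]
        assert p_gender == pytest.approx(0.078, abs=5e-4)
        p_apoe = table.set_index("variable").loc["apoe4", "p_value"]
        assert p_apoe < 0.001

    def test_identical_groups_mann_whitney_p_one(self):
        cohort = cohort_with_counts((10, 10), (10, 10), (5, 15), (5, 15))
        cohort.loc[cohort["status"] == "MCI", "age"] = (
            cohort.loc[cohort["status"] == "CN", "age"].to_numpy()
        )
        table = descriptives(cohort).set_index("variable")
        assert table.loc["age", "p_value"] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        cohort = cohort_with_counts((1, 0), (10, 10), (1, 0), (5, 15))
        with pytest.raises(ValueError):
            descriptives(cohort)


class TestRunAnalysis:
    def test_structure_and_determinism(self, small_study):
        cohort, visits, *_ = small_study
        rep1 = run_resilience_analysis(cohort, visits, B=19, seed=42)
        rep2 = run_resilience_analysis(cohort, visits, B=19, seed=42)
        pd.testing.assert_frame_equal(rep1.table, rep2.table)
        assert set(rep1.table["outcome"]) <= set(design.OUTCOMES)
        assert len(rep1.table) <= 12  # 3 outcomes x up to 4 terms
        assert set(rep1.marginal_r2) == set(design.OUTCOMES)
        for r2 in rep1.marginal_r2.values():
            assert 0 <= r2 <= 1
        for v in rep1.vif.values():
            assert (v > 0).all()
        assert rep1.table["p_lrt"].between(0, 1).all()
        assert rep1.table["p_boot"].between(0, 1).all()

    def test_report_serialization(self, small_study, tmp_path):
        cohort, visits, *_ = small_study
        rep = run_resilience_analysis(cohort, visits, outcomes=("mmse",), B=9, seed=3)
        rep.to_json(tmp_path / "r.json")
        rep.to_tsv(tmp_path / "r.tsv")
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert "results" in payload and "marginal_r2" in payload
        assert (tmp_path / "r.tsv").read_text().startswith("outcome\t")
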