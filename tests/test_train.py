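"""Splitting, elastic-net fitting, Brownian covariance, PGLS calibration."""

import json

import numpy as np
import pandas as pd
import pytest

from cpgclock import (
    ClockModel,
    PhyloCovariance,
    SpeciesRecord,
    TrainingConfig,
    assemble_clock,
    covariance_from_divergence,
    fit_elastic_net,
    fit_pgls_calibration,
    load_published_clock,
    raw_score,
    split_train_test,
    train_clock,
)
from cpgclock.train import elastic_net_path_nonzeros


def _records(counts: dict[str, int]) -> list[SpeciesRecord]:
    out = []
    for cls, n in counts.items():
        for i in range(n):
            out.append(SpeciesRecord(f"{cls[:2]}{i}", cls, 10.0 + i))
    return out


class TestSplitTrainTest:
    def test_stratified_counts(self):
        recs = _records({"Mammalia": 10, "Aves": 10})
        train, test = split_train_test(recs, TrainingConfig(seed=3))
        assert len(train) == 14 and len(test) == 6
        for cls in ("Mammalia", "Aves"):
            assert sum(s.startswith(cls[:2]) for s in train) == 7

    def test_seed_reproducibility(self):
        recs = _records({"Mammalia": 20, "Fish": 15})
        assert split_train_test(recs, TrainingConfig(seed=5)) == \
            split_train_test(recs, TrainingConfig(seed=5))
        assert split_train_test(recs, TrainingConfig(seed=5)) != \
            split_train_test(recs, TrainingConfig(seed=6))

    def test_partition_is_disjoint_and_exhaustive(self):
        recs = _records({"Mammalia": 13, "Aves": 7, "Fish": 5})
        train, test = split_train_test(recs, TrainingConfig(seed=1))
        assert set(train) | set(test) == {r.species_id for r in recs}
        assert not set(train) & set(test)

    def test_study_scale_class_sizes_give_176_76(self):
        recs = _records({"Mammalia": 100, "Aves": 80, "Fish": 40,
                         "Reptilia": 20, "Amphibia": 12})
        train, test = split_train_test(recs, TrainingConfig(seed=0))
        assert (len(train), len(test)) == (176, 76)

    def test_singleton_class_goes_to_training_with_warning(self):
        recs = _records({"Mammalia": 6, "Amphibia": 1})
        with pytest.warns(UserWarning, match="Amphibia"):
            train, _ = split_train_test(recs, TrainingConfig(seed=0))
        assert "Am0" in train


def _design(n=20, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"p{j}" for j in range(p)])
    beta = np.array([1.5, -2.0, 0.5][:p])
    y = 0.3 + X.to_numpy() @ beta + rng.normal(0, 0.1, n)
    return X, y


class TestFitElasticNet:
    def test_large_lambda_full_shrinkage(self):
        X, y = _design()
        w, w0, _ = fit_elastic_net(X, y, TrainingConfig(), fixed_lambda=1e6)
        assert w == {}
        assert w0 == pytest.approx(np.mean(y), abs=1e-10)

    def test_lambda_zero_matches_normal_equations(self):
        X, y = _design()
        w, w0, _ = fit_elastic_net(X, y, TrainingConfig(), fixed_lambda=0.0)
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)  # independent OLS oracle
        assert w0 == pytest.approx(beta[0], abs=1e-6)
        for j, col in enumerate(X.columns):
            assert w.get(col, 0.0) == pytest.approx(beta[j + 1], abs=1e-6)

    def test_univariate_lasso_soft_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x + rng.normal(0, 0.5, 50)
        lam = 0.3
        X = pd.DataFrame({"p0": x})
        cfg = TrainingConfig(alpha=1.0)
        w, w0, _ = fit_elastic_net(X, y, cfg, fixed_lambda=lam)
        rho = float(np.mean(x * (y - y.mean())))
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0)  # closed-form lasso
        assert w.get("p0", 0.0) == pytest.approx(expected, abs=1e-8)
        assert w0 == pytest.approx(y.mean(), abs=1e-8)

    def test_constant_response_errors(self):
        X, _ = _design()
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(len(X)), TrainingConfig())

    def test_fewer_rows_than_folds_errors(self):
        X, y = _design(n=5)
        with pytest.raises(ValueError):
            fit_elastic_net(X, y, TrainingConfig(cv_folds=10))

    def test_nonzero_count_non_increasing_in_lambda(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        y = X.iloc[:, 0] * 2 - X.iloc[:, 3] + rng.normal(0, 0.5, 60)
        path = elastic_net_path_nonzeros(X, y.to_numpy(), TrainingConfig(), n_lambdas=15)
        lams, counts = zip(*path)
        assert all(l1 >= l2 for l1, l2 in zip(lams, lams[1:]))  # descending path
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))


class TestRawScore:
    def test_hand_arithmetic(self):
        model = ClockModel({"p1": 2.0}, 1.0, 0.1, 0.0, 1.0, {})
        assert raw_score(model, {"p1": 0.25}) == pytest.approx(1.5)

    def test_all_zero_densities_give_intercept(self):
        model = ClockModel({"p1": 2.0, "p2": -1.0}, 0.7, 0.1, 0.0, 1.0, {})
        assert raw_score(model, {}) == pytest.approx(0.7)

    def test_bilinearity(self):
        model_a = ClockModel({"p1": 2.0, "p2": 4.0}, 0.0, 0.1, 0.0, 1.0, {})
        model_b = ClockModel({"p1": 4.0, "p2": 8.0}, 0.0, 0.1, 0.0, 1.0, {})
        d = {"p1": 0.2, "p2": 0.1}
        half = {k: v / 2 for k, v in d.items()}
        assert raw_score(model_a, d) == pytest.approx(raw_score(model_b, half))


class TestCovarianceFromDivergence:
    def test_two_species(self):
        df = pd.DataFrame([[0.0, 100.0], [100.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        cov = covariance_from_divergence(df)
        assert np.allclose(cov.V, [[100, 0], [0, 100]])

    def test_star_phylogeny(self):
        n = 4
        t = np.full((n, n), 80.0)
        np.fill_diagonal(t, 0.0)
        ids = list("abcd")
        cov = covariance_from_divergence(pd.DataFrame(t, index=ids, columns=ids))
        assert np.allclose(cov.V, 80.0 * np.eye(n))

    def test_cherry_tree_from_newick(self):
        cov = covariance_from_divergence("((A:50,B:50):50,C:100);")
        i = {s: k for k, s in enumerate(cov.species_ids)}
        assert cov.V[i["A"], i["B"]] == pytest.approx(50.0)
        assert cov.V[i["A"], i["A"]] == pytest.approx(100.0)
        assert cov.V[i["A"], i["C"]] == pytest.approx(0.0)

    def test_asymmetric_matrix_errors(self):
        t = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            covariance_from_divergence(t)

    def test_negative_times_error(self):
        t = pd.DataFrame([[0.0, -1.0], [-1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            covariance_from_divergence(t)


class TestFitPglsCalibration:
    def test_identity_covariance_equals_ols(self, rng):
        n = 40
        x = rng.normal(size=n)
        classes = ["Mammalia"] * 20 + ["Aves"] * 20
        y = 1.0 + 2.0 * x + np.array([0.5 if c == "Aves" else 0.0 for c in classes])
        y += rng.normal(0, 0.3, n)
        c0, c1, coeffs = fit_pgls_calibration(x, y, classes, cov=np.eye(n),
                                              reference_class="Mammalia")
        # independent OLS oracle via normal equations
        ind = np.array([float(c == "Aves") for c in classes])
        A = np.column_stack([np.ones(n), x, ind, ind * x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert c0 == pytest.approx(beta[0], abs=1e-8)
        assert c1 == pytest.approx(beta[1], abs=1e-8)
        assert coeffs["Aves"][1] == pytest.approx(beta[2], abs=1e-8)  # b
        assert coeffs["Aves"][0] == pytest.approx(beta[3], abs=1e-8)  # a

    def test_exact_linear_single_class(self):
        x = np.linspace(-1, 2, 10)
        y = 2 * x + 1
        c0, c1, coeffs = fit_pgls_calibration(x, y, ["Mammalia"] * 10)
        assert c0 == pytest.approx(1.0, abs=1e-8)
        assert c1 == pytest.approx(2.0, abs=1e-8)
        assert coeffs == {}

    def test_constant_score_class_errors_naming_class(self, rng):
        x = np.concatenate([rng.normal(size=5), np.zeros(5)])
        classes = ["Mammalia"] * 5 + ["Fish"] * 5
        with pytest.raises(ValueError, match="Fish"):
            fit_pgls_calibration(x, rng.normal(size=10), classes,
                                 reference_class="Mammalia")

    def test_singleton_reference_class_is_re_referenced(self, rng):
        """One reference-class member makes [1, x] collinear with the class
        dummies; the fit must re-reference instead of failing."""
        x = rng.normal(size=11)
        classes = ["Amphibia"] + ["Mammalia"] * 5 + ["Aves"] * 5
        y = 1.0 + 2.0 * x + rng.normal(0, 0.2, 11)
        with pytest.warns(UserWarning, match="re-referencing"):
            c0, c1, coeffs = fit_pgls_calibration(x, y, classes,
                                                  reference_class="Amphibia")
        assert "Mammalia" not in coeffs  # largest class became the reference
        assert "Aves" in coeffs
        assert c1 == pytest.approx(2.0, abs=1.0)

    def test_brownian_recovery_within_three_se(self):
        """Planted class offsets are recovered within 3 SE on Brownian data."""
        from cpgclock.simulate import simulate_tree

        rng = np.random.default_rng(99)
        hits = total = 0
        for rep in range(20):
            newick = simulate_tree(40, seed=rep)
            cov = covariance_from_divergence(newick)
            n = len(cov.species_ids)
            x = rng.normal(1.0, 0.8, n)
            classes = ["Mammalia"] * (n // 2) + ["Aves"] * (n - n // 2)
            a_true, b_true = 0.6, -0.4
            ind = np.array([float(c == "Aves") for c in classes])
            noise = rng.multivariate_normal(np.zeros(n), 0.002 * cov.V)
            y = 1.0 + 2.0 * x + a_true * ind * x + b_true * ind + noise
            _, _, coeffs = fit_pgls_calibration(
                x, y, classes, cov=cov.V, reference_class="Mammalia")
            # standard errors from the GLS closed form (independent of the fit)
            A = np.column_stack([np.ones(n), x, ind, ind * x])
            Vi = np.linalg.inv(cov.V)
            C = np.linalg.inv(A.T @ Vi @ A)
            resid = y - A @ np.linalg.solve(A.T @ Vi @ A, A.T @ Vi @ y)
            sigma2 = float(resid @ Vi @ resid) / (n - 4)
            se_b, se_a = np.sqrt(sigma2 * np.diag(C))[2:4]
            a_hat, b_hat = coeffs["Aves"]
            hits += abs(a_hat - a_true) <= 3 * se_a
            hits += abs(b_hat - b_true) <= 3 * se_b
            total += 2
        assert hits / total >= 0.95


class TestClockModelSerialization:
    def test_published_clock_loads_table_values(self):
        model = load_published_clock()
        assert model.global_intercept == -4.38996
        assert model.global_slope == 2.57328
        assert model.class_ab("Mammalia") == (-0.92888, 2.33508)
        assert model.class_ab("Fish") == (2.14632, -6.58228)
        assert model.class_ab("Aves") == (-0.90323, 2.14857)
        assert model.class_ab("Reptilia") == (-0.48958, 1.17281)
        assert model.class_ab("Amphibia") == (0.0, 0.0)

    def test_json_round_trip_bit_identical(self, tmp_path):
        model = assemble_clock(
            {"p1": 0.123456789012345, "p2": -3.3e-7}, 1.25, 0.16539,
            (-4.38996, 2.57328, {"Mammalia": (-0.92888, 2.33508)}),
            promoter_order=["p1", "p2", "p3"],
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ClockModel.from_json(path)
        assert loaded == model
        path2 = tmp_path / "model2.json"
        loaded.to_json(path2)
        assert path.read_text() == path2.read_text()

    def test_empty_weight_map_predicts_from_intercept(self):
        model = assemble_clock({}, 0.5, 1.0, (0.0, 1.0, {}))
        assert raw_score(model, {"p9": 0.3}) == 0.5


def test_train_clock_on_small_panel(small_panel):
    cfg = TrainingConfig(seed=2, cv_folds=4)
    model, train_ids, test_ids = train_clock(
        small_panel.density_matrix, small_panel.records, small_panel.tree, cfg
    )
    assert not set(train_ids) & set(test_ids)
    assert set(train_ids) | set(test_ids) == set(small_panel.density_matrix.species_ids)
    assert model.selected_lambda > 0
    assert all(w != 0 for w in model.promoter_weights.values())
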