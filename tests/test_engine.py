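import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

import intermed as im
from intermed.engine import CounterfactualSpec, counterfactual_mean, decompose_effects, expand_dataset
from intermed.models import FittedOutcomeModel

from helpers import ToyModels, ToyOutcome, enumerate_decomposition, enumerate_mean


class TestExpandDataset:
    def test_row_counting(self, small_dataset):
        df = small_dataset.df.head(3)
        out = expand_dataset(df, 4)
        assert len(out) == 12
        assert (out.groupby("_orig_row").size() == 4).all()
        assert (out["_rep"].to_numpy()[:4] == [0, 1, 2, 3]).all()

    def test_k1_is_identity_sized(self, small_dataset):
        out = expand_dataset(small_dataset.df, 1)
        assert len(out) == len(small_dataset.df)

    def test_full_scale_expansion_count(self, small_dataset):
        # a study-sized dataset expanded 1000-fold
        n = len(small_dataset.df)
        out = expand_dataset(small_dataset.df, 1000)
        assert len(out) == n * 1000

    def test_memory_guard(self, small_dataset):
        with pytest.raises(MemoryError, match="row budget"):
            expand_dataset(small_dataset.df, 10, row_budget=100)

    def test_k_must_be_positive(self, small_dataset):
        with pytest.raises(ValueError):
            expand_dataset(small_dataset.df, 0)


class TestCounterfactualSpec:
    def test_joint_requires_equal_sources(self):
        with pytest.raises(ValueError, match="joint"):
            CounterfactualSpec(1, 1, 0, 1, "joint")

    def test_levels_validated(self):
        with pytest.raises(ValueError):
            CounterfactualSpec(2, 1, 1, 1, "joint")


def _intercept_only_outcome():
    return FittedOutcomeModel(
        result=SimpleNamespace(params=np.array([0.0])),
        terms=[],
        column_names=["intercept"],
        outcome="y",
    )


class TestCounterfactualMean:
    def test_constant_model_gives_half(self, fitted_models, small_dataset):
        ex = expand_dataset(small_dataset.df, 5)
        om = _intercept_only_outcome()
        for spec in (
            CounterfactualSpec(1, 1, 1, 1, "joint"),
            CounterfactualSpec(0, 0, 0, 0, "joint"),
            CounterfactualSpec(1, 1, 0, 1, "marginal"),
        ):
            m = counterfactual_mean(ex, fitted_models, om, spec, np.random.default_rng(1))
            assert m == pytest.approx(0.5, abs=1e-12)

    def test_deterministic_under_seed(self, fitted_models, fitted_outcome, small_dataset):
        ex = expand_dataset(small_dataset.df, 20)
        spec = CounterfactualSpec(1, 1, 1, 1, "joint")
        a = counterfactual_mean(ex, fitted_models, fitted_outcome, spec, np.random.default_rng(9))
        b = counterfactual_mean(ex, fitted_models, fitted_outcome, spec, np.random.default_rng(9))
        assert a == b

    def test_matches_enumeration_on_toy(self):
        models = ToyModels()
        outcome = ToyOutcome()
        xs = np.array([0.0] * 6 + [1.0] * 4)  # empirical covariate rows
        df = pd.DataFrame({"x": np.repeat(xs, 2000)})
        rng = np.random.default_rng(33)
        for sources, mode, a_y in [
            ((1, 1, 1), "joint", 1),
            ((0, 0, 0), "joint", 0),
            ((1, 0, 1), "marginal", 1),
            ((0, 1, 0), "marginal", 1),
        ]:
            spec = CounterfactualSpec(a_y, *sources, mode)
            got = counterfactual_mean(df, models, outcome, spec, rng)
            want = enumerate_mean(models, outcome, xs, a_y, sources, mode)
            assert abs(got - want) < 0.01, (sources, mode)


class TestDecomposition:
    def test_exact_additivity(self, fitted_models, fitted_outcome, small_dataset):
        for seed in (0, 1, 2):
            dec = decompose_effects(
                small_dataset, fitted_models, fitted_outcome,
                k_copies=40, rng=np.random.default_rng(seed),
            )
            assert dec.additivity_gap() <= 1e-12

    def test_blocked_mediation_gives_zero_indirect(self, fitted_models, small_dataset, confounders):
        # outcome model with mediator coefficients forced to zero
        fitted = im.fit_outcome_model(small_dataset, confounders, ())
        params = np.asarray(fitted.result.params).copy()
        for term in ("m1", "m2_1", "m2_2", "m3"):
            params[fitted.column_names.index(term)] = 0.0
        blocked = FittedOutcomeModel(
            result=SimpleNamespace(params=params),
            terms=fitted.terms,
            column_names=fitted.column_names,
            outcome="y",
        )
        dec = decompose_effects(
            small_dataset, fitted_models, blocked, k_copies=30,
            rng=np.random.default_rng(4),
        )
        assert dec.ie_m1 == 0.0 and dec.ie_m2 == 0.0 and dec.ie_m3 == 0.0
        assert dec.ie_dep == pytest.approx(0.0, abs=1e-15)
        assert dec.te == pytest.approx(dec.de, abs=1e-15)

    def test_monte_carlo_error_shrinks_with_k(self, fitted_models, fitted_outcome, small_dataset):
        # component SD across repeated runs should scale roughly as 1/sqrt(K)
        def spread(k, reps=12):
            vals = [
                decompose_effects(
                    small_dataset, fitted_models, fitted_outcome, k_copies=k,
                    rng=np.random.default_rng(100 + r),
                ).ie_m2
                for r in range(reps)
            ]
            return np.std(vals)

        s50, s200, s800 = spread(50), spread(200), spread(800)
        assert s800 < s200 < s50  # monotone shrinkage in K
        assert 1.5 < s50 / s800 < 11  # sqrt(16) = 4 expected, wide guard band

    def test_dependence_vanishes_without_dependence(self):
        # generator with no M1->M2 link and no outcome interactions, fitted
        # with a main-effects outcome model: DEP should be MC-level noise
        cfg = im.default_config(seed=55, n_lima=800, n_saopaulo=1200)
        cfg.m2_coefs = {
            "cat1": dict(cfg.m2_coefs["cat1"], m1=0.0),
            "cat2": dict(cfg.m2_coefs["cat2"], m1=0.0),
        }
        cfg.m3_coefs = dict(cfg.m3_coefs, m1=0.0, m2_1=0.0, m2_2=0.0)
        cfg.y_coefs = {
            k: v for k, v in cfg.y_coefs.items() if ":" not in k
        }
        cc = im.complete_case_filter(im.from_frame(im.generate_trial(cfg, seed=55)))
        confs = ["phq9_baseline", "medication", "site"]
        models = im.fit_mediator_models(cc, confs)
        outcome = im.fit_outcome_model(cc, confs, ())
        dec = decompose_effects(
            cc, models, outcome, k_copies=300, rng=np.random.default_rng(5)
        )
        assert abs(dec.ie_dep) < 0.01

    def test_toy_decomposition_matches_enumeration(self):
        models = ToyModels()
        outcome = ToyOutcome()
        xs = np.array([0.0] * 5 + [1.0] * 5)
        df = pd.DataFrame({"x": xs})
        dec = decompose_effects(
            df, models, outcome, k_copies=4000, rng=np.random.default_rng(21)
        )
        exact = enumerate_decomposition(models, outcome, xs)
        for name, want in exact.items():
            assert abs(dec.components()[name] - want) < 0.012, name

    def test_order_is_configurable_and_reported(self, fitted_models, fitted_outcome, small_dataset):
        dec = decompose_effects(
            small_dataset, fitted_models, fitted_outcome, k_copies=30,
            rng=np.random.default_rng(8), order=("m3", "m1", "m2"),
        )
        assert dec.order == ("m3", "m1", "m2")
        assert dec.additivity_gap() <= 1e-12
        with pytest.raises(ValueError, match="permutation"):
            decompose_effects(
                small_dataset, fitted_models, fitted_outcome, k_copies=5,
                rng=np.random.default_rng(8), order=("m1", "m1", "m2"),
            )

    def test_row_budget_guard(self, fitted_models, fitted_outcome, small_dataset):
        with pytest.raises(MemoryError):
            decompose_effects(
                small_dataset, fitted_models, fitted_outcome,
                k_copies=1000, rng=np.random.default_rng(1), row_budget=1000,
            )
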