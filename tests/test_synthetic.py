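import numpy as np
import pytest

import intermed as im
from intermed.synthetic import _DEFAULT_COVARIATES


class TestGenerateTrial:
    def test_same_config_same_seed_identical(self, small_config):
        a = im.generate_trial(small_config, seed=5)
        b = im.generate_trial(small_config, seed=5)
        assert a.equals(b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_design_structure(self, small_config):
        df = im.generate_trial(small_config, seed=1)
        lima = df[df.site == "lima"]
        sp = df[df.site == "saopaulo"]
        # individually randomized site: singleton clusters, 1:1 allocation
        assert lima.cluster_id.nunique() == len(lima)
        assert abs(lima.arm.sum() - len(lima) / 2) <= 0.5
        # cluster randomized site: 20 clusters, arm constant within cluster
        assert sp.cluster_id.nunique() == small_config.n_clusters_saopaulo
        assert (sp.groupby("cluster_id").arm.nunique() == 1).all()
        # intervention-arm-only mediators at the unexposed level under control
        ctrl = df[df.arm == 0]
        assert (ctrl.m1 == 0).all() and (ctrl.m2 == 0).all()
        # outcome consistent with the back-filled six-month PHQ-9
        improved = (df.phq9_baseline - df.phq9_6m) >= 0.5 * df.phq9_baseline
        assert (df.y == improved.astype(int)).all()
        assert (df.y_sens == (df.phq9_6m < 10).astype(int)).all()

    def test_m1_marginal_matches_calibration(self):
        cfg = im.default_config(seed=8, n_lima=10000, n_saopaulo=10000)
        df = im.generate_trial(cfg, seed=8)
        interv = df[df.arm == 1]
        n = len(interv)
        assert n >= 10000
        p_hat = interv.m1.mean()
        se = np.sqrt(0.775 * 0.225 / n)
        assert abs(p_hat - 0.775) < 3 * se

    def test_generated_marginals_match_config(self):
        cfg = im.default_config(seed=9, n_lima=5000, n_saopaulo=5000)
        df = im.generate_trial(cfg, seed=9)
        for name, spec in _DEFAULT_COVARIATES.items():
            if spec["dist"] == "bernoulli":
                se = np.sqrt(spec["p"] * (1 - spec["p"]) / len(df))
                assert abs(df[name].mean() - spec["p"]) < 4 * se
            else:
                # the truncated-mean target; rounding contributes < 0.05
                se = df[name].std(ddof=1) / np.sqrt(len(df))
                assert abs(df[name].mean() - spec["target"]) < 4 * se + 0.05

    def test_null_config_has_no_arm_difference(self):
        cfg = im.null_config(seed=10, n_lima=8000, n_saopaulo=8000)
        df = im.generate_trial(cfg, seed=10)
        p1 = df[df.arm == 1].y.mean()
        p0 = df[df.arm == 0].y.mean()
        se = np.sqrt(p1 * (1 - p1) / (df.arm == 1).sum() + p0 * (1 - p0) / (df.arm == 0).sum())
        assert abs(p1 - p0) < 3 * se

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(n_lima=0),
            dict(n_saopaulo=-5),
            dict(n_clusters_saopaulo=1),
            dict(n_saopaulo=10, n_clusters_saopaulo=20),
            dict(cluster_sd=-0.1),
            dict(m3_sd=0.0),
            dict(m3_kind="weird"),
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            im.default_config(seed=0, **overrides)


class TestOracle:
    def test_null_model_truth_is_zero(self):
        truth = im.oracle_true_effects(im.null_config(seed=3), n_oracle=200_000)
        for name, value in truth.components().items():
            assert abs(value) < 4 * max(truth.mc_error[name], 1e-12), name

    def test_blocked_mediation_truth(self):
        cfg = im.default_config(seed=4)
        cfg.y_coefs = {
            k: v
            for k, v in cfg.y_coefs.items()
            if not any(m in k for m in ("m1", "m2", "m3"))
        }
        truth = im.oracle_true_effects(cfg, n_oracle=200_000)
        for name in ("ie_m1", "ie_m2", "ie_m3", "ie_dep"):
            assert abs(getattr(truth, name)) < 4 * max(truth.mc_error[name], 1e-12)
        # total reduces to the direct arm effect, which is nonzero here
        assert truth.te < -0.05

    def test_truth_additivity(self):
        truth = im.oracle_true_effects(im.default_config(seed=5), n_oracle=200_000)
        gap = abs(
            truth.de + truth.ie_m1 + truth.ie_m2 + truth.ie_m3 + truth.ie_dep - truth.te
        )
        assert gap <= 4 * max(truth.mc_error.values())

    def test_oracle_matches_exact_enumeration_on_discrete_instance(self):
        # fully discrete variant: two binary covariates, binary M3, no clusters
        cfg = im.SyntheticConfig(
            n_lima=100,
            n_saopaulo=100,
            n_clusters_saopaulo=4,
            cluster_sd=0.0,
            covariate_params={
                "medication": {"dist": "bernoulli", "p": 0.4},
                "friends": {"dist": "bernoulli", "p": 0.7},
            },
            m1_coefs={"intercept": 0.2, "medication": 0.6},
            m2_coefs={
                "cat1": {"intercept": 0.1, "m1": 0.8, "friends": 0.3},
                "cat2": {"intercept": -0.5, "m1": 1.1, "medication": 0.4},
            },
            m3_coefs={"intercept": -0.3, "arm": 0.5, "m1": 0.6, "m2_1": 0.4, "m2_2": 0.9},
            m3_kind="binary",
            y_coefs={
                "intercept": -0.4,
                "arm": 0.3,
                "m1": 0.5,
                "m2_1": 0.3,
                "m2_2": 0.7,
                "m3": 0.6,
                "medication": 0.5,
                "m1:m3": 0.3,
            },
            seed=0,
        )
        truth = im.oracle_true_effects(cfg, n_oracle=400_000, seed=77)
        exact = _enumerate_structural_truth(cfg)
        for name, value in exact.items():
            got = truth.components()[name]
            tol = 3 * max(truth.mc_error[name], 1e-12)
            assert abs(got - value) < tol, (name, got, value, tol)

    def test_write_truth_roundtrip(self, tmp_path):
        truth = im.oracle_true_effects(im.null_config(seed=1), n_oracle=100_000)
        path = tmp_path / "truth.txt"
        im.synthetic.write_truth(truth, path)
        text = path.read_text()
        assert "te = " in text and "n_oracle = " in text


def _enumerate_structural_truth(cfg):
    """Exact decomposition by summing over all covariate/mediator combos.

    Independent re-implementation of the estimand definitions by brute
    enumeration (only valid for bernoulli covariates, binary M3, no
    cluster effects).
    """
    from itertools import product

    from scipy.special import expit

    from intermed._design import linear_predictor

    cov_names = list(cfg.covariate_params)
    cov_probs = [cfg.covariate_params[c]["p"] for c in cov_names]

    def lp(coefs, **vals):
        data = {k: np.array([float(v)]) for k, v in vals.items()}
        return float(linear_predictor(coefs, data)[0])

    def p_m1(cv):
        return expit(lp(cfg.m1_coefs, **cv))

    def p_m2(cv, m1):
        e1 = np.exp(lp(cfg.m2_coefs["cat1"], m1=m1, **cv))
        e2 = np.exp(lp(cfg.m2_coefs["cat2"], m1=m1, **cv))
        return np.array([1, e1, e2]) / (1 + e1 + e2)

    def p_m3(cv, a, m1, m2):
        return expit(lp(cfg.m3_coefs, arm=a, m1=m1, m2=m2, **cv))

    def p_y(cv, a, m1, m2, m3):
        return expit(lp(cfg.y_coefs, arm=a, m1=m1, m2=m2, m3=m3, **cv))

    def m1_dist(cv, s):
        return {1: p_m1(cv), 0: 1 - p_m1(cv)} if s == 1 else {0: 1.0}

    def m2_joint_dist(cv, s, m1):
        if s == 0:
            return {0: 1.0}
        p = p_m2(cv, m1)
        return {j: p[j] for j in range(3)}

    def m2_marg_dist(cv, s):
        if s == 0:
            return {0: 1.0}
        acc = {0: 0.0, 1: 0.0, 2: 0.0}
        for m1, pm1 in m1_dist(cv, 1).items():
            p = p_m2(cv, m1)
            for j in range(3):
                acc[j] += pm1 * p[j]
        return acc

    def m3_joint_dist(cv, s, m1, m2):
        p = p_m3(cv, s, m1, m2)
        return {1: p, 0: 1 - p}

    def m3_marg_dist(cv, s):
        acc = {0: 0.0, 1: 0.0}
        for m1, pm1 in m1_dist(cv, s).items():
            for m2, pm2 in m2_joint_dist(cv, s, m1).items():
                p = p_m3(cv, s, m1, m2)
                acc[1] += pm1 * pm2 * p
                acc[0] += pm1 * pm2 * (1 - p)
        return acc

    def mean(a_y, sources, mode):
        total = 0.0
        for combo in product([0, 1], repeat=len(cov_names)):
            w = np.prod([p if v else 1 - p for v, p in zip(combo, cov_probs)])
            cv = dict(zip(cov_names, combo))
            s1, s2, s3 = sources
            for m1, pm1 in m1_dist(cv, s1).items():
                if mode == "joint":
                    d2 = m2_joint_dist(cv, s2, m1)
                else:
                    d2 = m2_marg_dist(cv, s2)
                for m2, pm2 in d2.items():
                    if mode == "joint":
                        d3 = m3_joint_dist(cv, s3, m1, m2)
                    else:
                        d3 = m3_marg_dist(cv, s3)
                    for m3, pm3 in d3.items():
                        total += w * pm1 * pm2 * pm3 * p_y(cv, a_y, m1, m2, m3)
        return total

    p11 = mean(1, (1, 1, 1), "joint")
    p00 = mean(0, (0, 0, 0), "joint")
    p10 = mean(1, (0, 0, 0), "joint")
    m000 = mean(1, (0, 0, 0), "marginal")
    m100 = mean(1, (1, 0, 0), "marginal")
    m110 = mean(1, (1, 1, 0), "marginal")
    m111 = mean(1, (1, 1, 1), "marginal")
    ie1, ie2, ie3 = m100 - m000, m110 - m100, m111 - m110
    return {
        "te": p11 - p00,
        "de": p10 - p00,
        "ie_m1": ie1,
        "ie_m2": ie2,
        "ie_m3": ie3,
        "ie_dep": (p11 - p10) - (ie1 + ie2 + ie3),
    }
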