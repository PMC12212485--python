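"""Independent oracles for the test suite.

``ToyModels`` / ``ToyOutcome`` form a fully discrete mediation instance
(one binary covariate, binary M1, 3-level M2, *binary* M3) with known
coefficient tables, implementing the same sampler/evaluator protocol the
engine consumes.  ``enumerate_mean`` computes every counterfactual mean by
exact summation over all covariate/mediator combinations — no Monte Carlo
— so the engine's expanded-dataset estimator can be checked against closed
arithmetic.  The enumeration code shares nothing with the engine's
sampling path.
"""

import numpy as np
from scipy.special import expit


class ToySampler:
    def __init__(self, models, x):
        self.m = models
        self.x = np.asarray(x, dtype=float)

    def draw_m1(self, idx, u1, source):
        if source == 0:
            return np.zeros(len(idx))
        return (u1 < self.m.p1(self.x[idx])).astype(float)

    def draw_m2(self, idx, u2, source, mode, m1=None):
        if source == 0:
            return np.zeros(len(idx))
        if mode == "marginal":
            probs = self.m.p2_marginal(self.x[idx])
        else:
            probs = self.m.p2_joint(self.x[idx], m1)
        cum = np.cumsum(probs, axis=1)
        return (u2[:, None] > cum[:, :2]).sum(axis=1).astype(float)

    def draw_m3(self, idx, u3, source, mode, m1=None, m2=None):
        if mode == "marginal":
            p = self.m.p3_marginal(self.x[idx], source)
        else:
            p = self.m.p3_joint(self.x[idx], source, m1, m2)
        return (u3 < p).astype(float)


class ToyModels:
    """Known discrete mediator models over one binary covariate x."""

    def __init__(self):
        self.a = (-0.3, 0.8)            # m1 logit: a0 + a1 x
        self.b1 = (0.2, 0.5, 0.9)       # m2 cat1 logit: b0 + b1 x + b2 m1
        self.b2 = (-0.6, 0.4, 1.1)      # m2 cat2 logit
        self.q = (0.15, 0.30)           # m2 marginal P(cat1), P(cat2) shift with x
        self.c_joint = (-0.4, 0.5, 0.6, 0.3, 0.7, 0.4)   # m3 | x, a, m1, m2_1, m2_2
        self.c_marg = (-0.1, 0.4, 0.9)  # m3 marginal: c0 + c1 x + c2 a

    def p1(self, x):
        return expit(self.a[0] + self.a[1] * x)

    def p2_joint(self, x, m1):
        e1 = np.exp(self.b1[0] + self.b1[1] * x + self.b1[2] * m1)
        e2 = np.exp(self.b2[0] + self.b2[1] * x + self.b2[2] * m1)
        den = 1 + e1 + e2
        return np.column_stack([1 / den, e1 / den, e2 / den])

    def p2_marginal(self, x):
        p1c = self.q[0] + 0.10 * x
        p2c = self.q[1] + 0.05 * x
        return np.column_stack([1 - p1c - p2c, p1c, p2c])

    def p3_joint(self, x, a, m1, m2):
        c0, cx, ca, cm1, c21, c22 = self.c_joint
        return expit(c0 + cx * x + ca * a + cm1 * m1 + c21 * (m2 == 1) + c22 * (m2 == 2))

    def p3_marginal(self, x, a):
        c0, cx, ca = self.c_marg
        return expit(c0 + cx * x + ca * a)

    def sampler(self, df):
        return ToySampler(self, np.asarray(df["x"], dtype=float))


class ToyOutcome:
    """Known logistic outcome model with an m1*m3 interaction."""

    coef = dict(intercept=-0.2, arm=0.4, m1=0.5, m2_1=0.3, m2_2=0.8, m3=0.6,
                x=0.5, m1_m3=0.4)

    def prob_scalar(self, x, a_y, m1, m2, m3):
        c = self.coef
        return expit(
            c["intercept"] + c["arm"] * a_y + c["m1"] * m1 + c["m2_1"] * (m2 == 1)
            + c["m2_2"] * (m2 == 2) + c["m3"] * m3 + c["x"] * x
            + c["m1_m3"] * m1 * m3
        )

    def evaluator(self, df):
        outer = self
        x = np.asarray(df["x"], dtype=float)

        class _Ev:
            def prob(self, idx, a_y, m1, m2, m3):
                return outer.prob_scalar(x[idx], a_y, m1, m2, m3)

        return _Ev()


def regime_distribution(models, x, sources, mode):
    """Exact P(m1, m2, m3) for one covariate value under one regime."""
    s1, s2, s3 = sources
    out = {}
    p1 = models.p1(np.array([x]))[0] if s1 == 1 else 0.0
    for m1 in (0, 1):
        pm1 = p1 if m1 == 1 else 1 - p1
        if pm1 == 0 and m1 == 1:
            continue
        if mode == "joint":
            p2 = (
                models.p2_joint(np.array([x]), np.array([m1]))[0]
                if s2 == 1
                else np.array([1.0, 0.0, 0.0])
            )
        else:
            p2 = (
                models.p2_marginal(np.array([x]))[0]
                if s2 == 1
                else np.array([1.0, 0.0, 0.0])
            )
        for m2 in (0, 1, 2):
            if p2[m2] == 0:
                continue
            if mode == "joint":
                p3 = models.p3_joint(
                    np.array([x]), s3, np.array([m1]), np.array([m2])
                )[0]
            else:
                p3 = models.p3_marginal(np.array([x]), s3)[0]
            for m3 in (0, 1):
                pm3 = p3 if m3 == 1 else 1 - p3
                prob = pm1 * p2[m2] * pm3
                if prob > 0:
                    out[(m1, m2, m3)] = out.get((m1, m2, m3), 0.0) + prob
    return out


def enumerate_mean(models, outcome, xs, a_y, sources, mode):
    """Exact counterfactual mean over the empirical covariate rows ``xs``."""
    total = 0.0
    for x in xs:
        dist = regime_distribution(models, x, sources, mode)
        total += sum(
            p * outcome.prob_scalar(x, a_y, m1, m2, m3)
            for (m1, m2, m3), p in dist.items()
        )
    return total / len(xs)


def enumerate_mean_variance(models, outcome, xs, a_y, sources, mode):
    """Mean per-draw variance of the outcome probability across rows.

    For an estimator averaging N independent draws (n rows x K copies) the
    Monte Carlo variance of the mean is this value divided by N.
    """
    per_row = []
    for x in xs:
        dist = regime_distribution(models, x, sources, mode)
        e1 = sum(
            p * outcome.prob_scalar(x, a_y, m1, m2, m3)
            for (m1, m2, m3), p in dist.items()
        )
        e2 = sum(
            p * outcome.prob_scalar(x, a_y, m1, m2, m3) ** 2
            for (m1, m2, m3), p in dist.items()
        )
        per_row.append(e2 - e1**2)
    return float(np.mean(per_row))


def enumerate_decomposition(models, outcome, xs):
    """Exact six-component decomposition for the toy instance."""
    em = lambda a_y, src, mode: enumerate_mean(models, outcome, xs, a_y, src, mode)
    p11 = em(1, (1, 1, 1), "joint")
    p00 = em(0, (0, 0, 0), "joint")
    p10 = em(1, (0, 0, 0), "joint")
    m000 = em(1, (0, 0, 0), "marginal")
    m100 = em(1, (1, 0, 0), "marginal")
    m110 = em(1, (1, 1, 0), "marginal")
    m111 = em(1, (1, 1, 1), "marginal")
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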