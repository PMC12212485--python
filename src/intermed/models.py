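"""Mediator and outcome models for the interventional-effects estimator.

Five component models are fitted with statsmodels on complete cases:

* ``m1_marginal`` — logistic model of M1 on confounders C, intervention arm;
* ``m2_marginal`` — multinomial (3-level) model of M2 on C, intervention arm;
* ``m2_joint``    — multinomial model of M2 on C and M1, intervention arm;
* ``m3_marginal`` — linear model of M3 on arm and C, both arms;
* ``m3_joint``    — linear model of M3 on arm, C, M1 and M2, both arms.

The marginal variants realize independent per-mediator counterfactual
draws; the joint variants realize sequential draws from the joint mediator
law factorized in the theorized order M1 -> M2 -> M3.  Under exposure
level 0 the intervention-arm-only mediators M1 and M2 are degenerate at
their unexposed level 0; M3 is drawn from its model at arm 0.

The outcome model is a logistic regression of Y on arm, the mediators,
confounders, and configurable interaction terms (mediator x mediator and
moderated-mediation terms such as M3 x medication).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, ndtri
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._design import MEDIATOR_FACTORS, build_design, check_full_rank, expand_terms
from .data import AnalysisDataset

__all__ = [
    "ModelFitError",
    "MediatorModelSet",
    "FittedOutcomeModel",
    "fit_mediator_models",
    "fit_outcome_model",
    "draw_mediators",
    "moderated_mediation_test",
    "DEFAULT_INTERACTIONS",
]

#: default outcome-model interaction terms: all pairwise mediator-mediator
#: interactions plus the medication moderation of behavioural activation.
#: Pooled runs append "m3:site".
DEFAULT_INTERACTIONS = ("m1:m2", "m1:m3", "m2:m3", "m3:medication")


class ModelFitError(RuntimeError):
    """A component model could not be fitted; carries the model name."""

    def __init__(self, model: str, reason: str):
        self.model = model
        super().__init__(f"{model}: {reason}")


def _as_frame(dataset) -> pd.DataFrame:
    return dataset.df if isinstance(dataset, AnalysisDataset) else dataset


def _fit_logit(y, X, names, model_name, start=None):
    # IRLS via GLM-Binomial: same MLE as Logit but robust to the transient
    # singular Hessians Newton hits under quasi-separation
    if np.ptp(y) == 0:
        raise ModelFitError(model_name, "response is constant (separation)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                start_params=start, maxiter=100
            )
        except (np.linalg.LinAlgError, ValueError, PerfectSeparationError) as exc:
            raise ModelFitError(model_name, str(exc)) from exc
    if not getattr(res, "converged", True) or not np.isfinite(res.params).all():
        raise ModelFitError(model_name, "did not converge (possible separation)")
    eta = X @ np.asarray(res.params)
    if np.abs(eta).max() > 30:  # fitted probabilities numerically at 0/1
        raise ModelFitError(model_name, "quasi-separation (degenerate fitted probabilities)")
    return res


def _fit_mnlogit(y, X, names, model_name, start=None):
    if set(np.unique(y)) != {0, 1, 2}:
        raise ModelFitError(model_name, "a mediator category is empty")
    if start is not None:
        start = np.asarray(start).ravel(order="F")  # MNLogit wants flat params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, X).fit(
                disp=0, method="newton", maxiter=100, start_params=start
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ModelFitError(model_name, str(exc)) from exc
    if not res.mle_retvals.get("converged", True) or not np.isfinite(res.params).all():
        raise ModelFitError(model_name, "did not converge (possible separation)")
    if np.abs(res.params).max() > 50:
        raise ModelFitError(model_name, "diverging coefficients (separation)")
    return res


@dataclass
class MediatorModelSet:
    """The five fitted mediator models plus the control-arm degeneracy rule.

    ``residual_kind`` selects how counterfactual M3 noise is drawn:
    ``"normal"`` uses the fitted residual SD (draws are deliberately not
    truncated to the BADS-SF range, for coherence with the linear model);
    ``"empirical"`` resamples the fitted model's residuals by inverse CDF.
    """

    confounders: list
    m1_marginal: object
    m2_marginal: object
    m2_joint: object
    m3_marginal: object
    m3_joint: object
    residual_sd: dict
    columns: dict
    residual_kind: str = "normal"
    residuals: dict = field(default_factory=dict)

    def params(self) -> dict:
        return {
            "m1_marginal": np.asarray(self.m1_marginal.params),
            "m2_marginal": np.asarray(self.m2_marginal.params),
            "m2_joint": np.asarray(self.m2_joint.params),
            "m3_marginal": np.asarray(self.m3_marginal.params),
            "m3_joint": np.asarray(self.m3_joint.params),
        }

    def sampler(self, cov_df) -> "MediatorSampler":
        return MediatorSampler(self, _as_frame(cov_df))


class MediatorSampler:
    """Vectorized counterfactual mediator draws over a covariate frame.

    Per-row model quantities are computed once at construction; draws are
    then made for arbitrary index vectors (for Monte Carlo expansion the
    index repeats each original row K times) from shared uniform streams,
    which lets different counterfactual regimes reuse common random
    numbers.
    """

    def __init__(self, models: MediatorModelSet, cov_df: pd.DataFrame):
        self.models = models
        cols = models.columns
        X1, _ = build_design(cov_df, cols["confounders"])
        self.p1 = expit(X1 @ np.asarray(models.m1_marginal.params).ravel())

        P2m = np.asarray(models.m2_marginal.params)  # (k, 2)
        eta2m = X1 @ P2m
        self.probs2_marginal = _softmax3(eta2m)

        # m2_joint design is [intercept, confounders..., m1]; split m1 out
        P2j = np.asarray(models.m2_joint.params)
        j_m1 = cols["m2_joint_m1_index"]
        keep = [i for i in range(P2j.shape[0]) if i != j_m1]
        self.eta2j_base = X1 @ P2j[keep, :]
        self.coef2j_m1 = P2j[j_m1, :]

        b3m = np.asarray(models.m3_marginal.params)
        i_arm = cols["m3_marginal_names"].index("arm")
        keep_m = [i for i in range(len(b3m)) if i != i_arm]
        self.base3m = X1 @ b3m[keep_m]
        self.coef3m_arm = b3m[i_arm]

        b3j = np.asarray(models.m3_joint.params)
        names_j = cols["m3_joint_names"]
        med_idx = {t: names_j.index(t) for t in ("arm", "m1", "m2_1", "m2_2")}
        keep_j = [i for i in range(len(b3j)) if i not in med_idx.values()]
        self.base3j = X1 @ b3j[keep_j]
        self.coef3j = {t: b3j[i] for t, i in med_idx.items()}

    def draw_m1(self, idx, u1, source: int):
        if source == 0:
            return np.zeros(len(idx))
        return (u1 < self.p1[idx]).astype(float)

    def draw_m2(self, idx, u2, source: int, mode: str, m1=None):
        if source == 0:
            return np.zeros(len(idx))
        if mode == "marginal":
            cum = np.cumsum(self.probs2_marginal[idx], axis=1)
        else:
            eta = self.eta2j_base[idx] + np.outer(m1, self.coef2j_m1)
            cum = np.cumsum(_softmax3(eta), axis=1)
        return (u2[:, None] > cum[:, :2]).sum(axis=1).astype(float)

    def draw_m3(self, idx, u3, source: int, mode: str, m1=None, m2=None):
        if mode == "marginal":
            mean = self.base3m[idx] + self.coef3m_arm * source
            key = "m3_marginal"
        else:
            c = self.coef3j
            mean = (
                self.base3j[idx]
                + c["arm"] * source
                + c["m1"] * m1
                + c["m2_1"] * (m2 == 1)
                + c["m2_2"] * (m2 == 2)
            )
            key = "m3_joint"
        sd = self.models.residual_sd[key]
        if self.models.residual_kind == "empirical":
            resid = self.models.residuals[key]
            order = np.floor(u3 * len(resid)).astype(int).clip(0, len(resid) - 1)
            return mean + np.sort(resid)[order]
        if sd == 0:
            return mean
        return mean + sd * ndtri(np.clip(u3, 1e-12, 1 - 1e-12))


def _softmax3(eta2: np.ndarray) -> np.ndarray:
    """Category probabilities (reference 0) from two non-reference logits."""
    full = np.column_stack([np.zeros(len(eta2)), eta2])
    e = np.exp(full - full.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def fit_mediator_models(
    dataset,
    confounders: list[str],
    warm: MediatorModelSet | None = None,
    residual_kind: str = "normal",
) -> MediatorModelSet:
    """Fit the five component mediator models on a complete-case dataset.

    ``warm`` supplies start values from a previous fit on comparable data
    (used by the bootstrap to cut Newton iterations).  Raises
    :class:`ModelFitError` naming the offending model on separation, empty
    mediator categories, or non-convergence.
    """
    df = _as_frame(dataset)
    interv = df[df["arm"] == 1]
    if interv.empty or (df["arm"] == 0).sum() == 0:
        raise ModelFitError("dataset", "both arms are required")

    ws = warm.params() if warm is not None else {}

    X1, n1 = build_design(interv, list(confounders))
    m1_fit = _fit_logit(
        interv["m1"].to_numpy(float), X1, n1, "m1_marginal", ws.get("m1_marginal")
    )
    m2m_fit = _fit_mnlogit(
        interv["m2"].to_numpy(float), X1, n1, "m2_marginal", ws.get("m2_marginal")
    )
    X2j, n2j = build_design(interv, list(confounders) + ["m1"])
    m2j_fit = _fit_mnlogit(
        interv["m2"].to_numpy(float), X2j, n2j, "m2_joint", ws.get("m2_joint")
    )

    X3m, n3m = build_design(df, ["arm"] + list(confounders))
    m3m_fit = sm.OLS(df["m3"].to_numpy(float), X3m).fit()
    X3j, n3j = build_design(df, ["arm"] + list(confounders) + ["m1", "m2"])
    m3j_fit = sm.OLS(df["m3"].to_numpy(float), X3j).fit()

    sds = {
        "m3_marginal": float(np.sqrt(m3m_fit.scale)),
        "m3_joint": float(np.sqrt(m3j_fit.scale)),
    }
    for k, v in sds.items():
        if not v > 0:
            raise ModelFitError(k, "residual SD is not positive")

    return MediatorModelSet(
        confounders=list(confounders),
        m1_marginal=m1_fit,
        m2_marginal=m2m_fit,
        m2_joint=m2j_fit,
        m3_marginal=m3m_fit,
        m3_joint=m3j_fit,
        residual_sd=sds,
        residual_kind=residual_kind,
        residuals={
            "m3_marginal": np.asarray(m3m_fit.resid),
            "m3_joint": np.asarray(m3j_fit.resid),
        },
        columns={
            "confounders": list(confounders),
            "m2_joint_m1_index": n2j.index("m1"),
            "m3_marginal_names": n3m,
            "m3_joint_names": n3j,
        },
    )


def draw_mediators(models: MediatorModelSet, covariates, a: int, mode: str, rng):
    """Draw one (m1, m2, m3) triple per covariate row at exposure ``a``.

    ``mode="joint"`` draws sequentially m1 -> m2|m1 -> m3|m1,m2;
    ``mode="marginal"`` draws each mediator independently from its marginal
    model.  Under ``a=0`` M1 and M2 are deterministically 0.  ``rng`` is
    mandatory — there is no hidden global random state.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if a not in (0, 1):
        raise ValueError("exposure level a must be 0 or 1")
    if mode not in ("joint", "marginal"):
        raise ValueError("mode must be 'joint' or 'marginal'")
    cov_df = _as_frame(covariates)
    n = len(cov_df)
    sampler = models.sampler(cov_df)
    idx = np.arange(n)
    u1, u2, u3 = rng.random((3, n))
    m1 = sampler.draw_m1(idx, u1, a)
    m2 = sampler.draw_m2(idx, u2, a, mode, m1=m1)
    m3 = sampler.draw_m3(idx, u3, a, mode, m1=m1, m2=m2)
    return m1, m2, m3


# --------------------------------------------------------------------------
# outcome model
# --------------------------------------------------------------------------


@dataclass
class FittedOutcomeModel:
    """Logistic outcome model with its expanded term list."""

    result: object
    terms: list
    column_names: list
    outcome: str

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params)

    @property
    def cov_params(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())

    def predict_prob(self, df) -> np.ndarray:
        X, _ = build_design(_as_frame(df), self.terms)
        return expit(X @ self.params)

    def evaluator(self, cov_df) -> "OutcomeEvaluator":
        return OutcomeEvaluator(self, _as_frame(cov_df))

    def coefficient_table(self) -> pd.DataFrame:
        res = self.result
        return pd.DataFrame(
            {
                "term": self.column_names,
                "coef": np.asarray(res.params),
                "se": np.asarray(res.bse),
                "p_value": np.asarray(res.pvalues),
            }
        )


class OutcomeEvaluator:
    """Evaluate outcome probabilities at counterfactual mediator draws.

    Splits each design column into a baseline part (covariates, site),
    an exposure part (powers of ``arm`` set to the regime's a_y), and a
    mediator part computed per draw, so million-row expanded predictions
    cost one pass of column products.
    """

    def __init__(self, model: FittedOutcomeModel, cov_df: pd.DataFrame):
        from ._design import resolve_factor

        self.base = np.zeros(len(cov_df))
        self.arm_cols = []  # (coef, static, arm_power)
        self.med_cols = []  # (coef, static, arm_power, med_factors)
        for name, coef in zip(model.column_names, model.params):
            factors = name.split(":") if name != "intercept" else []
            arm_power = sum(f == "arm" for f in factors)
            med = tuple(f for f in factors if f in MEDIATOR_FACTORS)
            rest = [f for f in factors if f != "arm" and f not in MEDIATOR_FACTORS]
            static = np.ones(len(cov_df))
            for f in rest:
                static = static * resolve_factor(cov_df, f)
            if name == "intercept":
                self.base += coef
            elif not med and arm_power == 0:
                self.base += coef * static
            elif not med:
                self.arm_cols.append((coef, static, arm_power))
            else:
                self.med_cols.append((coef, static, arm_power, med))

    def prob(self, idx, a_y: int, m1, m2, m3) -> np.ndarray:
        eta = self.base[idx].copy()
        for coef, static, ap in self.arm_cols:
            if a_y != 0:
                eta += coef * static[idx]
        for coef, static, ap, med in self.med_cols:
            if ap > 0 and a_y == 0:
                continue
            part = coef * static[idx]
            for f in med:
                if f == "m1":
                    part = part * m1
                elif f == "m2_1":
                    part = part * (m2 == 1)
                elif f == "m2_2":
                    part = part * (m2 == 2)
                else:
                    part = part * m3
            eta += part
        return expit(eta)


def fit_outcome_model(
    dataset,
    confounders: list[str],
    interaction_spec: tuple = DEFAULT_INTERACTIONS,
    outcome: str = "y",
    warm: FittedOutcomeModel | None = None,
) -> FittedOutcomeModel:
    """Fit the logistic outcome model with mediator and moderation terms.

    The design holds arm, M1, the two M2 contrasts, M3, the confounders,
    and the expanded interaction terms.  Rank deficiency raises a
    ``ValueError`` listing the aliased terms; separation or non-convergence
    raises :class:`ModelFitError`.
    """
    df = _as_frame(dataset)
    terms = ["arm", "m1", "m2", "m3"] + list(confounders) + list(interaction_spec or ())
    X, names = build_design(df, terms)
    check_full_rank(X, names)
    y = df[outcome].to_numpy(float)
    start = warm.params if warm is not None and len(warm.params) == X.shape[1] else None
    res = _fit_logit(y, X, names, "outcome", start)
    return FittedOutcomeModel(result=res, terms=terms, column_names=names, outcome=outcome)


def moderated_mediation_test(model: FittedOutcomeModel, interaction_term: str) -> float:
    """Wald p-value for a named interaction, e.g. ``"m3:medication"``.

    Multi-column terms (interactions involving the categorical M2) get a
    joint chi-square Wald test.
    """
    cols = expand_terms([interaction_term])
    idx = []
    for c in cols:
        if c not in model.column_names:
            raise ValueError(
                f"term {interaction_term!r} (column {c!r}) is not in the model"
            )
        idx.append(model.column_names.index(c))
    if len(idx) == 1:
        return float(np.asarray(model.result.pvalues)[idx[0]])
    R = np.zeros((len(idx), len(model.params)))
    for row, j in enumerate(idx):
        R[row, j] = 1.0
    wt = model.result.wald_test(R, scalar=True)
    return float(wt.pvalue)
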