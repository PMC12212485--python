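"""Bias-corrected nonparametric bootstrap honoring each site's design.

Resampling respects how each site was randomized: the individually
randomized site (lima) resamples participants with replacement within
randomization strata (arm, which preserves the realized allocation); the
cluster randomized site (saopaulo) resamples whole clusters with
replacement within arm, keeping every within-cluster row intact.  Pooled
datasets resample each site by its own design and concatenate.

Intervals are bias-corrected (BC, not accelerated) percentile intervals:
``z0 = ndtri(prop)`` with ``prop = (#{th* < th_hat} + 0.5 #{th* = th_hat}) / B``
(ties split evenly; prop clamped away from 0/1 with a warning), and the
nominal 95% bounds are the bootstrap quantiles at ``Phi(2 z0 -/+ 1.96)``.
With z0 = 0 this reduces to the plain percentile interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .data import AnalysisDataset
from .models import ModelFitError

__all__ = ["BootstrapResult", "bootstrap_effects", "bc_interval", "resample_indices"]

_Z95 = 1.96


@dataclass
class BootstrapResult:
    component: str
    point_estimate: float
    n_resamples: int
    z0: float
    ci_lower: float
    ci_upper: float
    resampling_design: str
    n_dropped: int = 0
    replicates: np.ndarray | None = None  # the bootstrap distribution itself

    @property
    def se(self) -> float:
        """Bootstrap standard error of the component."""
        return float(np.std(self.replicates, ddof=1)) if self.replicates is not None else float("nan")

    def as_dict(self) -> dict:
        return {
            "component": self.component,
            "estimate": self.point_estimate,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "z0": self.z0,
            "n_resamples": self.n_resamples,
            "n_dropped": self.n_dropped,
            "design": self.resampling_design,
        }


def resample_indices(df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """One design-respecting bootstrap resample of row positions."""
    parts = []
    pos = np.arange(len(df))
    sites = df["site"].to_numpy()
    arms = df["arm"].to_numpy()
    for site in pd.unique(sites):
        in_site = sites == site
        if site == "saopaulo":
            clusters = df["cluster_id"].to_numpy()
            for arm in (0, 1):
                mask = in_site & (arms == arm)
                cl = pd.unique(clusters[mask])
                if len(cl) == 0:
                    continue
                members = {c: pos[mask & (clusters == c)] for c in cl}
                chosen = rng.choice(len(cl), size=len(cl), replace=True)
                for c in cl[chosen]:
                    parts.append(members[c])
        else:
            for arm in (0, 1):
                mask = in_site & (arms == arm)
                rows = pos[mask]
                if len(rows) == 0:
                    continue
                parts.append(rng.choice(rows, size=len(rows), replace=True))
    return np.concatenate(parts)


def bc_interval(boot: np.ndarray, theta_hat: float, level: float = 0.95):
    """Bias-corrected percentile interval; returns (z0, lower, upper)."""
    b = len(boot)
    prop = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / b
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "every bootstrap replicate fell on one side of the estimate; "
            "bias-correction constant clamped"
        )
        prop = np.clip(prop, 1.0 / (2 * b), 1.0 - 1.0 / (2 * b))
    z0 = float(ndtri(prop))
    z = _Z95 if level == 0.95 else float(ndtri(0.5 + level / 2))
    a_lo = float(ndtr(2 * z0 - z))
    a_hi = float(ndtr(2 * z0 + z))
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return z0, float(lo), float(hi)


def bootstrap_effects(
    dataset,
    estimator,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    max_dropped_fraction: float = 0.05,
) -> list[BootstrapResult]:
    """BC bootstrap CIs for every component an estimator pipeline returns.

    ``estimator(df, rng)`` must rerun the full pipeline on the resampled
    frame — refit the mediator and outcome models and recompute the
    decomposition — and return a mapping of component name to estimate
    (confounder screening stays fixed: it is done once on the original
    sample, since re-screening per replicate would change the estimand).
    Resamples on which a model cannot be fitted (a single-arm cluster draw,
    an empty mediator category, separation) are dropped and counted; more
    than ``max_dropped_fraction`` dropped triggers a warning.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if B < 2:
        raise ValueError("B must be >= 2")
    df = dataset.df if isinstance(dataset, AnalysisDataset) else dataset
    theta_hat = estimator(df, rng)

    boots: dict[str, list] = {k: [] for k in theta_hat}
    dropped = 0
    for _ in range(B):
        idx = resample_indices(df, rng)
        df_b = df.iloc[idx].reset_index(drop=True)
        try:
            est = estimator(df_b, rng)
        except (ModelFitError, np.linalg.LinAlgError, ValueError):
            dropped += 1
            continue
        for k, v in est.items():
            boots[k].append(v)
    if dropped > max_dropped_fraction * B:
        warnings.warn(
            f"{dropped} of {B} bootstrap replicates were dropped "
            "(unfittable models); intervals may be unreliable"
        )

    design = "+".join(
        "cluster" if s == "saopaulo" else "stratified-individual"
        for s in sorted(pd.unique(df["site"]))
    )
    results = []
    for name, th in theta_hat.items():
        arr = np.asarray(boots[name])
        z0, lo, hi = bc_interval(arr, th)
        results.append(
            BootstrapResult(
                component=name,
                point_estimate=float(th),
                n_resamples=len(arr),
                z0=z0,
                ci_lower=lo,
                ci_upper=hi,
                resampling_design=design,
                n_dropped=dropped,
                replicates=arr,
            )
        )
    return results
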