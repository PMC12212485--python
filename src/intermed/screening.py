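"""Mediator-outcome confounder screening.

Each baseline candidate is tested univariably against every mediator and
against the outcome; a candidate is selected when any association has
p < alpha (default 0.10).  Tests match the target's type: Wald test in a
univariable logistic model for the binary M1 and for Y, a likelihood-ratio
joint test in a univariable multinomial model for the 3-level M2, and a
Wald test in a univariable linear model for the continuous M3.

M1 and M2 are structurally zero in the control arm, so their screening
models use intervention-arm records only; M3 and Y use both arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import AnalysisDataset

__all__ = ["ScreeningResult", "screen_site", "pooled_union", "selected_variables"]

TARGETS = ("m1", "m2", "m3", "y")


@dataclass
class ScreeningResult:
    candidate: str
    target: str
    p_value: float
    selected: bool
    alpha: float = 0.10
    note: str = ""


def _p_binary(y: np.ndarray, x: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=50)
    return float(res.pvalues[1])


def _p_multinomial(y: np.ndarray, x: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MNLogit(y, X).fit(disp=0, method="newton", maxiter=100)
        null = sm.MNLogit(y, np.ones((len(y), 1))).fit(disp=0, method="newton")
    lr = 2.0 * (full.llf - null.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df=2))


def _p_linear(y: np.ndarray, x: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    res = sm.OLS(y, X).fit()
    return float(res.pvalues[1])


def screen_site(
    dataset: AnalysisDataset,
    candidates: list[str],
    alpha: float = 0.10,
    outcome: str = "y",
) -> list[ScreeningResult]:
    """Screen baseline candidates against each mediator and the outcome.

    A constant candidate (no variance in the relevant estimation sample)
    cannot be tested; it is reported unselected with a diagnostic note.
    Results are returned candidate-major in input order, one row per
    candidate x target.
    """
    df = dataset.df
    interv = df[df["arm"] == 1]
    results: list[ScreeningResult] = []
    for cand in candidates:
        if cand not in df.columns:
            raise ValueError(f"unknown candidate variable {cand!r}")
        pvals = {}
        notes = {}
        for target in TARGETS:
            frame = interv if target in ("m1", "m2") else df
            x = frame[cand].to_numpy(dtype=float)
            t = frame[target if target != "y" else outcome].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                pvals[target] = np.nan
                notes[target] = "constant candidate"
                continue
            try:
                if target == "m1":
                    pvals[target] = _p_binary(t, x)
                elif target == "m2":
                    pvals[target] = _p_multinomial(t, x)
                elif target == "m3":
                    pvals[target] = _p_linear(t, x)
                else:
                    pvals[target] = _p_binary(t, x)
            except (np.linalg.LinAlgError, ValueError) as exc:
                pvals[target] = np.nan
                notes[target] = f"test failed: {exc}"
        # candidate-level selection: any target test below alpha
        any_selected = any(np.isfinite(p) and p < alpha for p in pvals.values())
        for target in TARGETS:
            p = pvals[target]
            results.append(
                ScreeningResult(
                    candidate=cand,
                    target=target,
                    p_value=float(p) if np.isfinite(p) else np.nan,
                    selected=any_selected,
                    alpha=alpha,
                    note=notes.get(target, ""),
                )
            )
    return results


def selected_variables(results: list[ScreeningResult]) -> list[str]:
    """Candidates selected by any target test, in first-appearance order."""
    out: list[str] = []
    for r in results:
        if r.selected and r.candidate not in out:
            out.append(r.candidate)
    return out


def pooled_union(
    site_results_lima: list[ScreeningResult],
    site_results_saopaulo: list[ScreeningResult],
) -> list[str]:
    """Union of the two sites' selected sets plus the site indicator.

    Order-stable: Lima's selections in order, then São Paulo's new ones,
    then ``"site"``.
    """
    out = selected_variables(site_results_lima)
    for v in selected_variables(site_results_saopaulo):
        if v not in out:
            out.append(v)
    out.append("site")
    return out


def screening_frame(results: list[ScreeningResult]):
    """Screening report as a DataFrame (candidate, target, p, selected)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "candidate": r.candidate,
                "target": r.target,
                "p_value": r.p_value,
                "selected": r.selected,
                "note": r.note,
            }
            for r in results
        ]
    )
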