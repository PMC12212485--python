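"""Term-list design matrices.

Model specifications throughout the package are lists of term strings such
as ``"arm"``, ``"m2"``, ``"m3:medication"``.  A term is a product of atomic
factors separated by ``:``.  The categorical mediator ``m2`` (0 / 1-10 /
11-27 activity levels) expands into two indicator contrasts ``m2_1`` and
``m2_2`` against level 0, including inside interactions.  ``site`` resolves
to an indicator for the cluster-randomized site.

Design matrices are assembled by plain numpy column products.  Model
*fitting* is always delegated to statsmodels; this module only builds the
matrices, which keeps bootstrap refits and million-row counterfactual
predictions cheap.
"""

from __future__ import annotations

from itertools import product as _cartesian

import numpy as np
import pandas as pd

#: atomic factors that depend on mediator draws rather than baseline data
MEDIATOR_FACTORS = ("m1", "m2_1", "m2_2", "m3")

_EXPANSIONS = {"m2": ["m2_1", "m2_2"]}


def expand_terms(terms: list[str]) -> list[str]:
    """Expand categorical factors, returning atomic design column names.

    ``["arm", "m2", "m1:m2"]`` becomes
    ``["arm", "m2_1", "m2_2", "m1:m2_1", "m1:m2_2"]``.
    """
    out: list[str] = []
    for term in terms:
        factors = term.split(":")
        choices = [_EXPANSIONS.get(f, [f]) for f in factors]
        for combo in _cartesian(*choices):
            name = ":".join(combo)
            if name not in out:
                out.append(name)
    return out


def resolve_factor(data, factor: str) -> np.ndarray:
    """Return the numeric column for one atomic factor.

    ``data`` may be a DataFrame or a plain mapping of numpy arrays.
    """
    if factor == "intercept":
        ref = resolve_factor(data, "arm")
        return np.ones(len(ref))
    if factor == "m2_1":
        return (np.asarray(data["m2"]) == 1).astype(float)
    if factor == "m2_2":
        return (np.asarray(data["m2"]) == 2).astype(float)
    if factor == "site":
        col = data["site"]
        if getattr(col, "dtype", None) is not None and col.dtype == object or (
            isinstance(col, pd.Series) and col.dtype == object
        ):
            return (np.asarray(col) == "saopaulo").astype(float)
        return np.asarray(col, dtype=float)
    return np.asarray(data[factor], dtype=float)


def column_value(data, name: str) -> np.ndarray:
    """Product of the atomic factors in one expanded design column."""
    factors = name.split(":")
    val = resolve_factor(data, factors[0])
    for f in factors[1:]:
        val = val * resolve_factor(data, f)
    return val


def build_design(data, terms: list[str], add_intercept: bool = True):
    """Build (X, column_names) for a term list; terms are expanded first."""
    names = expand_terms(terms)
    cols = [column_value(data, c) for c in names]
    if add_intercept:
        cols.insert(0, np.ones(len(cols[0]) if cols else len(data)))
        names = ["intercept"] + names
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise ValueError naming aliased columns when X is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        aliased = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(names[j])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased}"
        )


def linear_predictor(coefs: dict[str, float], data) -> np.ndarray:
    """Evaluate ``sum_k coef_k * column_k`` for a coefficient mapping.

    Keys are expanded design-column names plus optional ``"intercept"``.
    Used by the synthetic generator, whose structural models share the term
    naming of the fitted models.
    """
    n = len(next(iter(data.values()))) if isinstance(data, dict) else len(data)
    eta = np.zeros(n)
    for key, coef in coefs.items():
        if coef == 0.0:
            continue
        if key == "intercept":
            eta = eta + coef
        else:
            eta = eta + coef * column_value(data, key)
    return eta
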