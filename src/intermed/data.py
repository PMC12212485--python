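"""Trial data model: codebook-driven CSV ingestion and descriptives.

The canonical in-memory container is a pandas DataFrame with one row per
participant and the columns of :data:`ANALYSIS_COLUMNS`; a
:class:`TrialRecord` dataclass view is available for record-level work.
CSV files with arbitrary headers bind to this schema through a *codebook* —
a mapping from field name to source column, type and allowed range — so a
deposited analysis file can be read without code changes.

Conventions baked in here:

* the outcome ``y`` is 1 iff PHQ-9 fell by **at least** 50% between
  baseline and six months (closed boundary); ``y_sens`` is recovery,
  six-month PHQ-9 < 10;
* mediators M1 (understood content) and M2 (activities completed) exist
  only in the intervention arm; control-arm values are stored at the
  defined unexposed level 0, never as missing, because the mediation
  estimator needs a defined unexposed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "AnalysisDataset",
    "Codebook",
    "DEFAULT_CODEBOOK",
    "ANALYSIS_COLUMNS",
    "read_dataset",
    "from_frame",
    "complete_case_filter",
    "derive_outcomes",
    "derive_outcome_columns",
    "descriptive_table",
    "format_descriptive_table",
]

#: analysis variables in canonical order
ANALYSIS_COLUMNS = (
    "participant_id",
    "site",
    "cluster_id",
    "arm",
    "phq9_baseline",
    "age",
    "education_years",
    "medication",
    "friends",
    "phone_use",
    "bads_baseline",
    "m1",
    "m2",
    "m3",
    "phq9_6m",
    "y",
    "y_sens",
)

CONFOUNDER_CANDIDATES = (
    "phq9_baseline",
    "age",
    "education_years",
    "medication",
    "friends",
    "phone_use",
    "bads_baseline",
)


@dataclass
class TrialRecord:
    """One participant's covariates, arm, mediators and outcomes."""

    participant_id: str
    site: str
    cluster_id: str
    arm: int
    phq9_baseline: int
    age: float
    education_years: float
    medication: int
    friends: int
    phone_use: float
    bads_baseline: float
    m1: int
    m2: int
    m3: float
    phq9_6m: float | None = None
    y: float | None = None
    y_sens: float | None = None


@dataclass
class AnalysisDataset:
    """A trial dataset plus its provenance flags.

    ``range_violations`` lists ``(row_index, field, value)`` for cells that
    fell outside the codebook range; such records are kept but flagged.
    """

    df: pd.DataFrame
    site_filter: tuple = ("lima", "saopaulo")
    complete_case: bool = False
    retained: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)
    range_violations: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[TrialRecord]:
        cols = [c for c in ANALYSIS_COLUMNS if c in self.df.columns]
        return [
            TrialRecord(**{c: row[c] for c in cols})
            for row in self.df[cols].to_dict("records")
        ]

    def subset(self, site: str) -> "AnalysisDataset":
        if site == "pooled":
            return self
        if site not in ("lima", "saopaulo"):
            raise ValueError(f"unknown site {site!r}")
        return AnalysisDataset(
            df=self.df[self.df["site"] == site].reset_index(drop=True),
            site_filter=(site,),
            complete_case=self.complete_case,
        )


# --------------------------------------------------------------------------
# codebook
# --------------------------------------------------------------------------

_FIELD_SPECS = {
    # field: (dtype, lo, hi)  — None bounds mean unchecked
    "participant_id": ("str", None, None),
    "site": ("site", None, None),
    "cluster_id": ("str", None, None),
    "arm": ("int", 0, 1),
    "phq9_baseline": ("int", 0, 27),
    "age": ("float", 18, 120),
    "education_years": ("float", 0, 30),
    "medication": ("int", 0, 1),
    "friends": ("int", 0, 1),
    "phone_use": ("float", 0, 10),
    "bads_baseline": ("float", 0, 54),
    "m1": ("int", 0, 1),
    "m2": ("int", 0, 2),
    "m3": ("float", 0, 54),
    "phq9_6m": ("int", 0, 27),
}


@dataclass
class Codebook:
    """Mapping from analysis fields to CSV columns with type/range checks.

    ``columns`` maps field name -> source column name.  Extra candidate
    confounders (site-specific questionnaire items such as support from
    colleagues) can be declared in ``extra`` as
    ``{field: (column, dtype, lo, hi)}``.
    """

    columns: dict = field(default_factory=lambda: {f: f for f in _FIELD_SPECS})
    site_labels: dict = field(
        default_factory=lambda: {"lima": "lima", "saopaulo": "saopaulo"}
    )
    extra: dict = field(default_factory=dict)

    def fields(self):
        out = {f: (self.columns[f], *_FIELD_SPECS[f]) for f in self.columns}
        out.update(self.extra)
        return out


DEFAULT_CODEBOOK = Codebook()


def read_dataset(path, codebook: Codebook | None = None) -> AnalysisDataset:
    """Read a participant-level CSV through a codebook.

    Missing mandatory columns raise a ``ValueError`` naming the column;
    unparseable cells raise with the offending row index.  Out-of-range
    values are flagged (not dropped).  The control-arm unexposed convention
    is applied to M1/M2, and outcomes are (re)derived from the PHQ-9 pair
    whenever the six-month score is present.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    raw = pd.read_csv(path)
    return from_frame(raw, codebook)


def from_frame(raw: pd.DataFrame, codebook: Codebook | None = None) -> AnalysisDataset:
    """Bind an already-loaded frame to the analysis schema (see read_dataset)."""
    codebook = codebook or DEFAULT_CODEBOOK
    out = {}
    violations = []
    for fname, (col, dtype, lo, hi) in codebook.fields().items():
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} (field {fname!r}) missing")
        series = raw[col]
        if dtype == "str":
            out[fname] = series.astype(str)
            continue
        if dtype == "site":
            inv = {v: k for k, v in codebook.site_labels.items()}
            vals = series.map(inv)
            if vals.isna().any():
                bad = series[vals.isna()].index[0]
                raise ValueError(
                    f"row {bad}: unrecognized site label {series[bad]!r}"
                )
            out[fname] = vals
            continue
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna() & series.notna()
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {idx}: cannot parse value {series.iloc[idx]!r} "
                f"for field {fname!r}"
            )
        if lo is not None:
            oor = coerced.notna() & ((coerced < lo) | (coerced > hi))
            for idx in np.flatnonzero(oor):
                violations.append((int(idx), fname, float(coerced.iloc[idx])))
        out[fname] = coerced
    df = pd.DataFrame(out)

    # unexposed convention: control-arm M1/M2 are level 0 by definition
    ctrl = df["arm"] == 0
    df.loc[ctrl, "m1"] = 0
    df.loc[ctrl, "m2"] = 0

    y, y_sens = derive_outcome_columns(df["phq9_baseline"], df["phq9_6m"])
    df["y"] = y
    df["y_sens"] = y_sens
    return AnalysisDataset(df=df, range_violations=violations)


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def derive_outcomes(record: TrialRecord) -> tuple:
    """Derive (Y, y_sens) for one record.

    Y = 1 iff the PHQ-9 fell by at least half of its baseline value
    (closed boundary: a drop of exactly 50% counts as improved);
    y_sens = 1 iff the six-month score is below the clinical threshold 10.
    Returns ``(None, None)`` when the six-month score is missing.
    """
    if record.phq9_6m is None or (
        isinstance(record.phq9_6m, float) and np.isnan(record.phq9_6m)
    ):
        return (None, None)
    y = int(record.phq9_baseline - record.phq9_6m >= 0.5 * record.phq9_baseline)
    return (y, int(record.phq9_6m < 10))


def derive_outcome_columns(phq9_baseline, phq9_6m):
    """Vectorized outcome derivation; missing six-month scores give NaN."""
    base = np.asarray(phq9_baseline, dtype=float)
    six = np.asarray(phq9_6m, dtype=float)
    y = np.where(np.isnan(six), np.nan, (base - six >= 0.5 * base).astype(float))
    y_sens = np.where(np.isnan(six), np.nan, (six < 10).astype(float))
    return y, y_sens


# --------------------------------------------------------------------------
# complete cases
# --------------------------------------------------------------------------

def complete_case_filter(
    dataset: AnalysisDataset, variables: list[str] | None = None
) -> AnalysisDataset:
    """Keep records with every listed analysis variable non-missing.

    Retained/dropped counts are reported per site.  Raises if nothing
    survives the filter.
    """
    df = dataset.df
    if variables is None:
        variables = [
            c for c in ANALYSIS_COLUMNS if c in df.columns and c != "participant_id"
        ]
    unknown = [v for v in variables if v not in df.columns]
    if unknown:
        raise ValueError(f"variables not in dataset: {unknown}")
    keep = df[variables].notna().all(axis=1)
    retained = df.loc[keep].reset_index(drop=True)
    if retained.empty:
        raise ValueError("complete-case filter removed every record")
    per_site_kept = df.loc[keep, "site"].value_counts().to_dict()
    per_site_drop = df.loc[~keep, "site"].value_counts().to_dict()
    return AnalysisDataset(
        df=retained,
        site_filter=dataset.site_filter,
        complete_case=True,
        retained={s: int(per_site_kept.get(s, 0)) for s in ("lima", "saopaulo")},
        dropped={s: int(per_site_drop.get(s, 0)) for s in ("lima", "saopaulo")},
        range_violations=dataset.range_violations,
    )


# --------------------------------------------------------------------------
# descriptive tables
# --------------------------------------------------------------------------

_CATEGORICAL = {
    "m1": [1],
    "m2": [0, 1, 2],
    "medication": [1],
    "friends": [1],
}
_DESCRIPTIVE_VARS = (
    "m1",
    "m2",
    "m3",
    "phq9_baseline",
    "age",
    "education_years",
    "medication",
    "friends",
    "phone_use",
    "bads_baseline",
)


def descriptive_table(dataset: AnalysisDataset, stratifier: str = "arm") -> pd.DataFrame:
    """Per-variable summaries by stratum: the arm-comparison layout when
    ``stratifier="arm"`` and the outcome-comparison layout when
    ``stratifier="outcome"``.

    Categorical variables are summarized as count (proportion), continuous
    ones as mean (SD).  When stratifying by arm, M1/M2 are summarized in
    the intervention arm only (they are structurally 0 under control).
    Empty strata yield NaN cells, not zeros.
    """
    if stratifier not in ("arm", "outcome"):
        raise ValueError("stratifier must be 'arm' or 'outcome'")
    df = dataset.df
    strat_col = "arm" if stratifier == "arm" else "y"
    rows = []
    for level in (0, 1):
        mask = df[strat_col] == level
        sub = df.loc[mask]
        for var in _DESCRIPTIVE_VARS:
            if var not in df.columns:
                continue
            use = sub
            if stratifier == "arm" and var in ("m1", "m2"):
                if level == 0:
                    continue  # intervention-arm-only mediators
                use = sub
            if var in _CATEGORICAL:
                for cat in _CATEGORICAL[var]:
                    n = int((use[var] == cat).sum()) if len(use) else np.nan
                    denom = len(use) or np.nan
                    rows.append(
                        {
                            "variable": var if var != "m2" else f"m2=={cat}",
                            "stratum": level,
                            "stat": "count",
                            "value": n,
                            "proportion": n / denom if len(use) else np.nan,
                        }
                    )
            else:
                rows.append(
                    {
                        "variable": var,
                        "stratum": level,
                        "stat": "mean",
                        "value": float(use[var].mean()) if len(use) else np.nan,
                        "sd": float(use[var].std(ddof=1)) if len(use) > 1 else np.nan,
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["stratifier"] = stratifier
    table.attrs["n"] = len(df)
    return table


def format_descriptive_table(table: pd.DataFrame) -> str:
    """Render a descriptive table as aligned plain text."""
    lines = [f"stratifier: {table.attrs.get('stratifier')}  (n={table.attrs.get('n')})"]
    for _, r in table.iterrows():
        if r["stat"] == "count":
            val = (
                f"{r['value']:.0f} ({100 * r['proportion']:.1f}%)"
                if np.isfinite(r["value"])
                else "NA"
            )
        else:
            val = (
                f"{r['value']:.1f} ({r['sd']:.1f})" if np.isfinite(r["value"]) else "NA"
            )
        lines.append(f"  {r['variable']:<16} stratum={r['stratum']:<2.0f} {val}")
    return "\n".join(lines)
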