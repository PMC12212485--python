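"""End-to-end orchestration: load/generate -> complete cases -> screening ->
model fits -> decomposition -> bias-corrected bootstrap, per site and pooled,
for the primary (>= 50% PHQ-9 reduction) or sensitivity (recovery,
PHQ-9 < 10) outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bootstrap as bst
from . import data as td
from . import models as md
from . import screening as scr
from .engine import decompose_effects
from .synthetic import SyntheticConfig, default_config, generate_trial

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "sensitivity_run"]

OUTCOME_COLUMNS = {"improved50": "y", "recovery": "y_sens"}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    seed: int
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    codebook: td.Codebook | None = None
    sites: tuple = ("lima", "saopaulo", "pooled")
    candidates: tuple = td.CONFOUNDER_CANDIDATES
    alpha: float = 0.10
    interaction_spec: tuple | None = None  # None -> package default
    moderation_terms: tuple = ("m3:medication",)  # "+ m3:site" added when pooled
    k_copies: int = 1000
    k_copies_bootstrap: int | None = None  # None -> same as k_copies
    resamples: int = 1000
    outcome: str = "improved50"
    mediator_order: tuple = ("m1", "m2", "m3")
    residual_kind: str = "normal"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.k_copies < 1 or self.resamples < 2:
            raise ValueError("k_copies and resamples must be positive")
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")


@dataclass
class RunReport:
    """All artifacts of one pipeline run, JSON-serializable."""

    config: dict
    complete_case: dict
    screening: dict
    confounders: dict
    descriptives: dict
    site_results: dict
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(_jsonable(self.__dict__), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_text(self) -> str:
        """Plain-text effect table, one block per analysis set."""
        labels = {
            "te": "Total effect",
            "de": "Direct effect",
            "ie_m1": "Indirect effect via understanding content (M1)",
            "ie_m2": "Indirect effect via completed activities (M2)",
            "ie_m3": "Indirect effect via behavioural activation (M3)",
            "ie_dep": "Indirect effect via mediator dependence",
        }
        lines = []
        for site, res in self.site_results.items():
            n = self.complete_case["retained"].get(site) or sum(
                v or 0 for v in self.complete_case["retained"].values()
            )
            lines.append(f"== {site} (n = {n}, outcome = {self.config['outcome']}) ==")
            for comp, lab in labels.items():
                e = res["effects"][comp]
                ci = res["bootstrap"].get(comp)
                if ci:
                    lines.append(
                        f"  {lab:<48} {e:+.3f} ({ci['ci_lower']:+.3f}, {ci['ci_upper']:+.3f})"
                    )
                else:
                    lines.append(f"  {lab:<48} {e:+.3f}")
            for term, p in res.get("moderation", {}).items():
                lines.append(f"  moderated mediation {term}: p = {p:.4f}")
            lines.append("")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return obj


def _load(config: PipelineConfig) -> td.AnalysisDataset:
    if config.input_path is not None:
        return td.read_dataset(config.input_path, config.codebook)
    syn_cfg = config.synthetic or default_config(seed=config.seed)
    frame = generate_trial(syn_cfg, seed=config.seed)
    return td.from_frame(frame)


def _site_confounders(site, sel_lima, sel_sp, union):
    if site == "lima":
        return sel_lima
    if site == "saopaulo":
        return sel_sp
    return union


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis for each requested site and pooled.

    Screening is performed once per site on the original complete-case
    sample and held fixed across bootstrap replicates; mediator and
    outcome models are refitted on every resample.  Fully reproducible
    from ``(config, seed)``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: s
        for name, s in zip(
            ("decompose", "bootstrap"), ss.spawn(2)
        )
    }
    outcome_col = OUTCOME_COLUMNS[config.outcome]

    try:
        dataset = _load(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    analysis_vars = [
        "site", "cluster_id", "arm", *td.CONFOUNDER_CANDIDATES,
        "m1", "m2", "m3", outcome_col,
    ]
    try:
        cc = td.complete_case_filter(dataset, analysis_vars)
    except Exception as exc:
        raise RuntimeError(f"stage 'complete_case' failed: {exc}") from exc

    candidates = [c for c in config.candidates if c in cc.df.columns]
    try:
        res_lima = scr.screen_site(
            cc.subset("lima"), candidates, config.alpha, outcome_col
        )
        res_sp = scr.screen_site(
            cc.subset("saopaulo"), candidates, config.alpha, outcome_col
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'screening' failed: {exc}") from exc
    sel_lima = scr.selected_variables(res_lima)
    sel_sp = scr.selected_variables(res_sp)
    union = scr.pooled_union(res_lima, res_sp)

    site_results = {}
    for site in config.sites:
        sub = cc.subset(site)
        confs = _site_confounders(site, sel_lima, sel_sp, union)
        inter = list(
            config.interaction_spec
            if config.interaction_spec is not None
            else md.DEFAULT_INTERACTIONS
        )
        moderation = list(config.moderation_terms)
        if site == "pooled":
            if "m3:site" not in inter and config.interaction_spec is None:
                inter.append("m3:site")
            if "m3:site" not in moderation:
                moderation.append("m3:site")

        try:
            models = md.fit_mediator_models(
                sub, confs, residual_kind=config.residual_kind
            )
            outcome_model = md.fit_outcome_model(
                sub, confs, tuple(inter), outcome=outcome_col
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'fit[{site}]' failed: {exc}") from exc

        k_boot = config.k_copies_bootstrap or config.k_copies

        def estimator(df_b, rng, _site=site, _confs=confs, _inter=tuple(inter),
                      _warm_m=models, _warm_y=outcome_model, _k=k_boot):
            m = md.fit_mediator_models(
                df_b, _confs, warm=_warm_m, residual_kind=config.residual_kind
            )
            om = md.fit_outcome_model(
                df_b, _confs, _inter, outcome=outcome_col, warm=_warm_y
            )
            dec = decompose_effects(
                df_b, m, om, k_copies=_k, rng=rng, order=config.mediator_order
            )
            return dec.components()

        try:
            dec = decompose_effects(
                sub,
                models,
                outcome_model,
                k_copies=config.k_copies,
                rng=np.random.default_rng(seeds["decompose"]),
                order=config.mediator_order,
            )
            boot = bst.bootstrap_effects(
                sub,
                estimator,
                B=config.resamples,
                rng=np.random.default_rng(seeds["bootstrap"]),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'effects[{site}]' failed: {exc}") from exc
        # report the full-K point estimate alongside the replicate intervals
        boot_by_comp = {}
        for b in boot:
            d = b.as_dict()
            d["estimate"] = dec.components()[b.component]
            boot_by_comp[b.component] = d

        moderation_p = {}
        for term in moderation:
            try:
                moderation_p[term] = md.moderated_mediation_test(outcome_model, term)
            except ValueError:
                continue

        site_results[site] = {
            "n": len(sub.df),
            "confounders": list(confs),
            "interactions": list(inter),
            "effects": dec.components(),
            "k_copies": dec.k_copies,
            "means": dec.means,
            "bootstrap": boot_by_comp,
            "moderation": moderation_p,
            "outcome_coefficients": outcome_model.coefficient_table().to_dict("records"),
        }

    descr = {
        "by_arm": td.descriptive_table(cc, "arm").to_dict("records"),
        "by_outcome": td.descriptive_table(cc, "outcome").to_dict("records"),
    }
    return RunReport(
        config={
            "outcome": config.outcome,
            "k_copies": config.k_copies,
            "resamples": config.resamples,
            "alpha": config.alpha,
            "sites": list(config.sites),
            "mediator_order": list(config.mediator_order),
            "input": config.input_path or "synthetic",
        },
        complete_case={"retained": cc.retained, "dropped": cc.dropped},
        screening={
            "lima": scr.screening_frame(res_lima).to_dict("records"),
            "saopaulo": scr.screening_frame(res_sp).to_dict("records"),
            "pooled_union": union,
        },
        confounders={"lima": sel_lima, "saopaulo": sel_sp, "pooled": union},
        descriptives=descr,
        site_results=site_results,
        seed=config.seed,
    )


def sensitivity_run(config: PipelineConfig) -> dict:
    """Run the identical pipeline for both outcome definitions.

    Returns ``{"improved50": RunReport, "recovery": RunReport,
    "comparison": DataFrame}`` where the comparison table lists each
    component's estimate and CI side by side for every analysis set.
    """
    from dataclasses import replace

    primary = run_pipeline(replace(config, outcome="improved50"))
    recovery = run_pipeline(replace(config, outcome="recovery"))
    rows = []
    for site in primary.site_results:
        for comp in primary.site_results[site]["effects"]:
            row = {"site": site, "component": comp}
            for label, rep in (("improved50", primary), ("recovery", recovery)):
                res = rep.site_results[site]
                ci = res["bootstrap"].get(comp, {})
                row[f"{label}_estimate"] = res["effects"][comp]
                row[f"{label}_ci_lower"] = ci.get("ci_lower")
                row[f"{label}_ci_upper"] = ci.get("ci_upper")
            rows.append(row)
    return {
        "improved50": primary,
        "recovery": recovery,
        "comparison": pd.DataFrame(rows),
    }
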