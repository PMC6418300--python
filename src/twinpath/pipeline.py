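"""End-to-end analysis pipeline: descriptives -> univariate ladder (+ G x E
moderation) -> item-level model ladder -> comparison reports.

Each stage is a plain function over a :class:`TwinDataset` returning a JSON
-serializable report dict; :func:`run_pipeline` chains them, seeds every
stochastic component from one master seed, and writes the resolved
configuration alongside the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import TwinDataset, descriptives, load_twin_table, residualize
from .fiml import TwinModelResults
from .models import (CommonPathway, DirectVarCov, IndependentPathway,
                     ModeratedACE, SaturatedUnivariate, UnivariateACE,
                     ipm_params_from_cpm, standardize_components)
from .phenotypic import cronbach_alpha, ml_factor_1, one_per_pair, parallel_analysis
from .selection import ComparisonRow, aic, akaike_weights, comparison_frame, \
    comparison_table, lrt
from .simulate import SimConfig, midus_like_config, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    data_path: str | None = None        # CSV input; None -> simulate
    schema: dict | str | None = None
    sim: SimConfig | None = None        # synthetic input; None -> default
    covariates: tuple[str, ...] = ()    # e.g. ("age", "sex") when present
    max_missing_items: int = 2          # scale score missing if > this many
    n_restarts: int = 10
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.sim is not None:
            out["sim"] = self.sim.truth_manifest()
        return out


def scale_scores(data: TwinDataset, max_missing: int = 2) -> TwinDataset:
    """Per-person scale score = mean of the items; missing when more than
    ``max_missing`` items are missing. Returns a single-phenotype dataset."""
    fr = data.frame.copy()
    p = data.p
    for suf in ("_t1", "_t2"):
        cols = [it + suf for it in data.items]
        vals = fr[cols].to_numpy(float)
        n_obs = (~np.isnan(vals)).sum(axis=1)
        score = np.full(len(fr), np.nan)
        ok = n_obs > 0
        score[ok] = np.nansum(vals[ok], axis=1) / n_obs[ok]
        score[np.isnan(vals).sum(axis=1) > max_missing] = np.nan
        fr["scale" + suf] = score
    keep = [c for c in fr.columns if not any(
        c.startswith(it + "_t") for it in data.items)]
    out = fr[keep]
    both_missing = out[["scale_t1", "scale_t2"]].isna().all(axis=1)
    if both_missing.any():
        logger.info("dropping %d pair(s) with no scale score", int(both_missing.sum()))
        out = out.loc[~both_missing].reset_index(drop=True)
    return TwinDataset(out, ["scale"])


# ---------------------------------------------------------------------------
# stages


def run_phenotypic_stage(data: TwinDataset, seed: int = 0) -> dict:
    """Reliability, parallel analysis and 1-factor ML FA on one twin per pair."""
    items = one_per_pair(data, seed=seed)
    pa = parallel_analysis(items, seed=seed + 1)
    loadings, prop, heywood = ml_factor_1(items)
    return {
        "cronbach_alpha": float(cronbach_alpha(items)),
        "parallel_analysis": {
            "adjusted_eigenvalues": pa.adjusted.tolist(),
            "n_retained": pa.n_retained,
        },
        "factor_loadings": loadings.tolist(),
        "factor_proportion_variance": prop,
        "heywood": heywood,
    }


def run_univariate_stage(data: TwinDataset, n_restarts: int = 10,
                         seed: int = 0, compute_ci: bool = True) -> dict:
    """ACE / CE / AE ladder on scale scores, with Akaike weights and the full
    ACE model's path estimates, 95% profile CIs and standardized components."""
    if data.p != 1:
        data = scale_scores(data)
    fits: dict[str, TwinModelResults] = {}
    for comps in ("ACE", "CE", "AE"):
        fit = UnivariateACE(data, components=comps).fit(
            n_restarts=n_restarts, seed=seed)
        if not fit.converged:
            raise RuntimeError(f"univariate {comps} fit failed: {fit.status}")
        fits[comps] = fit
    rows = comparison_table([fits["CE"], fits["AE"]], baseline=fits["ACE"])
    weights = akaike_weights([aic(fits[m]) for m in ("ACE", "CE", "AE")])
    ace = fits["ACE"]
    report = {
        "comparison": comparison_frame(rows).to_dict(orient="records"),
        "akaike_weights": {m: float(w) for m, w in
                           zip(("ACE", "CE", "AE"), weights)},
        "ace_estimates": {k: float(v) for k, v in ace.params.items()},
        "ace_minus2ll": ace.minus2ll,
        "standardized_components":
            {k: float(v) for k, v in standardize_components(ace).items()},
    }
    if compute_ci:
        cis = {nm: list(ace.profile_ci(nm).astuple()) for nm in ("a", "c", "e")}
        report["ace_ci95"] = cis
    report["_fits"] = fits
    return report


def run_moderation_stage(data: TwinDataset, n_restarts: int = 10,
                         seed: int = 0) -> dict | None:
    """Purcell moderation test: full moderated ACE vs the 3-df reduction
    dropping all moderation slopes (the moderated mean is kept)."""
    if data.p != 1:
        data = scale_scores(data)
    if not data.has_moderator:
        logger.info("no moderator column; moderation stage skipped")
        return None
    full = ModeratedACE(data, moderated_paths=True).fit(
        n_restarts=n_restarts, seed=seed)
    reduced = ModeratedACE(data, moderated_paths=False).fit(
        n_restarts=n_restarts, seed=seed)
    if not (full.converged and reduced.converged):
        raise RuntimeError("moderation fits failed to converge")
    delta, ddf, p = lrt(full, reduced)
    return {
        "delta_minus2ll": delta, "delta_df": ddf, "p_value": p,
        "aic_full": aic(full), "aic_reduced": aic(reduced),
        "moderation_supported": p < 0.05,
        "full_estimates": {k: float(v) for k, v in full.params.items()},
        "_fits": {"full": full, "reduced": reduced},
    }


def run_item_stage(data: TwinDataset, n_restarts: int = 10, seed: int = 0,
                   cpm_factors=(1, 2, 3), ipm_factors=(1, 2)) -> dict:
    """Item-level ladder: direct variance-covariance baseline, common-pathway
    models, independent-pathway models, and no-A / no-C reductions of the
    AIC-best common-pathway model."""
    if data.p < 4:
        logger.warning("item stage on %d items; EP accounting adjusts", data.p)
    baseline = DirectVarCov(data).fit(n_restarts=n_restarts, seed=seed)
    if not baseline.converged:
        raise RuntimeError("baseline fit failed")

    # fit the common-pathway ladder warm-starting each model from its nested
    # neighbour (the nesting identities guarantee the warm start is feasible
    # and keep the fitted deviances monotone along the ladder)
    cpms: dict[int, TwinModelResults] = {}
    prev_params = None
    for f in sorted(cpm_factors):
        model = CommonPathway(data, n_factors=f)
        extra = [model.encode(prev_params)] if prev_params is not None else []
        cpms[f] = model.fit(n_restarts=n_restarts, seed=seed + f,
                            extra_starts=extra)
        if cpms[f].converged:
            prev_params = model._unpack(cpms[f].x_internal)

    ipms: dict[int, TwinModelResults] = {}
    prev_ipm = None
    for f in sorted(ipm_factors):
        model = IndependentPathway(data, n_factors=f)
        extra = []
        if f in cpms and cpms[f].converged:
            cp = cpms[f].model._unpack(cpms[f].x_internal)
            extra.append(model.encode(ipm_params_from_cpm(cp)))
        if prev_ipm is not None:
            extra.append(model.encode(prev_ipm))
        ipms[f] = model.fit(n_restarts=n_restarts, seed=seed + 10 + f,
                            extra_starts=extra)
        if ipms[f].converged:
            prev_ipm = model._unpack(ipms[f].x_internal)
    ladder = list(cpms.values()) + list(ipms.values())
    if any(not f.converged for f in ladder):
        raise RuntimeError("an item-level fit failed to converge")

    rows = comparison_table(ladder, baseline=baseline)

    best_cpm_f = min(cpms, key=lambda f: cpms[f].aic)
    best_cpm = cpms[best_cpm_f]
    best_ipm = min(ipms.values(), key=lambda r: r.aic) if ipms else None

    # quasi-nested CP-vs-IP comparison row, when the IPM is the larger model
    if best_ipm is not None and best_ipm.ep > best_cpm.ep:
        d, ddf, p = lrt(best_ipm, best_cpm)
        rows.append(ComparisonRow(
            model=best_cpm.model.name, ep=best_cpm.ep, delta_minus2ll=d,
            delta_df=ddf, p_value=p, aic=best_cpm.aic,
            compare_with=best_ipm.model.name))

    best_params = best_cpm.model._unpack(best_cpm.x_internal)
    reductions = {}
    for drop in ("C", "A"):
        red_model = CommonPathway(data, n_factors=best_cpm_f, drop=drop)
        red = red_model.fit(n_restarts=n_restarts, seed=seed + 20,
                            extra_starts=[red_model.encode(best_params)])
        if not red.converged:
            raise RuntimeError(f"no-{drop} reduction failed to converge")
        d, ddf, p = lrt(best_cpm, red)
        rows.append(ComparisonRow(
            model=red.model.name, ep=red.ep, delta_minus2ll=d, delta_df=ddf,
            p_value=p, aic=aic(red), compare_with=best_cpm.model.name))
        reductions[drop] = red

    se = best_cpm.wald_se()
    best_table = pd.DataFrame({"estimate": best_cpm.params, "se": se})
    return {
        "comparison": comparison_frame(rows).to_dict(orient="records"),
        "best_model": best_cpm.model.name,
        "best_model_aic": best_cpm.aic,
        "best_estimates": {k: [float(best_table.loc[k, "estimate"]),
                               float(best_table.loc[k, "se"])]
                           for k in best_table.index},
        "factor_components": standardize_components(best_cpm).to_dict(orient="index"),
        "_fits": {"baseline": baseline, "cpm": cpms, "ipm": ipms,
                  "reduced": reductions},
    }


# ---------------------------------------------------------------------------
# orchestration


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items()
                if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write reports under ``config.out_dir`` if set."""
    if config.data_path is not None:
        data = load_twin_table(config.data_path, config.schema)
    else:
        sim = config.sim if config.sim is not None \
            else midus_like_config(seed=config.seed)
        data = simulate(sim)

    if config.covariates:
        data = residualize(data, config.covariates)

    report: dict = {"config": config.to_dict(), "version": __version__,
                    "n_mz": data.n_mz, "n_dz": data.n_dz, "p": data.p}
    desc = descriptives(data)
    report["descriptives"] = {"avg_r": desc.avg_r}

    if data.p > 1:
        report["phenotypic"] = run_phenotypic_stage(data, seed=config.seed)

    scores = scale_scores(data, config.max_missing_items) if data.p > 1 else data
    report["univariate"] = run_univariate_stage(
        scores, n_restarts=config.n_restarts, seed=config.seed)
    mod = run_moderation_stage(scores, n_restarts=config.n_restarts,
                               seed=config.seed)
    if mod is not None:
        report["moderation"] = mod
    if data.p >= 4:
        report["items"] = run_item_stage(data, n_restarts=config.n_restarts,
                                         seed=config.seed)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        desc.table.to_csv(out / "descriptives.csv")
        clean = _strip_private(report)
        (out / "report.json").write_text(json.dumps(clean, indent=2))
        (out / "config.yaml").write_text(yaml.safe_dump(clean["config"]))
        for key in ("univariate", "items"):
            if key in report:
                pd.DataFrame(report[key]["comparison"]).to_csv(
                    out / f"comparison_{key}.csv", index=False)
        logger.info("pipeline outputs written to %s", out)
    return report
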