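"""Likelihood-ratio testing, AIC and Akaike weights, and comparison tables.

Degrees of freedom for a nested comparison are ``delta EP + delta
constraints``: a model that trades a free parameter for a nonlinear equality
constraint gives the test one extra degree of freedom, which is what makes
the common-pathway ledger (36 free parameters dropped but 37 df against the
direct variance-covariance baseline at one factor) come out right.

Boundary effects on the likelihood-ratio null (variance components tested at
zero) are ignored — the plain chi-square reference is used throughout, a
known approximation documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .fiml import TwinModelResults

logger = logging.getLogger(__name__)

#: p-values below this render as "< 0.001" in reports
P_RENDER_FLOOR = 1e-3


class NestingError(ValueError):
    """Models are not nested; the likelihood-ratio test is refused."""


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability (regularized incomplete gamma)."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(chi2.sf(x, df))


def aic(fit: TwinModelResults) -> float:
    """AIC = -2 log L + 2 EP."""
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return fit.minus2ll + 2.0 * fit.ep


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(-(AIC_i - min AIC)/2), normalized to sum 1.

    Interpretable as conditional model probabilities over the candidate set;
    invariant to adding a constant to every AIC.
    """
    arr = np.asarray(list(aics), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two AIC values")
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("all AIC values are non-finite")
    delta = arr - np.min(arr[finite])
    w = np.where(finite, np.exp(-0.5 * delta), 0.0)
    return w / w.sum()


def lrt(full: TwinModelResults, reduced: TwinModelResults
        ) -> tuple[float, int, float]:
    """(delta -2LL, delta df, p) for `reduced` against the nesting `full`.

    Nesting is validated structurally; a tiny negative deviance difference
    (> -1e-6, numerical noise) is clamped to zero with a warning.
    """
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    if full.model is reduced.model:
        raise NestingError("identical models: nothing to test")
    if not reduced.model.is_nested_in(full.model):
        raise NestingError(
            f"{reduced.model.name!r} is not nested in {full.model.name!r}")
    delta = reduced.minus2ll - full.minus2ll
    if delta < 0:
        if delta > -1e-6:
            logger.warning("clamping tiny negative delta -2LL (%.2e) to 0", delta)
            delta = 0.0
        else:
            raise ValueError(
                f"reduced model fits better by {-delta:.4g}; the full model's "
                "optimum was not found")
    # a nonlinear equality constraint removes one effective free parameter,
    # so it *adds* to the df of a comparison against a less-constrained model
    ddf = (full.ep - reduced.ep) + (reduced.n_constraints - full.n_constraints)
    if ddf < 1:
        raise NestingError("comparison has no degrees of freedom")
    return float(delta), int(ddf), chisq_sf(delta, ddf)


@dataclass
class ComparisonRow:
    """One row of a fit-comparison table (the Model/EP/delta-2LL/df/p/AIC schema)."""

    model: str
    ep: int
    delta_minus2ll: float | None
    delta_df: int | None
    p_value: float | None
    aic: float
    compare_with: str | None
    best: bool = False

    def render_p(self) -> str:
        if self.p_value is None:
            return ""
        if self.p_value < P_RENDER_FLOOR:
            return "< 0.001"
        return f"{self.p_value:.3f}"


def comparison_table(fits, baseline: TwinModelResults,
                     targets: dict | None = None) -> list[ComparisonRow]:
    """Comparison report: baseline row (EP and AIC only) plus one LRT row per
    fit against its comparison target (the baseline unless ``targets`` maps a
    fit's model name to another fit in the list). Flags the AIC-best row
    among baseline and unreduced fits."""
    fits = list(fits)
    by_name = {f.model.name: f for f in fits}
    rows = [ComparisonRow(model=baseline.model.name, ep=baseline.ep,
                          delta_minus2ll=None, delta_df=None, p_value=None,
                          aic=aic(baseline), compare_with=None)]
    for f in fits:
        target = baseline
        if targets and f.model.name in targets:
            tname = targets[f.model.name]
            target = by_name.get(tname, baseline) if isinstance(tname, str) else tname
        d, ddf, p = lrt(target, f)
        rows.append(ComparisonRow(model=f.model.name, ep=f.ep,
                                  delta_minus2ll=d, delta_df=ddf, p_value=p,
                                  aic=aic(f), compare_with=target.model.name))
    best_idx = int(np.argmin([r.aic for r in rows]))
    rows[best_idx].best = True
    return rows


def comparison_markdown(rows) -> str:
    """Markdown rendering of a comparison table."""
    frame = comparison_frame(rows)
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in frame.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.2f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def comparison_frame(rows) -> pd.DataFrame:
    """Render ComparisonRows as a DataFrame (p column formatted for print)."""
    return pd.DataFrame([
        {"model": r.model, "EP": r.ep,
         "delta_minus2LL": r.delta_minus2ll if r.delta_minus2ll is not None else "",
         "delta_df": r.delta_df if r.delta_df is not None else "",
         "p": r.render_p(), "AIC": round(r.aic, 2),
         "compare_with": r.compare_with or "", "best": r.best}
        for r in rows])
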