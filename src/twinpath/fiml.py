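"""Full-information maximum-likelihood engine for twin-pair models.

Every pair contributes the multivariate-normal deviance of its *observed*
entries only::

    -2 log L_i = k_i log(2 pi) + log|Sigma_i| + (x_i - mu_i)' Sigma_i^{-1} (x_i - mu_i)

where ``Sigma_i``/``mu_i`` are the rows/columns of the pair's zygosity-group
expected moments selected by its non-missing entries. A co-twin that is
entirely missing simply drops out, so singleton pairs are handled without
imputation.

For models whose moments are constant within a zygosity group the sum is
accumulated per missingness *pattern* from sufficient statistics, making the
cost of one deviance evaluation independent of sample size. Models with
pair-varying moments (G x E moderation) evaluate per pair.

The module also houses the generic model/results machinery: ``TwinModel``
subclasses supply a parameter vector -> moments map; ``fit`` runs multi-start
quasi-Newton optimization; ``TwinModelResults`` carries estimates, the
EP/constraint ledger used for degree-of-freedom accounting, and
profile-likelihood confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from scipy.stats import chi2

from .data import DZ, GROUPS, MZ, TwinDataset

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12  # optimizer-safe stand-in for +inf inside line searches


@dataclass
class ExpectedMoments:
    """Model-implied mean vector (length 2p) and 2p x 2p covariance for one group.

    Ordering matches :meth:`TwinDataset.phenotypes`: twin-1 items then twin-2
    items. The covariance must be symmetric with identical within-twin blocks.
    """

    group: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        k = self.mean.shape[0]
        if self.cov.shape != (k, k):
            raise ValueError("mean/covariance dimensions disagree")


# ---------------------------------------------------------------------------
# deviance evaluation


@dataclass
class _Pattern:
    mask: np.ndarray   # bool, length 2p
    n: int
    s1: np.ndarray     # sum of observed rows
    s2: np.ndarray     # sum of outer products of observed rows


def pattern_stats(y: np.ndarray) -> list[_Pattern]:
    """Sufficient statistics of an (n, k) data matrix per missingness pattern."""
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    out: list[_Pattern] = []
    if y.size == 0:
        return out
    codes = obs @ (1 << np.arange(y.shape[1], dtype=np.int64))
    for code in np.unique(codes):
        rows = codes == code
        mask = obs[np.argmax(rows)]
        if not mask.any():
            continue
        x = y[np.ix_(rows, mask)]
        out.append(_Pattern(mask=mask, n=x.shape[0], s1=x.sum(axis=0), s2=x.T @ x))
    return out


def neg2ll_from_stats(stats: Sequence[_Pattern], mean: np.ndarray,
                      cov: np.ndarray) -> float:
    """FIML deviance of one group given homogeneous expected moments.

    Returns ``+inf`` when the covariance sub-matrix of any observed pattern
    fails its Cholesky factorization (not positive definite).
    """
    total = 0.0
    for pat in stats:
        mu = mean[pat.mask]
        sig = cov[np.ix_(pat.mask, pat.mask)]
        try:
            chol = sla.cholesky(sig, lower=True, check_finite=False)
        except sla.LinAlgError:
            return np.inf
        diag = np.einsum("ii->i", chol)
        logdet = 2.0 * float(np.sum(np.log(diag)))
        k = mu.shape[0]
        sinv_s2 = sla.cho_solve((chol, True), pat.s2, check_finite=False)
        sinv_mu = sla.cho_solve((chol, True), mu, check_finite=False)
        quad = float(np.einsum("ii->", sinv_s2)) - 2.0 * float(pat.s1 @ sinv_mu) \
            + pat.n * float(mu @ sinv_mu)
        total += pat.n * (k * LOG_2PI + logdet) + quad
    return total


def fiml_neg2ll(data: TwinDataset,
                moments: Mapping[str, ExpectedMoments]) -> float:
    """Total FIML deviance of a dataset under per-group expected moments."""
    total = 0.0
    for group in GROUPS:
        y = data.phenotypes(group)
        if y.shape[0] == 0:
            continue
        m = moments[group]
        total += neg2ll_from_stats(pattern_stats(y), m.mean, m.cov)
    return float(total)


def moment_form_neg2ll(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Complete-data Gaussian deviance from sample moments (the FIML oracle).

    ``N [ q log(2 pi) + log|Sigma| + tr(Sigma^{-1} S) + (xbar-mu)' Sigma^{-1} (xbar-mu) ]``
    with S the ML (denominator N) sample covariance. Requires complete data.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("moment-form deviance requires complete data")
    n, q = y.shape
    xbar = y.mean(axis=0)
    s = (y - xbar).T @ (y - xbar) / n
    chol = sla.cholesky(cov, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    d = xbar - mean
    return float(n * (q * LOG_2PI + logdet
                      + np.trace(sla.cho_solve((chol, True), s))
                      + d @ sla.cho_solve((chol, True), d)))


# ---------------------------------------------------------------------------
# model base class


class TwinModel:
    """Base class for FIML-fitted twin models (statsmodels-style).

    Subclasses define an *internal* unconstrained parameter vector (what the
    optimizer sees) and a mapping to *reported* parameters (paths, loadings,
    means). Nonlinear equality constraints (unit factor variances) are made
    exact by spherical reparameterization internally while the reported table
    and the ``(ep, n_constraints)`` ledger keep the conventional accounting:
    comparison df = delta EP + delta constraints.
    """

    name: str = "twin model"

    def __init__(self, data: TwinDataset):
        self.data = data
        self._stats = {g: pattern_stats(data.phenotypes(g)) for g in GROUPS}
        self._nonpd_logged = False

    # -- to be provided by subclasses --------------------------------------

    @property
    def internal_names(self) -> list[str]:
        raise NotImplementedError

    def start_internal(self) -> np.ndarray:
        raise NotImplementedError

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        """Expected moments for homogeneous-group models."""
        raise NotImplementedError

    def moments_arrays(self, x: np.ndarray, group: str
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(mean, cov) fast path used inside the optimizer loop.

        Defaults to :meth:`moments`; subclasses override with validation-free
        array construction (the numbers are identical).
        """
        m = self.moments(x, group)
        return m.mean, m.cov

    def reported(self, x: np.ndarray) -> pd.Series:
        """Map internal coordinates to the reported parameter table."""
        raise NotImplementedError

    @property
    def ep(self) -> int:
        raise NotImplementedError

    @property
    def n_constraints(self) -> int:
        return 0

    #: reported-name -> internal index, for parameters where the two coincide
    identity_map: dict[str, int] = {}

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        """Map a solution to its reporting representative (sign conventions).

        Must leave the deviance unchanged; the default is the identity.
        """
        return np.asarray(x, float)

    def is_nested_in(self, other: "TwinModel") -> bool:
        return False

    # -- deviance -----------------------------------------------------------

    def deviance(self, x: np.ndarray) -> float:
        x = np.asarray(x, float)
        total = 0.0
        for group in GROUPS:
            if not self._stats[group]:
                continue
            mean, cov = self.moments_arrays(x, group)
            total += neg2ll_from_stats(self._stats[group], mean, cov)
        return float(total)

    def _objective(self, x: np.ndarray) -> float:
        val = self.deviance(x)
        if not np.isfinite(val):
            if not self._nonpd_logged:
                logger.info("%s: non-PD moments encountered during optimization",
                            self.name)
                self._nonpd_logged = True
            return _PENALTY
        return val

    # -- fitting ------------------------------------------------------------

    def fit(self, n_restarts: int = 10, jitter: float = 0.2, seed: int = 0,
            maxfun: int | None = None, early_stop: bool = True,
            start: np.ndarray | None = None,
            extra_starts: Sequence[np.ndarray] = ()) -> "TwinModelResults":
        """Minimize the FIML deviance with jittered multi-start L-BFGS.

        The first start is the model's moment-based heuristic (or ``start``);
        ``extra_starts`` (e.g. solutions of nested models mapped into this
        model's coordinates) are tried next; remaining restarts jitter the
        heuristic by ``+- jitter`` (relative, with an absolute floor). With
        ``early_stop`` the loop ends once three starts agree with the
        incumbent best deviance to 1e-6 (the usual signature of a dominant
        basin); a failed fit is never reported as success.
        """
        rng = np.random.default_rng(seed)
        x0 = np.asarray(start if start is not None else self.start_internal(), float)
        if maxfun is None:
            # numerical gradients cost dim+1 evaluations per iteration; give
            # high-dimensional models a proportionate budget
            maxfun = 5000 + 800 * x0.size
        self._nonpd_logged = False

        queue = [x0] + [np.asarray(s, float) for s in extra_starts]
        total = n_restarts + len(queue)
        best = None
        n_agree = 0
        used = 0
        for r in range(total):
            xs = queue[r] if r < len(queue) else self._jittered_start(x0, rng, jitter)
            res = optimize.minimize(
                self._objective, xs, method="L-BFGS-B",
                options={"maxfun": maxfun, "ftol": 1e-12, "gtol": 1e-7},
            )
            used += 1
            if best is None or res.fun < best.fun - 1e-9:
                if best is not None and abs(res.fun - best.fun) > 1e-6:
                    n_agree = 0
                best = res
            if abs(res.fun - best.fun) <= 1e-6:
                n_agree += 1
            if early_stop and n_agree >= 3 and best.success and r + 1 >= len(queue):
                break

        status = "converged" if best.success and best.fun < _PENALTY / 2 else "failed"
        if status == "failed":
            logger.warning("%s: optimization did not converge (%s)",
                           self.name, best.message)
        return TwinModelResults(
            model=self, x_internal=self.canonicalize(np.asarray(best.x, float)),
            minus2ll=float(best.fun), status=status, n_restarts_used=used)

    def _jittered_start(self, x0: np.ndarray, rng: np.random.Generator,
                        jitter: float) -> np.ndarray:
        scale = np.maximum(np.abs(x0), 0.25)
        return x0 + rng.uniform(-jitter, jitter, size=x0.shape) * scale


def fit_model(data: TwinDataset, spec, **options) -> "TwinModelResults":
    """Functional front end: fit a model specification to a dataset.

    ``spec`` may be a :class:`TwinModel` subclass (instantiated on ``data``),
    a ready-built instance on the same data, or a one-argument factory
    ``data -> TwinModel`` (e.g. ``lambda d: CommonPathway(d, n_factors=3)``).
    """
    if isinstance(spec, type) and issubclass(spec, TwinModel):
        model = spec(data)
    elif isinstance(spec, TwinModel):
        if spec.data is not data:
            raise ValueError("model instance is bound to a different dataset; "
                             "pass a factory instead")
        model = spec
    elif callable(spec):
        model = spec(data)
    else:
        raise TypeError("spec must be a TwinModel subclass, instance, or factory")
    return model.fit(**options)


# ---------------------------------------------------------------------------
# results


@dataclass
class ProfileInterval:
    lower: float
    upper: float
    lower_found: bool = True
    upper_found: bool = True

    def astuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)


class TwinModelResults:
    """Fit results: deviance, estimates, EP ledger, CIs, summary table."""

    def __init__(self, model: TwinModel, x_internal: np.ndarray, minus2ll: float,
                 status: str, n_restarts_used: int):
        self.model = model
        self.x_internal = x_internal
        self.minus2ll = minus2ll
        self.status = status
        self.n_restarts_used = n_restarts_used
        self.ci: dict[str, ProfileInterval] = {}

    # -- scalar summaries ---------------------------------------------------

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def ep(self) -> int:
        return self.model.ep

    @property
    def n_constraints(self) -> int:
        return self.model.n_constraints

    @property
    def params(self) -> pd.Series:
        return self.model.reported(self.x_internal)

    # estimates is the spec-facing alias for the reported parameter table
    estimates = params

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.ep

    def standardized_components(self):
        from .models import standardize_components
        return standardize_components(self)

    # -- uncertainty --------------------------------------------------------

    def wald_se(self, step: float = 1e-4) -> pd.Series:
        """Delta-method standard errors from the numerical deviance Hessian."""
        x = self.x_internal
        h = _numerical_hessian(self.model._objective, x, step)
        cov_int = 2.0 * np.linalg.pinv(h)  # deviance = 2 * negloglik
        jac = _numerical_jacobian(lambda z: self.model.reported(z).to_numpy(float),
                                  x, step)
        cov_rep = jac @ cov_int @ jac.T
        var = np.clip(np.diag(cov_rep), 0.0, None)
        return pd.Series(np.sqrt(var), index=self.params.index)

    def profile_ci(self, param: str, level: float = 0.95,
                   tol: float = 1e-4) -> ProfileInterval:
        """Profile-likelihood interval: deviance rise of chi2(1) quantile.

        Paths are sign-unbounded, so intervals may cross zero. If a bound is
        not found inside the search box the interval is flagged one-sided.
        """
        iv = profile_ci(self, param, level=level, tol=tol)
        self.ci[param] = iv
        return iv

    def conf_int(self, params: Iterable[str] | None = None,
                 level: float = 0.95) -> pd.DataFrame:
        names = list(params) if params is not None else list(self.params.index)
        rows = {nm: self.profile_ci(nm, level=level).astuple() for nm in names}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["lower", "upper"])

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        est = self.params
        lines = [
            f"{self.model.name}",
            "=" * 58,
            f"-2 log L      {self.minus2ll:14.4f}    AIC  {self.aic:12.4f}",
            f"EP            {self.ep:4d}    constraints {self.n_constraints:2d}"
            f"    status: {self.status}",
            "-" * 58,
            f"{'parameter':<18}{'estimate':>12}  {'95% CI':>22}",
        ]
        for nm, val in est.items():
            if nm in self.ci:
                lo, hi = self.ci[nm].astuple()
                ci_txt = f"[{lo:8.3f}, {hi:8.3f}]"
            else:
                ci_txt = ""
            lines.append(f"{nm:<18}{val:12.4f}  {ci_txt:>22}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def estimates_frame(self) -> pd.DataFrame:
        """Path-table export: estimate with lower/upper bounds where a CI
        has been computed (suitable for CSV path tables)."""
        est = self.params
        lower = pd.Series({k: v.lower for k, v in self.ci.items()})
        upper = pd.Series({k: v.upper for k, v in self.ci.items()})
        return pd.DataFrame({"estimate": est,
                             "lower": lower.reindex(est.index),
                             "upper": upper.reindex(est.index)})

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "minus2ll": self.minus2ll,
            "ep": self.ep,
            "n_constraints": self.n_constraints,
            "aic": self.aic,
            "status": self.status,
            "n_restarts_used": self.n_restarts_used,
            "estimates": {k: float(v) for k, v in self.params.items()},
            "ci": {k: [v.lower, v.upper] for k, v in self.ci.items()},
        }


#: spec-facing alias
FitResult = TwinModelResults


# ---------------------------------------------------------------------------
# profile likelihood


def _profile_deviance(results: TwinModelResults, param: str, value: float,
                      warm: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum deviance with one reported parameter pinned at `value`."""
    model = results.model
    idx = model.identity_map.get(param)
    if idx is not None:
        free = np.ones(len(warm), dtype=bool)
        free[idx] = False

        def obj(z):
            x = warm.copy()
            x[idx] = value
            x[free] = z
            return model._objective(x)

        res = optimize.minimize(obj, warm[free], method="L-BFGS-B",
                                options={"maxfun": 4000, "ftol": 1e-12})
        x = warm.copy()
        x[idx] = value
        x[free] = res.x
        return float(res.fun), x

    names = list(results.params.index)
    if param not in names:
        raise KeyError(f"unknown parameter {param!r}")
    j = names.index(param)

    res = optimize.minimize(
        model._objective, warm, method="SLSQP",
        constraints=[{"type": "eq",
                      "fun": lambda x: model.reported(x).iloc[j] - value}],
        options={"maxiter": 400, "ftol": 1e-10},
    )
    return float(res.fun), np.asarray(res.x, float)


def profile_ci(results: TwinModelResults, param: str, level: float = 0.95,
               tol: float = 1e-4, max_doublings: int = 30) -> ProfileInterval:
    if not results.converged:
        raise ValueError("profile CI requires a converged fit")
    threshold = results.minus2ll + float(chi2.ppf(level, 1))
    est = float(results.params[param])

    try:
        se = float(results.wald_se()[param])
    except Exception:  # pragma: no cover - fallback scale
        se = 0.0
    step0 = se if np.isfinite(se) and se > 1e-8 else 0.1 * max(1.0, abs(est))

    def pdev(value, warm):
        # re-optimize nuisance parameters from both the carried warm start
        # and the MLE, keeping the better: a warm start from across a ridge
        # can strand the local search at an inflated profile value
        d1, x1 = _profile_deviance(results, param, value, warm)
        d2, x2 = _profile_deviance(results, param, value,
                                   results.x_internal.copy())
        return (d1, x1) if d1 <= d2 else (d2, x2)

    bounds = {}
    found = {}
    for direction in (-1.0, +1.0):
        warm = results.x_internal.copy()
        v_in = est
        step = step0
        v_out = None
        for _ in range(max_doublings):
            v_try = v_in + direction * step
            dev, warm = pdev(v_try, warm)
            if dev > threshold:
                v_out = v_try
                break
            v_in = v_try
            step *= 1.7
        if v_out is None:
            bounds[direction] = v_in
            found[direction] = False
            continue
        # bisect between v_in (below threshold) and v_out (above)
        lo, hi = (v_in, v_out)
        while abs(hi - lo) > tol:
            mid = 0.5 * (lo + hi)
            dev, warm = pdev(mid, warm)
            if dev > threshold:
                hi = mid
            else:
                lo = mid
        bounds[direction] = 0.5 * (lo + hi)
        found[direction] = True

    return ProfileInterval(lower=bounds[-1.0], upper=bounds[+1.0],
                           lower_found=found[-1.0], upper_found=found[+1.0])


# ---------------------------------------------------------------------------
# numerical derivatives (small fixed-step central differences; adequate at the
# smooth, well-scaled optima these models produce)


def _numerical_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                       step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, float)
    k = x.size
    h = np.maximum(np.abs(x), 1.0) * step
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            val = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _numerical_jacobian(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                        step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, float)
    h = np.maximum(np.abs(x), 1.0) * step
    cols = []
    for i in range(x.size):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        cols.append((f(xp) - f(xm)) / (2.0 * h[i]))
    return np.column_stack(cols)
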