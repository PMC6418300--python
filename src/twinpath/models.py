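"""Biometric twin models: parameter containers, expected-moment builders, and
FIML-fitted model classes.

All models share the classical twin-design identification device: additive
genetic latents correlate 1.0 across MZ co-twins and 0.5 across DZ co-twins,
shared-environment latents correlate 1.0 in both groups, unique-environment
latents are independent. Latents have unit variance; scale lives in the paths.

Model families
--------------
``UnivariateACE``      one phenotype; sub-models ACE / AE / CE / E
``SaturatedUnivariate`` free per-group means/variances/covariance (baseline)
``ModeratedACE``       Purcell-style G x E moderation: every path (and the
                       mean) a linear function of a pair-level moderator
``CommonPathway``      f latent psychometric factors, each with its own unit
                       -variance ACE decomposition, loading on all items;
                       plus item-specific ACE influences
``IndependentPathway`` separate A-, C-, E-common factor loadings per item
``DirectVarCov``       saturated baseline estimating full symmetric A, C, E
                       component matrices directly, with no positivity
                       constraint on the individual components

Degrees of freedom for comparisons are ``delta EP + delta constraints``:
means are equated across twin order and zygosity, the f unit-variance factor
constraints of the common-pathway model are counted separately from its free
parameters, and the unconstrained loading matrices of multi-factor models are
left rotationally free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DZ, GROUPS, MZ, TwinDataset
from .fiml import ExpectedMoments, LOG_2PI, TwinModel, TwinModelResults

logger = logging.getLogger(__name__)

#: DZ additive-genetic cross-twin correlation; 0.5 under random mating.
#: Raising it models assortative mating (exposed, not exercised here).
DZ_RA = 0.5


def _r_a(group: str, dz_ra: float = DZ_RA) -> float:
    return 1.0 if group == MZ else dz_ra


def _fast_assemble(means: np.ndarray, within: np.ndarray,
                   cross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean, cov) without validation; `cross` must already be symmetric."""
    p = means.shape[0]
    mean = np.concatenate([means, means])
    cov = np.empty((2 * p, 2 * p))
    cov[:p, :p] = within
    cov[p:, p:] = within
    cov[:p, p:] = cross
    cov[p:, :p] = cross
    return mean, cov


def _assemble(group: str, means: np.ndarray, within: np.ndarray,
              cross: np.ndarray) -> ExpectedMoments:
    means = np.atleast_1d(np.asarray(means, float))
    within = np.atleast_2d(np.asarray(within, float))
    cross = np.atleast_2d(np.asarray(cross, float))
    mean = np.concatenate([means, means])
    cov = np.block([[within, cross], [cross.T, within]])
    return ExpectedMoments(group=group, mean=mean, cov=cov)


# ---------------------------------------------------------------------------
# parameter containers and moment builders


@dataclass
class UnivariateACEParams:
    a: float
    c: float
    e: float
    b0: float = 0.0


def univariate_ace_moments(params: UnivariateACEParams, group: str,
                           dz_ra: float = DZ_RA) -> ExpectedMoments:
    """Var = a^2+c^2+e^2; cross-twin Cov = r_A a^2 + c^2 with r_A = 1 (MZ), 0.5 (DZ)."""
    a2, c2, e2 = params.a ** 2, params.c ** 2, params.e ** 2
    var = a2 + c2 + e2
    cov = _r_a(group, dz_ra) * a2 + c2
    return _assemble(group, [params.b0], [[var]], [[cov]])


def saturated_univariate_moments(mean_t1: float, mean_t2: float, var_t1: float,
                                 var_t2: float, cov: float,
                                 group: str) -> ExpectedMoments:
    """Pass-through unstructured bivariate moments for one group."""
    mean = np.array([mean_t1, mean_t2])
    sigma = np.array([[var_t1, cov], [cov, var_t2]])
    return ExpectedMoments(group=group, mean=mean, cov=sigma)


@dataclass
class ModeratedACEParams:
    a0: float
    a1: float
    c0: float
    c1: float
    e0: float
    e1: float
    b0: float = 0.0
    bM: float = 0.0


def moderated_ace_moments(params: ModeratedACEParams, group: str, M: float,
                          dz_ra: float = DZ_RA) -> ExpectedMoments:
    """Purcell moderation: paths (and the mean) linear in the pair moderator M."""
    a = params.a0 + params.a1 * M
    c = params.c0 + params.c1 * M
    e = params.e0 + params.e1 * M
    mu = params.b0 + params.bM * M
    var = a * a + c * c + e * e
    cov = _r_a(group, dz_ra) * a * a + c * c
    return _assemble(group, [mu], [[var]], [[cov]])


@dataclass
class CPMParams:
    loadings: np.ndarray   # (p, f)
    a_f: np.ndarray        # (f,)
    c_f: np.ndarray
    e_f: np.ndarray
    a_s: np.ndarray        # (p,)
    c_s: np.ndarray
    e_s: np.ndarray
    b0: np.ndarray         # (p,)

    def __post_init__(self):
        for name in ("loadings", "a_f", "c_f", "e_f", "a_s", "c_s", "e_s", "b0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.loadings = np.atleast_2d(self.loadings)


def cpm_moments(params: CPMParams, group: str, dz_ra: float = DZ_RA,
                check: bool = True) -> ExpectedMoments:
    """Common-pathway moments.

    Within-twin Cov = Lam Lam' + diag(specific totals) (each factor has unit
    variance by the a_f^2+c_f^2+e_f^2 = 1 constraint); cross-twin
    Cov = Lam diag(r_A a_f^2 + c_f^2) Lam' + diag(r_A a_s^2 + c_s^2).
    """
    tot_f = params.a_f ** 2 + params.c_f ** 2 + params.e_f ** 2
    if check and np.any(np.abs(tot_f - 1.0) > 1e-8):
        raise ValueError(f"factor variance constraint violated: {tot_f}")
    lam = params.loadings
    ra = _r_a(group, dz_ra)
    spec_tot = params.a_s ** 2 + params.c_s ** 2 + params.e_s ** 2
    spec_cross = ra * params.a_s ** 2 + params.c_s ** 2
    within = lam @ np.diag(tot_f) @ lam.T + np.diag(spec_tot)
    cross = lam @ np.diag(ra * params.a_f ** 2 + params.c_f ** 2) @ lam.T \
        + np.diag(spec_cross)
    return _assemble(group, params.b0, within, cross)


@dataclass
class IPMParams:
    a_load: np.ndarray     # (p, f)
    c_load: np.ndarray
    e_load: np.ndarray
    a_s: np.ndarray        # (p,)
    c_s: np.ndarray
    e_s: np.ndarray
    b0: np.ndarray

    def __post_init__(self):
        for name in ("a_load", "c_load", "e_load"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        for name in ("a_s", "c_s", "e_s", "b0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


def ipm_moments(params: IPMParams, group: str, dz_ra: float = DZ_RA) -> ExpectedMoments:
    """Independent-pathway moments; r_A enters only the A terms."""
    ra = _r_a(group, dz_ra)
    aa = params.a_load @ params.a_load.T
    cc = params.c_load @ params.c_load.T
    ee = params.e_load @ params.e_load.T
    within = aa + cc + ee + np.diag(params.a_s ** 2 + params.c_s ** 2
                                    + params.e_s ** 2)
    cross = ra * aa + cc + np.diag(ra * params.a_s ** 2 + params.c_s ** 2)
    return _assemble(group, params.b0, within, cross)


def ipm_params_from_cpm(params: CPMParams) -> IPMParams:
    """The nesting identity: loading matrices = Lam * factor path, specifics kept."""
    lam = params.loadings
    return IPMParams(
        a_load=lam * params.a_f, c_load=lam * params.c_f, e_load=lam * params.e_f,
        a_s=params.a_s, c_s=params.c_s, e_s=params.e_s, b0=params.b0)


@dataclass
class DirectVarCovParams:
    A: np.ndarray          # (p, p) symmetric, not constrained PSD
    C: np.ndarray
    E: np.ndarray
    b0: np.ndarray

    def __post_init__(self):
        for name in ("A", "C", "E"):
            m = np.atleast_2d(np.asarray(getattr(self, name), float))
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} component matrix must be symmetric")
            setattr(self, name, m)
        self.b0 = np.asarray(self.b0, dtype=float)


def direct_varcov_moments(params: DirectVarCovParams, group: str,
                          dz_ra: float = DZ_RA) -> ExpectedMoments:
    """Direct variance-covariance baseline: within = A+C+E, cross = r_A A + C.

    The individual component matrices are deliberately *not* constrained
    positive semidefinite — that freedom is what makes this baseline unbiased
    where a Cholesky-parameterized one is not; only the total within-twin
    covariance must be PD at evaluation (the engine rejects otherwise).
    """
    ra = _r_a(group, dz_ra)
    within = params.A + params.C + params.E
    cross = ra * params.A + params.C
    return _assemble(group, params.b0, within, cross)


# ---------------------------------------------------------------------------
# shared start-value helpers


def _pooled_within_cov(data: TwinDataset) -> tuple[np.ndarray, np.ndarray]:
    """(mean, covariance) over individuals, pooling twins; pairwise-complete."""
    y = data.phenotypes()
    p = data.p
    stacked = np.vstack([y[:, :p], y[:, p:]])
    mean = np.nanmean(stacked, axis=0)
    frame = pd.DataFrame(stacked)
    cov = frame.cov().to_numpy()
    cov = np.where(np.isnan(cov), 0.0, cov)
    return mean, cov


def _cross_twin_cov(data: TwinDataset, group: str) -> np.ndarray:
    """Pairwise-complete cross-twin covariance block, symmetrized."""
    y = data.phenotypes(group)
    p = data.p
    frame = pd.DataFrame(np.hstack([y[:, :p], y[:, p:]]))
    full = frame.cov().to_numpy()
    b = full[:p, p:]
    b = np.where(np.isnan(b), 0.0, b)
    return 0.5 * (b + b.T)


def _shrink_to_diag(m: np.ndarray, amount: float = 0.1) -> np.ndarray:
    return (1.0 - amount) * m + amount * np.diag(np.diag(m))


def _moment_decomposition(data: TwinDataset) -> tuple[np.ndarray, ...]:
    """Method-of-moments A, C, E matrices from W, B_MZ, B_DZ."""
    _, w = _pooled_within_cov(data)
    bmz = _cross_twin_cov(data, MZ)
    bdz = _cross_twin_cov(data, DZ)
    a = 2.0 * (bmz - bdz)
    c = 2.0 * bdz - bmz
    e = w - bmz
    return a, c, e, w


def _top_f_factorization(m: np.ndarray, f: int, floor: float = 1e-4) -> np.ndarray:
    """(p, f) loading matrix from the top-f eigenpairs, eigenvalues floored."""
    sym = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(sym)
    order = np.argsort(w)[::-1][:f]
    return v[:, order] * np.sqrt(np.clip(w[order], floor, None))


def _random_rotation(f: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((f, f)))
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# univariate models


class UnivariateACE(TwinModel):
    """Univariate ACE-family model (ACE, AE, CE or E) for a single phenotype.

    Paths are sign-unbounded (the likelihood is even in each); the fitted
    solution is canonicalized to the non-negative representative.
    """

    def __init__(self, data: TwinDataset, components: str = "ACE",
                 dz_ra: float = DZ_RA):
        if data.p != 1:
            raise ValueError("UnivariateACE requires a single phenotype; "
                             "compute scale scores first")
        comps = components.upper()
        if "E" not in comps or not set(comps) <= set("ACE"):
            raise ValueError("components must be one of ACE, AE, CE, E")
        super().__init__(data)
        self.components = "".join(c for c in "ACE" if c in comps)
        self.dz_ra = dz_ra
        self.name = f"univariate {self.components}"
        self._path_names = [c.lower() for c in self.components]
        self.identity_map = {nm: i for i, nm in enumerate(self.internal_names)}

    @property
    def internal_names(self) -> list[str]:
        return ["b0"] + [c.lower() for c in self.components]

    def start_internal(self) -> np.ndarray:
        y = self.data.phenotypes()
        var = float(np.nanvar(y, ddof=1))
        k = len(self._path_names)
        return np.array([float(np.nanmean(y))] + [np.sqrt(max(var, 1e-6) / k)] * k)

    def _params(self, x: np.ndarray) -> UnivariateACEParams:
        vals = dict(zip(self.internal_names, x))
        return UnivariateACEParams(a=vals.get("a", 0.0), c=vals.get("c", 0.0),
                                   e=vals.get("e", 0.0), b0=vals["b0"])

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        return univariate_ace_moments(self._params(x), group, self.dz_ra)

    def moments_arrays(self, x, group):
        pr = self._params(x)
        a2, c2, e2 = pr.a ** 2, pr.c ** 2, pr.e ** 2
        var = a2 + c2 + e2
        cov = _r_a(group, self.dz_ra) * a2 + c2
        return (np.array([pr.b0, pr.b0]),
                np.array([[var, cov], [cov, var]]))

    def reported(self, x: np.ndarray) -> pd.Series:
        return pd.Series(np.asarray(x, float), index=self.internal_names)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).copy()
        x[1:] = np.abs(x[1:])
        return x

    @property
    def ep(self) -> int:
        return 1 + len(self._path_names)

    def is_nested_in(self, other: TwinModel) -> bool:
        if isinstance(other, UnivariateACE):
            return set(self.components) < set(other.components)
        if isinstance(other, SaturatedUnivariate):
            return True
        if isinstance(other, ModeratedACE):
            return False
        return False


class SaturatedUnivariate(TwinModel):
    """Unstructured per-group bivariate Gaussian: 2 means, 2 variances, 1
    covariance per zygosity group (EP = 10). Serves as its own baseline."""

    name = "saturated univariate"

    _REPORTED = [f"{nm}_{g.lower()}" for g in GROUPS
                 for nm in ("mean_t1", "mean_t2", "var_t1", "var_t2", "cov")]

    def __init__(self, data: TwinDataset):
        if data.p != 1:
            raise ValueError("SaturatedUnivariate requires a single phenotype")
        super().__init__(data)
        # internal: per group (m1, m2, log v1, log v2, atanh r)
        self.identity_map = {f"mean_t1_{g.lower()}": 5 * i for i, g in enumerate(GROUPS)}
        self.identity_map.update(
            {f"mean_t2_{g.lower()}": 5 * i + 1 for i, g in enumerate(GROUPS)})

    @property
    def internal_names(self) -> list[str]:
        return [f"{nm}_{g.lower()}" for g in GROUPS
                for nm in ("m1", "m2", "logv1", "logv2", "zr")]

    def start_internal(self) -> np.ndarray:
        out = []
        for g in GROUPS:
            y = self.data.phenotypes(g)
            m1 = float(np.nanmean(y[:, 0])) if np.isfinite(y[:, 0]).any() else 0.0
            m2 = float(np.nanmean(y[:, 1])) if np.isfinite(y[:, 1]).any() else 0.0
            v1 = max(float(np.nanvar(y[:, 0], ddof=1)), 1e-6)
            v2 = max(float(np.nanvar(y[:, 1], ddof=1)), 1e-6)
            ok = ~np.isnan(y).any(axis=1)
            r = float(np.corrcoef(y[ok, 0], y[ok, 1])[0, 1]) if ok.sum() >= 3 else 0.0
            r = float(np.clip(r, -0.99, 0.99))
            out += [m1, m2, np.log(v1), np.log(v2), np.arctanh(r)]
        return np.array(out)

    def _group_vals(self, x: np.ndarray, gi: int) -> tuple[float, ...]:
        m1, m2, lv1, lv2, zr = x[5 * gi:5 * gi + 5]
        v1, v2 = np.exp(lv1), np.exp(lv2)
        cov = np.tanh(zr) * np.sqrt(v1 * v2)
        return m1, m2, v1, v2, cov

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        gi = GROUPS.index(group)
        return saturated_univariate_moments(*self._group_vals(x, gi), group=group)

    def moments_arrays(self, x, group):
        m1, m2, v1, v2, cov = self._group_vals(x, GROUPS.index(group))
        return np.array([m1, m2]), np.array([[v1, cov], [cov, v2]])

    def reported(self, x: np.ndarray) -> pd.Series:
        vals = []
        for gi in range(2):
            vals.extend(self._group_vals(x, gi))
        return pd.Series(vals, index=self._REPORTED)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float)

    @property
    def ep(self) -> int:
        return 10


class ModeratedACE(TwinModel):
    """Purcell G x E moderation of a univariate ACE model.

    Every path is ``p0 + p1 * M`` with M a pair-level moderator (childhood
    SES here); the mean is ``b0 + bM * M``. With ``moderated_paths=False`` the
    three moderation slopes are fixed at zero (the 3-df reduction the
    moderation LRT tests) while the mean effect ``bM`` is retained.
    """

    def __init__(self, data: TwinDataset, moderated_paths: bool = True,
                 dz_ra: float = DZ_RA):
        if data.p != 1:
            raise ValueError("ModeratedACE requires a single phenotype")
        if not data.has_moderator:
            raise ValueError("dataset has no moderator column")
        keep = data.frame["moderator"].notna()
        if not keep.all():
            logger.warning("dropping %d pair(s) with missing moderator",
                           int((~keep).sum()))
            data = TwinDataset(data.frame.loc[keep].reset_index(drop=True),
                               list(data.items))
        super().__init__(data)
        self.moderated_paths = moderated_paths
        self.dz_ra = dz_ra
        self.name = "moderated ACE" if moderated_paths else "ACE + moderated mean"
        self.identity_map = {nm: i for i, nm in enumerate(self.internal_names)}
        self._prep_arrays()

    def _prep_arrays(self) -> None:
        self._both: dict[str, tuple[np.ndarray, ...]] = {}
        self._single: dict[str, tuple[np.ndarray, ...]] = {}
        for g in GROUPS:
            y = self.data.phenotypes(g)
            m = self.data.moderator_values(g)
            obs = ~np.isnan(y)
            both = obs.all(axis=1)
            self._both[g] = (y[both, 0], y[both, 1], m[both])
            one = obs.sum(axis=1) == 1
            xs = np.where(obs[one, 0], y[one, 0], y[one, 1])
            self._single[g] = (xs, m[one])

    @property
    def internal_names(self) -> list[str]:
        base = ["b0", "bM", "a0", "c0", "e0"]
        return base + (["a1", "c1", "e1"] if self.moderated_paths else [])

    def start_internal(self) -> np.ndarray:
        y = self.data.phenotypes()
        var = float(np.nanvar(y, ddof=1))
        path = np.sqrt(max(var, 1e-6) / 3.0)
        base = [float(np.nanmean(y)), 0.0, path, path, path]
        return np.array(base + ([0.0, 0.0, 0.0] if self.moderated_paths else []))

    def _params(self, x: np.ndarray) -> ModeratedACEParams:
        vals = dict(zip(self.internal_names, x))
        return ModeratedACEParams(
            a0=vals["a0"], a1=vals.get("a1", 0.0), c0=vals["c0"],
            c1=vals.get("c1", 0.0), e0=vals["e0"], e1=vals.get("e1", 0.0),
            b0=vals["b0"], bM=vals["bM"])

    def moments_at(self, x: np.ndarray, group: str, M: float) -> ExpectedMoments:
        return moderated_ace_moments(self._params(x), group, M, self.dz_ra)

    def deviance(self, x: np.ndarray) -> float:
        pr = self._params(x)
        total = 0.0
        for g in GROUPS:
            ra = _r_a(g, self.dz_ra)
            x1, x2, m = self._both[g]
            if m.size:
                a = pr.a0 + pr.a1 * m
                c = pr.c0 + pr.c1 * m
                e = pr.e0 + pr.e1 * m
                v = a * a + c * c + e * e
                cv = ra * a * a + c * c
                det = v * v - cv * cv
                if np.any(det <= 0) or np.any(v <= 0):
                    return np.inf
                d1 = x1 - (pr.b0 + pr.bM * m)
                d2 = x2 - (pr.b0 + pr.bM * m)
                quad = (v * (d1 * d1 + d2 * d2) - 2.0 * cv * d1 * d2) / det
                total += float(np.sum(2.0 * LOG_2PI + np.log(det) + quad))
            xs, ms = self._single[g]
            if ms.size:
                a = pr.a0 + pr.a1 * ms
                c = pr.c0 + pr.c1 * ms
                e = pr.e0 + pr.e1 * ms
                v = a * a + c * c + e * e
                if np.any(v <= 0):
                    return np.inf
                d = xs - (pr.b0 + pr.bM * ms)
                total += float(np.sum(LOG_2PI + np.log(v) + d * d / v))
        return total

    def reported(self, x: np.ndarray) -> pd.Series:
        return pd.Series(np.asarray(x, float), index=self.internal_names)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).copy()
        names = self.internal_names
        for p0, p1 in (("a0", "a1"), ("c0", "c1"), ("e0", "e1")):
            i0 = names.index(p0)
            if x[i0] < 0:
                x[i0] = -x[i0]
                if p1 in names:
                    i1 = names.index(p1)
                    x[i1] = -x[i1]
        return x

    @property
    def ep(self) -> int:
        return len(self.internal_names)

    def is_nested_in(self, other: TwinModel) -> bool:
        return (isinstance(other, ModeratedACE) and other.moderated_paths
                and not self.moderated_paths)


# ---------------------------------------------------------------------------
# multivariate item-level models


def _spherical_paths(angles: np.ndarray, comps: str) -> np.ndarray:
    """Map free angles to unit-norm (a, c, e) factor paths (exact constraint)."""
    if comps == "ACE":
        t1, t2 = angles
        return np.array([np.cos(t1), np.sin(t1) * np.cos(t2),
                         np.sin(t1) * np.sin(t2)])
    t, = angles
    return np.array([np.cos(t), np.sin(t)])


def _angles_from_paths(paths: np.ndarray, comps: str) -> np.ndarray:
    paths = np.abs(paths)
    if comps == "ACE":
        a, c, e = paths
        return np.array([np.arccos(np.clip(a, -1, 1)), np.arctan2(e, c)])
    x, y = paths
    return np.array([np.arctan2(y, x)])


class CommonPathway(TwinModel):
    """Common-pathway model: f unit-variance latent factors, each an ACE
    composite, loading on all p items, plus item-specific ACE influences.

    ``drop='A'`` / ``drop='C'`` removes that component's factor path *and* all
    its item-specific paths (the conventional block reduction). The unit
    factor variance is enforced exactly by spherical angles internally; the
    ledger still reports 3 factor paths per factor as free parameters plus f
    nonlinear constraints, so comparison df work out on the usual convention.
    """

    def __init__(self, data: TwinDataset, n_factors: int = 1,
                 drop: str | None = None, dz_ra: float = DZ_RA):
        if data.p < 2:
            raise ValueError("CommonPathway requires at least 2 items")
        if drop not in (None, "A", "C"):
            raise ValueError("drop must be None, 'A' or 'C'")
        super().__init__(data)
        self.f = int(n_factors)
        self.drop = drop
        self.dz_ra = dz_ra
        self.comps = "".join(c for c in "ACE" if c != drop)
        self._n_angles = 2 if self.comps == "ACE" else 1
        tag = "" if drop is None else f", no {drop}"
        self.name = f"{self.f}-factor common pathway{tag}"
        self._build_layout()

    def _build_layout(self) -> None:
        p, f, items = self.data.p, self.f, self.data.items
        names: list[str] = [f"b0_{it}" for it in items]
        names += [f"lambda_{it}_f{k + 1}" for k in range(f) for it in items]
        self._angle_slice = slice(len(names), len(names) + f * self._n_angles)
        names += [f"theta{j + 1}_f{k + 1}" for k in range(f)
                  for j in range(self._n_angles)]
        for comp in self.comps:
            names += [f"{comp.lower()}s_{it}" for it in items]
        self._internal = names
        self.identity_map = {nm: i for i, nm in enumerate(names)
                             if not nm.startswith("theta")}
        self._lam_slice = slice(p, p + p * f)
        self._spec_start = self._angle_slice.stop

    @property
    def internal_names(self) -> list[str]:
        return list(self._internal)

    def _unpack(self, x: np.ndarray) -> CPMParams:
        p, f = self.data.p, self.f
        b0 = x[:p]
        lam = x[self._lam_slice].reshape(f, p).T
        angles = x[self._angle_slice].reshape(f, self._n_angles)
        a_f = np.zeros(f); c_f = np.zeros(f); e_f = np.zeros(f)
        for k in range(f):
            paths = _spherical_paths(angles[k], self.comps)
            vals = dict(zip(self.comps, paths))
            a_f[k] = vals.get("A", 0.0)
            c_f[k] = vals.get("C", 0.0)
            e_f[k] = vals.get("E", 0.0)
        spec = {"A": np.zeros(p), "C": np.zeros(p), "E": np.zeros(p)}
        off = self._spec_start
        for comp in self.comps:
            spec[comp] = x[off:off + p]
            off += p
        return CPMParams(loadings=lam, a_f=a_f, c_f=c_f, e_f=e_f,
                         a_s=spec["A"], c_s=spec["C"], e_s=spec["E"], b0=b0)

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        return cpm_moments(self._unpack(x), group, self.dz_ra, check=False)

    def moments_arrays(self, x, group):
        p, f = self.data.p, self.f
        b0 = x[:p]
        lam = x[self._lam_slice].reshape(f, p).T
        angles = x[self._angle_slice].reshape(f, self._n_angles)
        ra = _r_a(group, self.dz_ra)
        if self.comps == "ACE":
            a2 = np.cos(angles[:, 0]) ** 2
            c2 = (np.sin(angles[:, 0]) * np.cos(angles[:, 1])) ** 2
        elif self.comps == "CE":
            a2 = np.zeros(f)
            c2 = np.cos(angles[:, 0]) ** 2
        else:  # AE
            a2 = np.cos(angles[:, 0]) ** 2
            c2 = np.zeros(f)
        off = self._spec_start
        spec2 = {}
        for comp in self.comps:
            spec2[comp] = x[off:off + p] ** 2
            off += p
        as2 = spec2.get("A", 0.0)
        cs2 = spec2.get("C", 0.0)
        es2 = spec2.get("E", 0.0)
        # factor variances are exactly 1 under the spherical parameterization
        within = lam @ lam.T
        within[np.diag_indices(p)] += as2 + cs2 + es2
        cross = (lam * (ra * a2 + c2)) @ lam.T
        cross[np.diag_indices(p)] += ra * as2 + cs2
        return _fast_assemble(b0, within, cross)

    def start_internal(self) -> np.ndarray:
        p, f = self.data.p, self.f
        mean, w = _pooled_within_cov(self.data)
        lam0 = _top_f_factorization(w, f) * 0.85
        resid = np.clip(np.diag(w) - np.sum(lam0 ** 2, axis=1),
                        0.05 * np.diag(w), None)
        x = list(mean)
        x += list(lam0.T.ravel())
        if self.comps == "ACE":
            x += [np.arccos(1.0 / np.sqrt(3.0)), np.pi / 4.0] * f
            shares = {"A": 0.2, "C": 0.15, "E": 0.65}
        else:
            x += [np.pi / 4.0] * f
            shares = {c: s for c, s in zip(self.comps, (0.3, 0.7))}
        for comp in self.comps:
            x += list(np.sqrt(shares[comp] * resid))
        return np.array(x)

    def _jittered_start(self, x0, rng, jitter):
        x = super()._jittered_start(x0, rng, jitter)
        if self.f > 1:
            p, f = self.data.p, self.f
            lam = x[self._lam_slice].reshape(f, p).T
            x[self._lam_slice] = (lam @ _random_rotation(f, rng)).T.ravel()
        return x

    def reported(self, x: np.ndarray) -> pd.Series:
        pr = self._unpack(x)
        p, f, items = self.data.p, self.f, self.data.items
        out: dict[str, float] = {}
        for j, it in enumerate(items):
            out[f"b0_{it}"] = pr.b0[j]
        for k in range(f):
            for j, it in enumerate(items):
                out[f"lambda_{it}_f{k + 1}"] = pr.loadings[j, k]
        for k in range(f):
            if "A" in self.comps:
                out[f"aF{k + 1}"] = pr.a_f[k]
            if "C" in self.comps:
                out[f"cF{k + 1}"] = pr.c_f[k]
            out[f"eF{k + 1}"] = pr.e_f[k]
        for comp in self.comps:
            vec = {"A": pr.a_s, "C": pr.c_s, "E": pr.e_s}[comp]
            for j, it in enumerate(items):
                out[f"{comp.lower()}s_{it}"] = vec[j]
        return pd.Series(out)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).copy()
        p, f = self.data.p, self.f
        lam = x[self._lam_slice].reshape(f, p).T
        for k in range(f):
            if lam[:, k].sum() < 0:
                lam[:, k] = -lam[:, k]
        x[self._lam_slice] = lam.T.ravel()
        angles = x[self._angle_slice].reshape(f, self._n_angles)
        for k in range(f):
            paths = _spherical_paths(angles[k], self.comps)
            angles[k] = _angles_from_paths(paths, self.comps)
        x[self._angle_slice] = angles.ravel()
        x[self._spec_start:] = np.abs(x[self._spec_start:])
        return x

    def encode(self, params: CPMParams) -> np.ndarray:
        """Internal coordinate vector for a parameter container.

        Loading columns beyond the container's factors are filled with small
        values; factor paths are restricted to this model's components and
        renormalized to the unit sphere (equal split when degenerate).
        Useful for warm-starting a fit from a nested model's solution.
        """
        p, f = self.data.p, self.f
        src_f = params.loadings.shape[1]
        lam = np.full((p, f), 0.05)
        lam[:, :min(f, src_f)] = params.loadings[:, :min(f, src_f)]
        x = list(np.asarray(params.b0, float))
        x += list(lam.T.ravel())
        comp_vecs = {"A": params.a_f, "C": params.c_f, "E": params.e_f}
        for k in range(f):
            if k < src_f:
                paths = np.array([comp_vecs[c][k] for c in self.comps])
                norm = np.linalg.norm(paths)
                paths = paths / norm if norm > 1e-6 else \
                    np.full(len(self.comps), 1.0 / np.sqrt(len(self.comps)))
            else:
                paths = np.full(len(self.comps), 1.0 / np.sqrt(len(self.comps)))
            x += list(_angles_from_paths(paths, self.comps))
        spec_vecs = {"A": params.a_s, "C": params.c_s, "E": params.e_s}
        for comp in self.comps:
            x += list(np.asarray(spec_vecs[comp], float))
        return np.array(x)

    @property
    def ep(self) -> int:
        p, f, k = self.data.p, self.f, len(self.comps)
        return p + p * f + k * f + k * p

    @property
    def n_constraints(self) -> int:
        return self.f

    def is_nested_in(self, other: TwinModel) -> bool:
        if isinstance(other, DirectVarCov):
            return other.data.p == self.data.p
        if isinstance(other, CommonPathway):
            if other.data.p != self.data.p:
                return False
            if self.drop is not None and other.drop is None and self.f == other.f:
                return True
            return self.drop == other.drop and self.f < other.f
        if isinstance(other, IndependentPathway):
            # the CPM is subsumed within the IPM; comparisons against an IPM
            # with fewer factors but more parameters follow the quasi-nested
            # likelihood-comparison convention
            return other.data.p == self.data.p and other.ep > self.ep
        return False


class IndependentPathway(TwinModel):
    """Independent-pathway model: A-, C- and E-common loading matrices (p x f)
    act directly on the items, plus item-specific ACE influences. No variance
    constraints, so EP = p + 3 p f + 3 p."""

    def __init__(self, data: TwinDataset, n_factors: int = 1,
                 dz_ra: float = DZ_RA):
        if data.p < 2:
            raise ValueError("IndependentPathway requires at least 2 items")
        super().__init__(data)
        self.f = int(n_factors)
        self.dz_ra = dz_ra
        self.name = f"{self.f}-factor independent pathway"
        items = data.items
        names = [f"b0_{it}" for it in items]
        for comp in "ace":
            names += [f"{comp}L_{it}_f{k + 1}" for k in range(self.f)
                      for it in items]
        for comp in "ace":
            names += [f"{comp}s_{it}" for it in items]
        self._internal = names
        self.identity_map = {nm: i for i, nm in enumerate(names)}

    @property
    def internal_names(self) -> list[str]:
        return list(self._internal)

    def _unpack(self, x: np.ndarray) -> IPMParams:
        p, f = self.data.p, self.f
        b0 = x[:p]
        off = p
        loads = []
        for _ in range(3):
            loads.append(x[off:off + p * f].reshape(f, p).T)
            off += p * f
        specs = [x[off + i * p: off + (i + 1) * p] for i in range(3)]
        return IPMParams(a_load=loads[0], c_load=loads[1], e_load=loads[2],
                         a_s=specs[0], c_s=specs[1], e_s=specs[2], b0=b0)

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        return ipm_moments(self._unpack(x), group, self.dz_ra)

    def moments_arrays(self, x, group):
        p, f = self.data.p, self.f
        ra = _r_a(group, self.dz_ra)
        b0 = x[:p]
        off = p
        blocks = []
        for _ in range(3):
            lam = x[off:off + p * f].reshape(f, p).T
            blocks.append(lam @ lam.T)
            off += p * f
        aa, cc, ee = blocks
        as2 = x[off:off + p] ** 2
        cs2 = x[off + p:off + 2 * p] ** 2
        es2 = x[off + 2 * p:off + 3 * p] ** 2
        within = aa + cc + ee
        within[np.diag_indices(p)] += as2 + cs2 + es2
        cross = ra * aa + cc
        cross[np.diag_indices(p)] += ra * as2 + cs2
        return _fast_assemble(b0, within, cross)

    def start_internal(self) -> np.ndarray:
        p, f = self.data.p, self.f
        mean, w = _pooled_within_cov(self.data)
        a, c, e, _ = _moment_decomposition(self.data)
        x = list(mean)
        spec_parts = []
        for comp in (a, c, e):
            load = _top_f_factorization(comp, f)
            x += list(load.T.ravel())
            resid = np.clip(np.diag(comp) - np.sum(load ** 2, axis=1),
                            0.02 * np.diag(w), None)
            spec_parts.append(np.sqrt(resid))
        for s in spec_parts:
            x += list(s)
        return np.array(x)

    def _jittered_start(self, x0, rng, jitter):
        x = super()._jittered_start(x0, rng, jitter)
        if self.f > 1:
            p, f = self.data.p, self.f
            off = p
            for _ in range(3):
                lam = x[off:off + p * f].reshape(f, p).T
                x[off:off + p * f] = (lam @ _random_rotation(f, rng)).T.ravel()
                off += p * f
        return x

    def reported(self, x: np.ndarray) -> pd.Series:
        return pd.Series(np.asarray(x, float), index=self._internal)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).copy()
        p, f = self.data.p, self.f
        off = p
        for _ in range(3):
            lam = x[off:off + p * f].reshape(f, p).T
            for k in range(f):
                if lam[:, k].sum() < 0:
                    lam[:, k] = -lam[:, k]
            x[off:off + p * f] = lam.T.ravel()
            off += p * f
        x[off:] = np.abs(x[off:])
        return x

    def encode(self, params: IPMParams) -> np.ndarray:
        """Internal coordinates from an IPMParams (extra columns padded small)."""
        p, f = self.data.p, self.f
        x = list(np.asarray(params.b0, float))
        for load in (params.a_load, params.c_load, params.e_load):
            src_f = load.shape[1]
            lam = np.full((p, f), 0.02)
            lam[:, :min(f, src_f)] = load[:, :min(f, src_f)]
            x += list(lam.T.ravel())
        for vec in (params.a_s, params.c_s, params.e_s):
            x += list(np.asarray(vec, float))
        return np.array(x)

    @property
    def ep(self) -> int:
        p, f = self.data.p, self.f
        return p + 3 * p * f + 3 * p

    def is_nested_in(self, other: TwinModel) -> bool:
        if isinstance(other, DirectVarCov):
            return other.data.p == self.data.p
        if isinstance(other, IndependentPathway):
            return other.data.p == self.data.p and self.f < other.f
        return False


class DirectVarCov(TwinModel):
    """Direct variance-covariance ACE baseline: full symmetric A, C, E
    component matrices estimated directly (no PSD constraint on each), means
    equated across twins and groups. EP = p + 3 p(p+1)/2 (69 at p = 6)."""

    def __init__(self, data: TwinDataset, dz_ra: float = DZ_RA):
        super().__init__(data)
        self.dz_ra = dz_ra
        self.name = "direct variance-covariance baseline"
        p = data.p
        items = data.items
        self._tri = np.triu_indices(p)
        names = [f"b0_{it}" for it in items]
        for comp in "ACE":
            names += [f"{comp}_{items[i]}_{items[j]}"
                      for i, j in zip(*self._tri)]
        self._internal = names
        self.identity_map = {nm: i for i, nm in enumerate(names)}

    @property
    def internal_names(self) -> list[str]:
        return list(self._internal)

    def _vech_to_sym(self, v: np.ndarray) -> np.ndarray:
        p = self.data.p
        m = np.zeros((p, p))
        m[self._tri] = v
        return m + np.triu(m, 1).T

    def _unpack(self, x: np.ndarray) -> DirectVarCovParams:
        p = self.data.p
        nv = p * (p + 1) // 2
        b0 = x[:p]
        mats = [self._vech_to_sym(x[p + i * nv: p + (i + 1) * nv])
                for i in range(3)]
        return DirectVarCovParams(A=mats[0], C=mats[1], E=mats[2], b0=b0)

    def moments(self, x: np.ndarray, group: str) -> ExpectedMoments:
        return direct_varcov_moments(self._unpack(x), group, self.dz_ra)

    def moments_arrays(self, x, group):
        p = self.data.p
        nv = p * (p + 1) // 2
        ra = _r_a(group, self.dz_ra)
        b0 = x[:p]
        mats = []
        for i in range(3):
            m = np.zeros((p, p))
            m[self._tri] = x[p + i * nv: p + (i + 1) * nv]
            mats.append(m + np.triu(m, 1).T)
        a, c, e = mats
        return _fast_assemble(b0, a + c + e, ra * a + c)

    def start_internal(self) -> np.ndarray:
        mean, _ = _pooled_within_cov(self.data)
        a, c, e, _ = _moment_decomposition(self.data)
        x = list(mean)
        for m in (a, c, e):
            x += list(_shrink_to_diag(m)[self._tri])
        return np.array(x)

    def reported(self, x: np.ndarray) -> pd.Series:
        return pd.Series(np.asarray(x, float), index=self._internal)

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float)

    @property
    def ep(self) -> int:
        p = self.data.p
        return p + 3 * (p * (p + 1) // 2)


# ---------------------------------------------------------------------------
# accounting and standardization


def count_parameters(spec: TwinModel) -> tuple[int, int]:
    """(freely estimated parameters, nonlinear equality constraints).

    Comparison df between nested models = delta EP + delta constraints.
    """
    return spec.ep, spec.n_constraints


def standardize_components(fit: TwinModelResults):
    """Proportions of variance (A%, C%, E%) implied by a fitted ACE-family model.

    Univariate models return a Series summing to 1; common-pathway models a
    per-factor DataFrame (squared factor paths, which sum to 1 by the unit
    -variance constraint); IPM/direct-variance models a per-item DataFrame of
    diagonal variance shares.
    """
    model = fit.model
    est = fit.params
    if isinstance(model, UnivariateACE):
        parts = {comp: est.get(comp.lower(), 0.0) ** 2 for comp in "ACE"}
    elif isinstance(model, ModeratedACE):
        parts = {comp: est[f"{comp.lower()}0"] ** 2 for comp in "ACE"}
    elif isinstance(model, CommonPathway):
        pr = model._unpack(fit.x_internal)
        rows = {f"F{k + 1}": {"A": pr.a_f[k] ** 2, "C": pr.c_f[k] ** 2,
                              "E": pr.e_f[k] ** 2} for k in range(model.f)}
        return pd.DataFrame.from_dict(rows, orient="index")
    elif isinstance(model, IndependentPathway):
        pr = model._unpack(fit.x_internal)
        comp_diag = {
            "A": np.diag(pr.a_load @ pr.a_load.T) + pr.a_s ** 2,
            "C": np.diag(pr.c_load @ pr.c_load.T) + pr.c_s ** 2,
            "E": np.diag(pr.e_load @ pr.e_load.T) + pr.e_s ** 2,
        }
        return _item_shares(comp_diag, model.data.items)
    elif isinstance(model, DirectVarCov):
        pr = model._unpack(fit.x_internal)
        comp_diag = {"A": np.diag(pr.A), "C": np.diag(pr.C), "E": np.diag(pr.E)}
        return _item_shares(comp_diag, model.data.items)
    else:
        raise TypeError(f"no standardization rule for {type(model).__name__}")

    total = sum(parts.values())
    if total <= 0:
        raise ValueError("zero total variance; standardized components undefined")
    return pd.Series({k: v / total for k, v in parts.items()})


def _item_shares(comp_diag: dict[str, np.ndarray], items: list[str]) -> pd.DataFrame:
    total = sum(comp_diag.values())
    if np.any(total <= 0):
        raise ValueError("zero total variance; standardized components undefined")
    return pd.DataFrame({k: v / total for k, v in comp_diag.items()}, index=items)
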