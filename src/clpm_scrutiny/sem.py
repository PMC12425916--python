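"""A minimal maximum-likelihood SEM engine in RAM parameterization.

A structural model is held as three matrices over the ordered variable list
(observed and latent): a directed-path matrix ``A`` (entry ``A[i, j]`` is the
coefficient of variable ``j`` in the equation for variable ``i``), a
symmetric (co)variance matrix ``S`` of exogenous variances, residual
variances and covariances, and a selector ``F`` picking out the observed
variables.  The model-implied covariance matrix of the observed variables is

    Sigma(theta) = F (I - A)^{-1} S (I - A)^{-T} F^T.

Fitting minimizes the normal-theory maximum-likelihood discrepancy

    F_ML(theta) = log|Sigma| + tr(S_sample Sigma^{-1}) - log|S_sample| - p

over the free parameters.  The model chi-square is ``n * F_min`` (the
denominator-n normal-likelihood convention; configurable to ``n - 1``), and
standard errors come from the expected information at the optimum,

    Info_kl = (n / 2) * tr(Sigma^{-1} dSigma_k Sigma^{-1} dSigma_l),

with analytic ``dSigma_k``.  Iteration stops when the largest absolute
change in unscaled parameter values between iterations falls below 1e-4 or
the gradient norm falls below 1e-8; non-convergence is raised, never
silently accepted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    IdentificationError,
    NumericalError,
    ValidationError,
)

__all__ = [
    "SemSpec",
    "SemFit",
    "FitIndices",
    "SemModel",
    "model_implied_sigma",
    "ml_discrepancy",
    "fit_ml",
    "baseline_chi2",
    "fit_indices",
    "rmsea_ci",
    "saturated_spec",
    "independence_spec",
]

_FREE = "free"
_FIXED = "fixed"


class SemSpec:
    """A structural model pattern: free/fixed directed paths and (co)variances.

    Free parameters are referred to by string labels; the same label in
    several entries imposes an equality constraint.  Only recursive
    (acyclic) path structures are accepted.
    """

    def __init__(self, variables: Sequence[str], observed: Sequence[str],
                 name: str = "sem"):
        self.variables = list(variables)
        self.observed = list(observed)
        unknown = set(self.observed) - set(self.variables)
        if unknown:
            raise ValidationError(f"observed variables not declared: {sorted(unknown)}")
        if len(set(self.variables)) != len(self.variables):
            raise ValidationError("duplicate variable names")
        self.name = name
        self._idx = {v: i for i, v in enumerate(self.variables)}
        self._paths: dict[tuple[int, int], tuple[str, object]] = {}
        self._covs: dict[tuple[int, int], tuple[str, object]] = {}
        self.start_values: dict[str, float] = {}
        # focal metadata: (parameter label, source variable, target variable)
        self.focal: tuple[str, str, str] | None = None

    # -- construction -----------------------------------------------------
    def add_path(self, src: str, dst: str, free: str | None = None,
                 fixed: float | None = None) -> "SemSpec":
        """Directed regression path ``src -> dst``."""
        self._paths[(self._var(dst), self._var(src))] = self._entry(free, fixed)
        return self

    def add_variance(self, var: str, free: str | None = None,
                     fixed: float | None = None) -> "SemSpec":
        i = self._var(var)
        self._covs[(i, i)] = self._entry(free, fixed)
        return self

    def add_covariance(self, a: str, b: str, free: str | None = None,
                       fixed: float | None = None) -> "SemSpec":
        i, j = sorted((self._var(a), self._var(b)))
        self._covs[(i, j)] = self._entry(free, fixed)
        return self

    def set_focal(self, label: str, source: str, target: str) -> "SemSpec":
        self._var(source), self._var(target)
        self.focal = (label, source, target)
        return self

    def _var(self, name: str) -> int:
        if name not in self._idx:
            raise ValidationError(f"unknown variable {name!r} in spec {self.name!r}")
        return self._idx[name]

    @staticmethod
    def _entry(free, fixed):
        if (free is None) == (fixed is None):
            raise ValidationError("exactly one of free=<label> or fixed=<value> required")
        return (_FREE, free) if free is not None else (_FIXED, float(fixed))

    # -- derived structure -------------------------------------------------
    @property
    def labels(self) -> list[str]:
        """Free-parameter labels in order of first appearance (A first, then S)."""
        seen: list[str] = []
        for store in (self._paths, self._covs):
            for key in sorted(store):
                kind, val = store[key]
                if kind == _FREE and val not in seen:
                    seen.append(val)
        return seen

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def degrees_of_freedom(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def _check_recursive(self) -> None:
        m = len(self.variables)
        edges = {i: set() for i in range(m)}
        for (dst, src) in self._paths:
            edges[src].add(dst)
        # Kahn's algorithm; leftovers mean a cycle
        indeg = {i: 0 for i in range(m)}
        for src in edges:
            for dst in edges[src]:
                indeg[dst] += 1
        queue = [i for i in range(m) if indeg[i] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for w in edges[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen < m:
            raise ValidationError(
                f"spec {self.name!r} contains a cyclic path structure; "
                "only recursive models are supported"
            )

    def compile(self) -> "_CompiledSpec":
        self._check_recursive()
        return _CompiledSpec(self)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        m = len(self.variables)

        def cell(store, i, j):
            if (i, j) not in store:
                return 0
            kind, val = store[(i, j)]
            return f"free:{val}" if kind == _FREE else f"fix:{val}"

        a = [[cell(self._paths, i, j) for j in range(m)] for i in range(m)]
        # S is stored as its upper triangle only
        s = [[cell(self._covs, i, j) if i <= j else 0 for j in range(m)]
             for i in range(m)]
        doc = {
            "name": self.name,
            "variables": self.variables,
            "observed": self.observed,
            "A": a,
            "S": s,
            "start_values": self.start_values,
            "focal": list(self.focal) if self.focal else None,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SemSpec":
        text = Path(source).read_text(encoding="utf-8") if (
            isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                         and source.endswith(".json"))
        ) else str(source)
        doc = json.loads(text)
        spec = cls(doc["variables"], doc["observed"], name=doc.get("name", "sem"))

        def parse(cell):
            if isinstance(cell, str):
                kind, _, val = cell.partition(":")
                if kind == "free":
                    return {"free": val}
                if kind == "fix":
                    return {"fixed": float(val)}
                raise ValidationError(f"bad spec cell {cell!r}")
            return None if cell == 0 else {"fixed": float(cell)}

        names = doc["variables"]
        for i, row in enumerate(doc["A"]):
            for j, cell in enumerate(row):
                kw = parse(cell)
                if kw is not None:
                    spec.add_path(names[j], names[i], **kw)
        for i, row in enumerate(doc["S"]):
            for j, cell in enumerate(row):
                if j < i:
                    continue
                kw = parse(cell)
                if kw is not None:
                    spec.add_covariance(names[i], names[j], **kw)
        spec.start_values = dict(doc.get("start_values") or {})
        if doc.get("focal"):
            spec.set_focal(*doc["focal"])
        return spec

    def equations(self) -> str:
        """One-line-per-relation human-readable rendering."""
        lines = []
        for (dst, src), (kind, val) in sorted(self._paths.items()):
            coef = val if kind == _FREE else f"{val:g}"
            lines.append(f"{self.variables[dst]} <- {coef} * {self.variables[src]}")
        for (i, j), (kind, val) in sorted(self._covs.items()):
            coef = val if kind == _FREE else f"{val:g}"
            if i == j:
                lines.append(f"var({self.variables[i]}) = {coef}")
            else:
                lines.append(f"cov({self.variables[i]}, {self.variables[j]}) = {coef}")
        return "\n".join(lines)


class _CompiledSpec:
    """Index structures for fast evaluation of Sigma(theta) and its gradient."""

    def __init__(self, spec: SemSpec):
        self.spec = spec
        m = len(spec.variables)
        self.m = m
        self.obs_idx = np.array([spec._idx[v] for v in spec.observed])
        self.labels = spec.labels
        self.label_pos = {lab: k for k, lab in enumerate(self.labels)}
        self.a0 = np.zeros((m, m))
        self.s0 = np.zeros((m, m))
        self.a_pos: list[list[tuple[int, int]]] = [[] for _ in self.labels]
        self.s_pos: list[list[tuple[int, int]]] = [[] for _ in self.labels]
        for (i, j), (kind, val) in spec._paths.items():
            if kind == _FIXED:
                self.a0[i, j] = val
            else:
                self.a_pos[self.label_pos[val]].append((i, j))
        for (i, j), (kind, val) in spec._covs.items():
            if kind == _FIXED:
                self.s0[i, j] = self.s0[j, i] = val
            else:
                self.s_pos[self.label_pos[val]].append((i, j))
        # a parameter is variance-type iff it appears only on the S diagonal
        self.is_variance = np.array([
            bool(self.s_pos[k]) and not self.a_pos[k]
            and all(i == j for (i, j) in self.s_pos[k])
            for k in range(len(self.labels))
        ])

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = self.a0.copy()
        s = self.s0.copy()
        for k, t in enumerate(theta):
            for (i, j) in self.a_pos[k]:
                a[i, j] = t
            for (i, j) in self.s_pos[k]:
                s[i, j] = s[j, i] = t
        return a, s

    def sigma_full(self, theta: np.ndarray) -> np.ndarray:
        a, s = self.matrices(theta)
        eye = np.eye(self.m)
        try:
            b = np.linalg.solve(eye - a, eye)
        except np.linalg.LinAlgError as err:
            raise NumericalError(
                f"(I - A) is singular for spec {self.spec.name!r}"
            ) from err
        return b @ s @ b.T

    def sigma_obs(self, theta: np.ndarray) -> np.ndarray:
        sig = self.sigma_full(theta)
        return sig[np.ix_(self.obs_idx, self.obs_idx)]

    def dsigma_obs(self, theta: np.ndarray) -> list[np.ndarray]:
        """Analytic derivatives of the observed-block Sigma w.r.t. each parameter."""
        a, s = self.matrices(theta)
        eye = np.eye(self.m)
        b = np.linalg.solve(eye - a, eye)
        sbt = s @ b.T
        out = []
        oi = self.obs_idx
        for k in range(len(self.labels)):
            d = np.zeros((self.m, self.m))
            for (i, j) in self.a_pos[k]:
                t = np.outer(b[:, i], b[j, :] @ sbt)
                d += t + t.T
            for (i, j) in self.s_pos[k]:
                if i == j:
                    d += np.outer(b[:, i], b[:, i])
                else:
                    d += np.outer(b[:, i], b[:, j]) + np.outer(b[:, j], b[:, i])
            out.append(d[np.ix_(oi, oi)])
        return out


# --------------------------------------------------------------------------
# Fit containers
# --------------------------------------------------------------------------

@dataclass
class SemFit:
    """A fitted structural model."""

    spec: SemSpec
    theta: dict[str, float]
    se: dict[str, float]
    sigma_hat: np.ndarray
    sigma_full: np.ndarray
    chi2: float
    df: int
    n: int
    converged: bool
    n_iter: int
    fmin: float
    s_sample: np.ndarray
    labels: list[str] = field(default_factory=list)
    param_cov: np.ndarray | None = None
    chi2_multiplier: str = "n"


@dataclass(frozen=True)
class FitIndices:
    """Global fit of a model: chi-square and the standard descriptive indices.

    ``tli``, ``rmsea`` and the RMSEA interval are NaN when df = 0 (saturated
    models have no misfit to rate per degree of freedom).
    """

    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------

def model_implied_sigma(spec: SemSpec, theta: Mapping[str, float]) -> np.ndarray:
    """Model-implied covariance matrix of the observed variables at ``theta``."""
    comp = spec.compile()
    missing = [lab for lab in comp.labels if lab not in theta]
    if missing:
        raise ValidationError(f"theta lacks values for free labels {missing}")
    vec = np.array([theta[lab] for lab in comp.labels])
    return comp.sigma_obs(vec)


def ml_discrepancy(sigma: np.ndarray, s: np.ndarray) -> float:
    """Normal-theory ML fit function log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    sigma = np.asarray(sigma, float)
    s = np.asarray(s, float)
    p = s.shape[0]
    if sigma.shape != s.shape:
        raise ValidationError("sigma and s must have the same shape")
    try:
        cho_sig = cho_factor(sigma)
        cho_s = cho_factor(s)
    except np.linalg.LinAlgError as err:
        raise NumericalError("ml_discrepancy requires positive definite inputs") from err
    logdet_sig = 2.0 * np.sum(np.log(np.diag(cho_sig[0])))
    logdet_s = 2.0 * np.sum(np.log(np.diag(cho_s[0])))
    return float(logdet_sig + np.trace(cho_solve(cho_sig, s)) - logdet_s - p)


class SemModel(BaseEstimator):
    """Maximum-likelihood SEM estimator over a :class:`SemSpec`.

    Parameters
    ----------
    spec : SemSpec
        The model pattern to fit.
    chi2_multiplier : {"n", "n-1"}
        Scale of the chi-square statistic (normal-likelihood convention uses
        ``n``; Wishart-likelihood software uses ``n - 1``).
    param_tol : float
        Convergence when the maximum absolute change in unscaled parameter
        values between iterations falls below this (default 1e-4).
    grad_tol : float
        Alternative convergence on the gradient norm (default 1e-8).
    variance_transform : {"log", "none"}
        Log-transform variance-type parameters during iteration to keep the
        implied covariance matrix positive definite.

    Attributes (after ``fit``)
    --------------------------
    theta_ : dict mapping label to estimate
    se_ : dict mapping label to standard error (expected information)
    sigma_ : implied covariance matrix of the observed variables
    chi2_, df_, n_iter_, converged_ : fit statistics
    """

    def __init__(self, spec: SemSpec, chi2_multiplier: str = "n",
                 max_iter: int = 1000, param_tol: float = 1e-4,
                 grad_tol: float = 1e-8, variance_transform: str = "log",
                 n_restarts: int = 2):
        self.spec = spec
        self.chi2_multiplier = chi2_multiplier
        self.max_iter = max_iter
        self.param_tol = param_tol
        self.grad_tol = grad_tol
        self.variance_transform = variance_transform
        self.n_restarts = n_restarts

    # -- public API --------------------------------------------------------
    def fit(self, X, y=None) -> "SemModel":
        """Fit from raw data (n x p array or DataFrame in observed order)."""
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            X = X.loc[:, self.spec.observed].to_numpy(float)
        x = np.asarray(X, float)
        if x.ndim != 2 or x.shape[1] != len(self.spec.observed):
            raise ValidationError(
                f"expected n x {len(self.spec.observed)} data for spec "
                f"{self.spec.name!r}, got shape {x.shape}"
            )
        xc = x - x.mean(axis=0)
        s = xc.T @ xc / x.shape[0]
        return self.fit_moments(s, x.shape[0])

    def fit_moments(self, s: np.ndarray, n: int) -> "SemModel":
        """Fit from a sample covariance/correlation matrix and sample size."""
        s = np.asarray(s, float)
        p = len(self.spec.observed)
        if s.shape != (p, p):
            raise ValidationError(f"S must be {p}x{p} for spec {self.spec.name!r}")
        try:
            cho_s = cho_factor(s)
        except np.linalg.LinAlgError as err:
            raise NumericalError("sample covariance matrix is not positive definite") from err
        logdet_s = 2.0 * np.sum(np.log(np.diag(cho_s[0])))

        comp = self.spec.compile()
        if comp.spec.degrees_of_freedom() < 0:
            raise IdentificationError(
                f"spec {self.spec.name!r} has more free parameters than moments"
            )
        k = len(comp.labels)
        use_log = self.variance_transform == "log" and k > 0

        def to_theta(u):
            t = u.copy()
            if use_log:
                t[comp.is_variance] = np.exp(u[comp.is_variance])
            return t

        def to_u(t):
            u = t.copy()
            if use_log:
                u[comp.is_variance] = np.log(np.maximum(t[comp.is_variance], 1e-8))
            return u

        def value_and_grad(u):
            theta = to_theta(u)
            try:
                sig = comp.sigma_obs(theta)
                cho = cho_factor(sig)
            except (np.linalg.LinAlgError, NumericalError):
                return np.inf, np.zeros(k)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            c = cho_solve(cho, np.eye(p))          # Sigma^{-1}
            f = logdet + float(np.sum(c * s)) - logdet_s - p
            w = c - c @ s @ c
            dsig = comp.dsigma_obs(theta)
            g = np.array([float(np.sum(w * d)) for d in dsig])
            if use_log:
                g[comp.is_variance] *= theta[comp.is_variance]
            return f, g

        theta0 = self._start_values(comp, s)
        history: list[np.ndarray] = []

        def callback(u):
            history.append(to_theta(np.asarray(u, float)))

        best = None
        rng = np.random.default_rng(0)
        for attempt in range(self.n_restarts + 1):
            start = theta0 if attempt == 0 else theta0 * (
                1.0 + 0.5 * rng.standard_normal(k)) + 0.05 * rng.standard_normal(k)
            start = start.copy()
            if use_log:
                start[comp.is_variance] = np.maximum(start[comp.is_variance], 1e-3)
            history.clear()
            history.append(start.copy())
            res = optimize.minimize(
                value_and_grad, to_u(start), jac=True, method="BFGS",
                callback=callback,
                options={"gtol": self.grad_tol, "maxiter": self.max_iter},
            )
            theta = to_theta(res.x)
            grad_norm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
            last_step = (float(np.max(np.abs(history[-1] - history[-2])))
                         if len(history) >= 2 else np.inf)
            converged = bool(res.success) or grad_norm < self.grad_tol \
                or last_step < self.param_tol
            if converged and np.isfinite(res.fun):
                best = (theta, res, converged)
                break
            if best is None or (np.isfinite(res.fun) and res.fun < best[1].fun):
                best = (theta, res, converged)
        theta, res, converged = best
        if res.nit >= self.max_iter:
            raise ConvergenceError(
                f"spec {self.spec.name!r}: iteration cap {self.max_iter} exceeded"
            )
        if not converged or not np.isfinite(res.fun):
            raise ConvergenceError(
                f"spec {self.spec.name!r}: optimizer failed to converge "
                f"(status: {res.message})"
            )

        fmin = max(float(res.fun), 0.0)
        mult = n if self.chi2_multiplier == "n" else n - 1
        sig = comp.sigma_obs(theta)
        se, pcov = self._standard_errors(comp, theta, sig, n)

        self.comp_ = comp
        self.labels_ = list(comp.labels)
        self.theta_ = dict(zip(comp.labels, theta.tolist()))
        self.se_ = se
        self.param_cov_ = pcov
        self.sigma_ = sig
        self.sigma_full_ = comp.sigma_full(theta)
        self.fmin_ = fmin
        self.chi2_ = mult * fmin
        self.df_ = self.spec.degrees_of_freedom()
        self.n_ = int(n)
        self.s_sample_ = s
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        return self

    def to_semfit(self) -> SemFit:
        return SemFit(
            spec=self.spec, theta=self.theta_, se=self.se_,
            sigma_hat=self.sigma_, sigma_full=self.sigma_full_,
            chi2=self.chi2_, df=self.df_, n=self.n_,
            converged=self.converged_, n_iter=self.n_iter_,
            fmin=self.fmin_, s_sample=self.s_sample_,
            labels=self.labels_, param_cov=self.param_cov_,
            chi2_multiplier=self.chi2_multiplier,
        )

    # -- internals ---------------------------------------------------------
    def _start_values(self, comp: _CompiledSpec, s: np.ndarray) -> np.ndarray:
        base_var = 0.5 * float(np.mean(np.diag(s)))
        theta0 = np.where(comp.is_variance, base_var, 0.1)
        for lab, val in self.spec.start_values.items():
            if lab in comp.label_pos:
                theta0[comp.label_pos[lab]] = val
        return theta0

    def _standard_errors(self, comp, theta, sig, n):
        k = len(comp.labels)
        if k == 0:
            return {}, np.zeros((0, 0))
        try:
            cho = cho_factor(sig)
        except np.linalg.LinAlgError as err:
            raise NumericalError("implied covariance not positive definite at optimum") from err
        c = cho_solve(cho, np.eye(sig.shape[0]))
        dsig = comp.dsigma_obs(theta)
        cd = [c @ d for d in dsig]
        m = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                m[a, b] = m[b, a] = float(np.sum(cd[a] * cd[b].T))
        eig = np.linalg.eigvalsh(m)
        if eig[0] < 1e-10 * max(eig[-1], 1.0):
            raise IdentificationError(
                f"spec {self.spec.name!r}: information matrix is rank-deficient "
                f"(eigenvalues {eig})"
            )
        mult = n if self.chi2_multiplier == "n" else n - 1
        pcov = (2.0 / mult) * np.linalg.inv(m)
        se = {lab: math.sqrt(max(pcov[i, i], 0.0))
              for i, lab in enumerate(comp.labels)}
        return se, pcov


def fit_ml(spec: SemSpec, s: np.ndarray, n: int, **kwargs) -> SemFit:
    """Fit ``spec`` to sample moments ``s`` with sample size ``n``."""
    return SemModel(spec, **kwargs).fit_moments(s, n).to_semfit()


# --------------------------------------------------------------------------
# Baseline model and fit indices
# --------------------------------------------------------------------------

def saturated_spec(observed: Sequence[str], name: str = "saturated") -> SemSpec:
    """All variances and covariances free, no paths (df = 0)."""
    spec = SemSpec(observed, observed, name=name)
    for i, a in enumerate(observed):
        spec.add_variance(a, free=f"v_{a}")
        for b in observed[i + 1:]:
            spec.add_covariance(a, b, free=f"c_{a}_{b}")
    return spec


def independence_spec(observed: Sequence[str], name: str = "independence") -> SemSpec:
    """Free variances, all covariances fixed to zero (the CFI/TLI baseline)."""
    spec = SemSpec(observed, observed, name=name)
    for a in observed:
        spec.add_variance(a, free=f"v_{a}")
    return spec


def baseline_chi2(s: np.ndarray, n: int,
                  chi2_multiplier: str = "n") -> tuple[float, int]:
    """Chi-square and df of the independence baseline model.

    The ML solution of the independence model is analytic (fitted variances
    equal the sample variances), giving F_min = sum(log s_ii) - log|S|,
    i.e. minus the log-determinant of the sample correlation matrix.
    """
    s = np.asarray(s, float)
    p = s.shape[0]
    try:
        cho_s = cho_factor(s)
    except np.linalg.LinAlgError as err:
        raise NumericalError("baseline_chi2 requires a positive definite S") from err
    logdet_s = 2.0 * np.sum(np.log(np.diag(cho_s[0])))
    fmin = max(float(np.sum(np.log(np.diag(s))) - logdet_s), 0.0)
    mult = n if chi2_multiplier == "n" else n - 1
    return mult * fmin, p * (p - 1) // 2


def rmsea_ci(chi2: float, df: int, n: int,
             level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi-square confidence interval for the RMSEA.

    The bounds invert the noncentral chi-square distribution: the lower
    (upper) noncentrality is the value at which the observed chi-square sits
    at the (1+level)/2 ((1-level)/2) quantile; each bound is
    sqrt(lambda / (df * n)), floored at zero.
    """
    if df <= 0:
        raise ValidationError("rmsea_ci requires df > 0")
    chi2 = float(chi2)
    alpha_lo = (1.0 + level) / 2.0   # e.g. 0.95
    alpha_hi = (1.0 - level) / 2.0   # e.g. 0.05

    def cdf(lam):
        if lam <= 0:
            return stats.chi2.cdf(chi2, df)
        return stats.ncx2.cdf(chi2, df, lam)

    def solve(target):
        # cdf is decreasing in lambda
        if cdf(0.0) <= target:
            return 0.0
        hi = max(chi2, 1.0)
        for _ in range(200):
            if cdf(hi) < target:
                break
            hi *= 2.0
        else:  # pragma: no cover
            raise NumericalError(
                f"rmsea_ci: failed to bracket lambda for chi2={chi2}, df={df}"
            )
        return optimize.brentq(lambda lam: cdf(lam) - target, 0.0, hi, xtol=1e-10)

    lam_lo = solve(alpha_lo)
    lam_hi = solve(alpha_hi)
    lo = math.sqrt(max(lam_lo, 0.0) / (df * n))
    hi = math.sqrt(max(lam_hi, 0.0) / (df * n))
    return (min(lo, hi), max(lo, hi))


def fit_indices(fit: SemFit, baseline: tuple[float, int] | None = None,
                s: np.ndarray | None = None) -> FitIndices:
    """Descriptive fit indices for a fitted model.

    CFI and TLI compare misfit against the independence baseline (computed
    from the fit's own sample matrix when not supplied); RMSEA rates misfit
    per degree of freedom; SRMR is the root mean square of standardized
    residuals over the p(p+1)/2 unique elements including the diagonal.
    """
    s = fit.s_sample if s is None else np.asarray(s, float)
    if baseline is None:
        baseline = baseline_chi2(s, fit.n, chi2_multiplier=fit.chi2_multiplier)
    chi2_b, df_b = baseline
    if df_b < fit.df:
        raise ValidationError("baseline df must be >= model df")
    chi2, df, n = fit.chi2, fit.df, fit.n

    excess = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)

    if df > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = math.nan

    if df > 0:
        rmsea = math.sqrt(excess / (df * n))
        ci = rmsea_ci(chi2, df, n)
        p_value = float(stats.chi2.sf(chi2, df))
    else:
        rmsea = math.nan
        ci = (math.nan, math.nan)
        p_value = math.nan

    d = np.sqrt(np.diag(s))
    resid = (s - fit.sigma_hat) / np.outer(d, d)
    iu = np.triu_indices(s.shape[0])
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    return FitIndices(chi2=chi2, df=df, p_value=p_value, cfi=cfi, tli=tli,
                      rmsea=rmsea, rmsea_ci90=ci, srmr=srmr)
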