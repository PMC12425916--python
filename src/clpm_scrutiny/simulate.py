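"""Standardized two-wave data simulation matched to a target correlation matrix.

Variables are always ordered (P1, P2, E1, E2): predictor then outcome, wave 1
then wave 2 within each construct.  Draws come from a zero-mean multivariate
normal.  Two modes are provided:

``exact``
    The raw normal draws are whitened by their own sample covariance factor
    and recolored by the target factor, so the sample correlation matrix
    (denominator-n convention) equals the target to machine precision and
    every column has mean 0 and SD 1.  Standardized regression effects are
    functions of correlations, so exact mode makes every downstream fitted
    effect a deterministic function of the target matrix.

``stochastic``
    Plain i.i.d. multivariate-normal sampling; sample correlations fluctuate
    around the target, emulating a literal simulation draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .exceptions import DegenerateDataError, NotPositiveSemiDefiniteError, ValidationError
from .studies import StudyRecord

__all__ = [
    "VARIABLES",
    "CorrelationMatrix4",
    "Dataset",
    "correlation_matrix",
    "sample_mvn",
    "sample_correlations",
    "random_correlation_matrix",
]

VARIABLES = ("P1", "P2", "E1", "E2")

_SYM_TOL = 1e-12
_PSD_TOL = -1e-10


@dataclass(frozen=True)
class CorrelationMatrix4:
    """A validated 4x4 correlation matrix in (P1, P2, E1, E2) order."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(np.diag(m), 1.0, atol=_SYM_TOL):
            raise ValidationError("correlation matrix must have a unit diagonal")
        if not np.allclose(m, m.T, atol=_SYM_TOL):
            raise ValidationError("correlation matrix must be symmetric")
        smallest = float(np.linalg.eigvalsh(m)[0])
        if smallest < _PSD_TOL:
            raise NotPositiveSemiDefiniteError(
                f"correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {smallest:.3e})",
                smallest_eigenvalue=smallest,
            )
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, key):
        return self.matrix[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=VARIABLES, columns=VARIABLES)


@dataclass(frozen=True)
class Dataset:
    """An n x 4 standardized score matrix, columns in (P1, P2, E1, E2) order."""

    scores: np.ndarray
    mode: str
    seed: int

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=VARIABLES)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def correlation_matrix(record: StudyRecord) -> CorrelationMatrix4:
    """Assemble a study's six correlations into the 4x4 (P1, P2, E1, E2) matrix."""
    c = record.correlations()
    m = np.array([
        [1.0,          c["r_p1p2"], c["r_p1e1"], c["r_p1e2"]],
        [c["r_p1p2"], 1.0,          c["r_p2e1"], c["r_p2e2"]],
        [c["r_p1e1"], c["r_p2e1"], 1.0,          c["r_e1e2"]],
        [c["r_p1e2"], c["r_p2e2"], c["r_e1e2"], 1.0],
    ])
    try:
        return CorrelationMatrix4(m)
    except NotPositiveSemiDefiniteError as err:
        raise NotPositiveSemiDefiniteError(
            f"effect {record.effect_id!r}: {err}",
            smallest_eigenvalue=err.smallest_eigenvalue,
        ) from err


def _psd_cholesky(m: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of a semidefinite target."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def sample_mvn(target: CorrelationMatrix4, n: int, mode: str = "exact",
               seed: int = 0) -> Dataset:
    """Draw an n x 4 standardized dataset with the given target correlations.

    In exact mode the sample correlation matrix equals ``target`` to 1e-10
    and each column has mean 0 and SD 1 (denominator-n convention); the
    target must then be strictly positive definite and ``n > 4`` so that the
    sample covariance of the raw draws is invertible.
    """
    if not isinstance(target, CorrelationMatrix4):
        target = CorrelationMatrix4(np.asarray(target, dtype=float))
    if mode not in ("exact", "stochastic"):
        raise ValueError(f"mode must be 'exact' or 'stochastic', got {mode!r}")
    if n <= 4:
        raise ValueError(f"n must exceed 4 (got {n}); whitening is undefined below")
    rng = np.random.default_rng(seed)
    t = target.matrix
    if mode == "stochastic":
        scores = rng.multivariate_normal(np.zeros(4), t, size=n,
                                         method="cholesky" if _is_pd(t) else "eigh")
        return Dataset(scores=scores, mode=mode, seed=seed)
    # exact mode: whiten by the sample factor, recolor by the target factor
    z = rng.standard_normal((n, 4))
    z -= z.mean(axis=0)
    s = z.T @ z / n
    try:
        l_s = np.linalg.cholesky(s)
    except np.linalg.LinAlgError as err:  # pragma: no cover - needs degenerate draw
        raise DegenerateDataError("sample covariance of raw draws is singular") from err
    zw = solve_triangular(l_s, z.T, lower=True).T  # whitened: sample covariance = I
    l_t = _psd_cholesky(t)
    scores = zw @ l_t.T
    return Dataset(scores=scores, mode="exact", seed=seed)


def _is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def random_correlation_matrix(rng: np.random.Generator | int = 0,
                              n_factors: int = 6) -> CorrelationMatrix4:
    """A random positive-definite 4x4 correlation matrix (factor method).

    Rows of a random 4 x ``n_factors`` loading matrix are normalized so the
    Gram matrix has a unit diagonal; with more factors than variables the
    result is almost surely strictly positive definite.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w = rng.standard_normal((4, n_factors))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    r = w @ w.T
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix4((r + r.T) / 2.0)


def sample_correlations(data: Dataset) -> CorrelationMatrix4:
    """Pearson correlation matrix of a dataset's columns."""
    x = np.asarray(data.scores, dtype=float)
    if x.shape[0] < 4:
        raise DegenerateDataError("need at least 4 rows to compute correlations")
    sd = x.std(axis=0)
    if np.any(sd <= 0):
        bad = [VARIABLES[i] for i in np.where(sd <= 0)[0]]
        raise DegenerateDataError(f"zero-variance column(s): {bad}")
    r = np.corrcoef(x, rowvar=False)
    # guard tiny asymmetries/overshoot from floating point
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix4(r)
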