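"""Practical identifiability: sensitivity matrix, confidence intervals and
collinearity screening of parameter subsets.

The sensitivity matrix S is the N x m Jacobian of the (optionally
variance-stabilized) model solution at every observation with respect to the
m = 40 free parameters.  Confidence intervals follow the joint-projection
(Bates-Watts) form

    theta_j +/- sqrt( m * F(alpha; m, N-m) * s^2 * [(S'S)^-1]_jj ),
    s^2 = Phi / (N - m),

under normally distributed residuals; an interval that excludes zero makes
the parameter's sign identifiable.  The collinearity index of a parameter
subset is gamma = 1/sqrt(lambda_min) of the Gram matrix of the unit-
normalized sensitivity columns of that subset; gamma >= 1, and large values
flag jointly non-identifiable subsets.  Subsets of dimension 2 and 3 are
enumerated exhaustively, and a triple is only reported when none of its
pairs is already flagged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .fitting import CostEvaluator
from .model import (CircuitParameters, CircuitError, ExternalInputSeries,
                    default_bounds, parameter_labels)
from .simulate import DEFAULT_SCHEDULE, IntegrationError, Schedule

logger = logging.getLogger(__name__)

__all__ = ["SensitivityMatrix", "ConfidenceInterval", "CollinearSubset",
           "sensitivity", "confidence_intervals", "collinearity_index",
           "flag_subsets", "wildtype_only_analysis", "subset_table",
           "finite_difference_jacobian"]


def finite_difference_jacobian(fun, theta, steps, scheme: str = "central"):
    """Columnwise finite-difference Jacobian of a vector-valued function.

    ``fun(theta) -> (N,)``; ``steps`` is the per-parameter step.  Central
    differences are exact for affine models and second-order otherwise.
    Raises whatever ``fun`` raises (callers handle per-column failures).
    """
    theta = np.asarray(theta, float)
    steps = np.broadcast_to(np.asarray(steps, float), theta.shape)
    base = fun(theta) if scheme == "forward" else None
    cols = []
    for j in range(theta.size):
        dj = np.zeros_like(theta)
        dj[j] = steps[j]
        if scheme == "central":
            cols.append((fun(theta + dj) - fun(theta - dj)) / (2 * steps[j]))
        elif scheme == "forward":
            cols.append((fun(theta + dj) - base) / steps[j])
        else:
            raise CircuitError(f"unknown FD scheme {scheme!r}")
    return np.column_stack(cols)

#: collinearity-index threshold for flagging subsets
GAMMA_THRESHOLD = 7.0


@dataclass
class SensitivityMatrix:
    """N x m Jacobian with row/column bookkeeping.

    ``wt_rows`` flags rows computed at wild-type observations; ``labels``
    are the two-letter weight labels plus R/D/lam names; ``unreliable``
    marks columns at which a perturbed simulation failed.
    """

    S: np.ndarray
    labels: list
    wt_rows: np.ndarray
    transformed: bool = False
    unreliable: np.ndarray | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, float)
        n, m = self.S.shape
        if n <= m:
            raise CircuitError("need more observations than parameters")
        if len(self.labels) != m or self.wt_rows.size != n:
            raise CircuitError("label/row bookkeeping mismatch")
        if self.unreliable is None:
            self.unreliable = np.zeros(m, bool)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def m(self) -> int:
        return self.S.shape[1]

    def restricted(self, rows: np.ndarray) -> "SensitivityMatrix":
        sub = SensitivityMatrix.__new__(SensitivityMatrix)
        sub.S = self.S[rows]
        sub.labels = self.labels
        sub.wt_rows = self.wt_rows[rows]
        sub.transformed = self.transformed
        sub.unreliable = self.unreliable
        return sub


def sensitivity(params: CircuitParameters, dataset: ExpressionDataset,
                external: ExternalInputSeries | None = None,
                transform: bool = True,
                schedule: Schedule = DEFAULT_SCHEDULE,
                scheme: str = "central", rel_step: float = 1e-4,
                evaluator: CostEvaluator | None = None,
                **evaluator_kwargs) -> SensitivityMatrix:
    """Finite-difference Jacobian of the model observations.

    With ``transform=True`` the square-root variance-stabilizing transform
    is applied to the model solution before differencing, matching the
    transformed objective.  Steps are ``rel_step * max(|theta_j|, w_j)``
    with w_j the search-bound width of parameter j (central differences by
    default).  Columns whose perturbed simulation fails are zeroed and
    marked unreliable.
    """
    if external is not None:
        from dataclasses import replace
        dataset = replace(dataset, external=external)
    tf = (lambda y: np.sqrt(np.clip(y, 0.0, None))) if transform else None
    ev = evaluator or CostEvaluator(dataset, schedule, transform=tf,
                                    **evaluator_kwargs)

    theta = params.to_vector()
    m = theta.size
    lo, hi = default_bounds(params.roster)
    scale = np.maximum(np.abs(theta), hi - lo)
    steps = rel_step * scale

    def model_at(vec):
        p = CircuitParameters.from_vector(vec, roster=params.roster)
        y = ev.predict(p)
        return tf(y) if tf is not None else y

    S = np.zeros((ev.n, m))
    unreliable = np.zeros(m, bool)
    for j in range(m):
        ej = np.zeros(m)
        ej[j] = 1.0
        try:
            S[:, j] = finite_difference_jacobian(
                lambda a: model_at(theta + a[0] * ej), np.zeros(1),
                steps[j], scheme)[:, 0]
        except IntegrationError as exc:
            logger.warning("sensitivity column %d unreliable: %s", j, exc)
            unreliable[j] = True
    return SensitivityMatrix(S, parameter_labels(params.roster),
                             ev.wt_rows.copy(), transformed=transform,
                             unreliable=unreliable)


@dataclass
class ConfidenceInterval:
    label: str
    estimate: float
    lower: float
    upper: float
    alpha: float = 0.05
    identifiable: bool = True      # False when (S'S) was rank-deficient

    def __post_init__(self):
        if not (self.lower <= self.estimate <= self.upper):
            raise CircuitError("interval must bracket the estimate")

    @property
    def sign_identifiable(self) -> bool:
        """True when the interval is bounded away from zero."""
        return (self.lower > 0) or (self.upper < 0)


def confidence_intervals(S: SensitivityMatrix, residuals: np.ndarray,
                         estimates: np.ndarray,
                         alpha: float = 0.05) -> list:
    """Joint-projection confidence intervals for all parameters.

    half-width_j = sqrt( m * F(alpha; m, N-m) * s^2 * [(S'S)^-1]_jj ) with
    s^2 = Phi/(N-m).  A rank-deficient S'S falls back to the pseudo-inverse
    with a warning; the affected parameters are marked non-identifiable.
    """
    residuals = np.asarray(residuals, float)
    estimates = np.asarray(estimates, float)
    n, m = S.S.shape
    if residuals.size != n or estimates.size != m:
        raise CircuitError("residual/estimate sizes do not match S")
    gram = S.S.T @ S.S
    rank = np.linalg.matrix_rank(gram)
    deficient = rank < m
    if deficient:
        logger.warning("S'S is rank-deficient (rank %d < %d); using the "
                       "pseudo-inverse", rank, m)
        cov = np.linalg.pinv(gram)
        # parameters involved in the null space are not identifiable
        w, V = np.linalg.eigh(gram)
        null = V[:, w < w.max() * 1e-10]
        affected = np.any(np.abs(null) > 1e-8, axis=1)
    else:
        cov = np.linalg.inv(gram)
        affected = np.zeros(m, bool)
    phi = float(residuals @ residuals)
    s2 = phi / (n - m)
    fq = stats.f.ppf(1.0 - alpha, m, n - m)
    diag = np.clip(np.diag(cov), 0.0, None)
    half = np.sqrt(m * fq * s2 * diag)
    return [ConfidenceInterval(S.labels[j], float(estimates[j]),
                               float(estimates[j] - half[j]),
                               float(estimates[j] + half[j]), alpha,
                               identifiable=not affected[j])
            for j in range(m)]


# ---------------------------------------------------------------------------
# collinearity analysis
# ---------------------------------------------------------------------------

@dataclass
class CollinearSubset:
    labels: tuple
    gamma: float
    indices: tuple = field(default=())
    circuit_count: int = 1

    def __post_init__(self):
        if len(self.labels) < 2:
            raise CircuitError("a collinear subset has dimension >= 2")


def _normalized(S: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(S, axis=0)
    out = np.zeros_like(S)
    nz = norms > 0
    out[:, nz] = S[:, nz] / norms[nz]
    return out, nz


def collinearity_index(S, subset) -> float:
    """Collinearity index gamma = 1/sqrt(lambda_min) of the unit-normalized
    Gram matrix of the selected sensitivity columns.

    Columns are normalized to unit length (not centered).  A zero column or
    an exactly singular Gram matrix yields +inf.
    """
    A = S.S if isinstance(S, SensitivityMatrix) else np.asarray(S, float)
    if isinstance(subset[0], str):
        if not isinstance(S, SensitivityMatrix):
            raise CircuitError("label subsets need a SensitivityMatrix")
        subset = [S.labels.index(l) for l in subset]
    cols = A[:, list(subset)]
    if cols.shape[1] < 2:
        raise CircuitError("subset dimension must be >= 2")
    Sn, nz = _normalized(cols)
    if not np.all(nz):
        return np.inf
    lam_min = float(np.linalg.eigvalsh(Sn.T @ Sn)[0])
    if lam_min <= 1e-300:
        return np.inf
    return 1.0 / np.sqrt(lam_min)


def flag_subsets(S, kmax: int = 3, threshold: float = GAMMA_THRESHOLD,
                 labels=None) -> list:
    """Exhaustively screen parameter subsets of dimension 2..kmax.

    Reports every subset with gamma above the threshold that does not
    contain an already-flagged lower-dimensional subset, sorted by gamma
    descending.
    """
    A = S.S if isinstance(S, SensitivityMatrix) else np.asarray(S, float)
    labels = labels or (S.labels if isinstance(S, SensitivityMatrix)
                        else [str(j) for j in range(A.shape[1])])
    m = A.shape[1]
    Sn, nz = _normalized(A)
    flagged = []
    flagged_sets = []

    # dimension 2 via the cosine matrix: lambda_min = 1 - |cos|
    C = Sn.T @ Sn
    for i, j in itertools.combinations(range(m), 2):
        if not (nz[i] and nz[j]):
            gamma = np.inf
        else:
            lam = 1.0 - abs(C[i, j])
            gamma = np.inf if lam <= 1e-300 else 1.0 / np.sqrt(lam)
        if gamma > threshold:
            flagged.append(CollinearSubset((labels[i], labels[j]), gamma,
                                           (i, j)))
            flagged_sets.append({i, j})

    for k in range(3, kmax + 1):
        for combo in itertools.combinations(range(m), k):
            cs = set(combo)
            if any(fs <= cs for fs in flagged_sets if len(fs) < k):
                continue
            if not all(nz[j] for j in combo):
                gamma = np.inf
            else:
                lam = float(np.linalg.eigvalsh(
                    Sn[:, combo].T @ Sn[:, combo])[0])
                gamma = np.inf if lam <= 1e-300 else 1.0 / np.sqrt(lam)
            if gamma > threshold:
                flagged.append(CollinearSubset(
                    tuple(labels[j] for j in combo), gamma, combo))
                flagged_sets.append(cs)
    flagged.sort(key=lambda f: -f.gamma)
    return flagged


def wildtype_only_analysis(S: SensitivityMatrix, kmax: int = 3,
                           threshold: float = GAMMA_THRESHOLD) -> dict:
    """Collinearity screening restricted to the wild-type observation rows.

    Returns the restricted flags together with the full-data flags for
    comparison; a two-genotype fit is expected to flag no more subsets than
    the wild-type-only analysis.
    """
    full = flag_subsets(S, kmax, threshold)
    wt = flag_subsets(S.restricted(S.wt_rows), kmax, threshold)
    return {"wildtype_only": wt, "full": full,
            "n_wildtype_only": len(wt), "n_full": len(full)}


def subset_table(flags_per_circuit, threshold: float = GAMMA_THRESHOLD
                 ) -> pd.DataFrame:
    """Aggregate flagged subsets across circuits: parameter combination,
    mean collinearity index, and the number of circuits in which the index
    exceeds the threshold."""
    acc = {}
    for flags in flags_per_circuit:
        for f in flags:
            acc.setdefault(f.labels, []).append(f.gamma)
    rows = [{"parameters": "-".join(labels),
             "mean_gamma": float(np.mean([g for g in gs if np.isfinite(g)])
                                 if any(np.isfinite(g) for g in gs)
                                 else np.inf),
             "circuit_count": sum(g > threshold for g in gs)}
            for labels, gs in acc.items()]
    df = pd.DataFrame(rows)
    return df.sort_values("mean_gamma",
                          ascending=False).reset_index(drop=True)
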