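"""Regularized partial-correlation network estimation (EBIC-glasso).

A Gaussian graphical model encodes each pairwise conditional dependence as a
nonzero entry of the precision (inverse covariance) matrix K; the edge
weight between nodes i and j is the partial correlation

    rho_ij = -K_ij / sqrt(K_ii * K_jj).

Estimation follows the standard psychometric-network recipe: compute the
sample correlation matrix, fit the graphical lasso along a descending
log-spaced penalty grid, score every fit with the extended Bayesian
information criterion

    EBIC = -2 L + E log n + 4 E gamma log p,
    L = (n/2) (log det K - tr(S K)),

where E counts nonzero upper-triangle precision entries, and keep the
minimizer (ties break toward the larger penalty, i.e. the sparser model).
``gamma = 0.5`` is the conventional sparsity preference.  The reported
log-likelihood omits the additive -(n p / 2) log(2 pi) constant, which
cancels in model comparison.

Correlations default to Pearson on the node scores, with Spearman as the
rank-based option; polychoric correlations are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from ._glasso import glasso
from .exceptions import EstimationError, ValidationError
from .scales import NodeScoreTable

#: magnitude below which a weight counts as an exact zero
ZERO_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationMatrix:
    S: np.ndarray
    node_ids: tuple[str, ...]
    n: int
    method: str  # pearson | spearman

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class LambdaGrid:
    values: np.ndarray  # strictly positive, descending

    @property
    def n_lambda(self) -> int:
        return len(self.values)

    @property
    def min_ratio(self) -> float:
        return float(self.values[-1] / self.values[0])


@dataclass(frozen=True)
class PrecisionMatrix:
    K: np.ndarray
    lambda_used: float


@dataclass(frozen=True)
class EBICPath:
    """Per-penalty fit records and the EBIC-selected index."""

    table: pd.DataFrame  # columns: lambda, n_edges, log_likelihood, ebic
    gamma: float
    selected_index: int


@dataclass
class PartialCorrelationNetwork:
    """Symmetric partial-correlation adjacency with node/community labels."""

    W: np.ndarray
    node_ids: tuple[str, ...]
    community: dict[str, str]
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def edge_list(self) -> pd.DataFrame:
        """Nonzero upper-triangle edges as (node_i, node_j, weight)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.W[i, j]) > ZERO_TOL:
                    rows.append((self.node_ids[i], self.node_ids[j], self.W[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def correlation_matrix(scores: NodeScoreTable, method: str = "pearson") -> CorrelationMatrix:
    """Sample correlation matrix of the node scores.

    Raises
    ------
    ValidationError
        If a node has zero variance (correlation undefined), naming it.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if scores.n < 2:
        raise ValidationError("correlation requires at least 2 respondents")
    X = scores.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [scores.node_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance node(s): {bad}")
    if method == "pearson":
        S = np.corrcoef(X, rowvar=False)
    else:  # spearman = pearson on within-column ranks
        S = np.corrcoef(stats.rankdata(X, axis=0), rowvar=False)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return CorrelationMatrix(
        S=S, node_ids=tuple(scores.node_ids), n=scores.n, method=method
    )


def make_lambda_grid(
    S: CorrelationMatrix | np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01
) -> LambdaGrid:
    """Descending log-spaced penalty grid from lambda_max = max |S_offdiag|."""
    M = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S)
    if M.shape[0] < 2:
        raise ValidationError("need at least 2 nodes for a penalty grid")
    off = np.abs(M - np.diag(np.diag(M)))
    lam_max = float(off.max())
    if lam_max <= ZERO_TOL:
        raise EstimationError("all off-diagonal correlations are zero; degenerate grid")
    return LambdaGrid(values=np.geomspace(lam_max, min_ratio * lam_max, n_lambda))


def glasso_fit(
    S: CorrelationMatrix | np.ndarray,
    lam: float,
    W_init: np.ndarray | None = None,
    tol: float = 1e-6,
) -> PrecisionMatrix:
    """Graphical-lasso precision estimate at one penalty level.

    At ``lam = 0`` this is the unpenalized MLE ``inv(S)``; a singular S at
    ``lam = 0`` raises :class:`EstimationError` advising a positive penalty.
    """
    M = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValidationError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValidationError("penalty must be nonnegative")
    if lam == 0 and np.linalg.matrix_rank(M) < M.shape[0]:
        raise EstimationError(
            "S is singular at lambda=0; use a positive penalty"
        )
    _, K = glasso(M, lam, W_init=W_init, tol=tol)
    eig = np.linalg.eigvalsh(K)
    if eig.min() <= 0:
        raise EstimationError(
            f"glasso returned a non-PD precision at lambda={lam:g} "
            f"(min eigenvalue {eig.min():.3g})"
        )
    return PrecisionMatrix(K=K, lambda_used=float(lam))


def n_edges(K: np.ndarray) -> int:
    """Count nonzero upper-triangle off-diagonals (|.| > 1e-10)."""
    iu = np.triu_indices_from(K, k=1)
    return int(np.sum(np.abs(K[iu]) > ZERO_TOL))


def ebic_score(
    K: PrecisionMatrix | np.ndarray,
    S: CorrelationMatrix | np.ndarray,
    n: int,
    gamma: float,
) -> float:
    """Extended BIC of a fitted precision matrix (gamma=0 gives plain BIC)."""
    Km = K.K if isinstance(K, PrecisionMatrix) else np.asarray(K)
    Sm = S.S if isinstance(S, CorrelationMatrix) else np.asarray(S)
    sign, logdet = np.linalg.slogdet(Km)
    if sign <= 0:
        raise EstimationError("precision matrix must be positive definite")
    L = 0.5 * n * (logdet - np.trace(Sm @ Km))
    E = n_edges(Km)
    p = Km.shape[0]
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_partial(K: PrecisionMatrix | np.ndarray) -> np.ndarray:
    """Convert a precision matrix to partial-correlation edge weights.

    rho_ij = -K_ij / sqrt(K_ii K_jj); the diagonal is exactly zero and
    magnitudes below 1e-10 are stored as exact zeros.
    """
    Km = K.K if isinstance(K, PrecisionMatrix) else np.asarray(K, dtype=float)
    d = np.diag(Km)
    if np.any(d <= 0):
        raise EstimationError("precision diagonal must be positive")
    denom = np.sqrt(np.outer(d, d))
    W = -Km / denom
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < ZERO_TOL] = 0.0
    return (W + W.T) / 2.0


def ebic_glasso(
    scores: NodeScoreTable,
    gamma: float = 0.5,
    method: str = "pearson",
    n_lambda: int = 100,
    min_ratio: float = 0.01,
) -> tuple[PartialCorrelationNetwork, EBICPath]:
    """Estimate the partial-correlation network by glasso + EBIC selection.

    Fits the whole descending penalty grid with warm starts, scores each fit
    by EBIC at ``gamma``, and selects the minimizer (first/larger-penalty
    fit on exact ties).  Fits that fail numerically are recorded with
    infinite EBIC and skipped.
    """
    S = correlation_matrix(scores, method=method)
    grid = make_lambda_grid(S, n_lambda=n_lambda, min_ratio=min_ratio)
    records = []
    fits: list[np.ndarray | None] = []
    W_warm: np.ndarray | None = None
    for lam in grid.values:
        try:
            Wc, K = glasso(S.S, float(lam), W_init=W_warm)
            eig_min = np.linalg.eigvalsh(K).min()
            if eig_min <= 0:
                raise EstimationError("non-PD fit")
            W_warm = Wc
        except (EstimationError, np.linalg.LinAlgError, FloatingPointError):
            records.append((float(lam), 0, np.nan, np.inf))
            fits.append(None)
            continue
        sign, logdet = np.linalg.slogdet(K)
        L = 0.5 * S.n * (logdet - np.trace(S.S @ K))
        E = n_edges(K)
        ebic = -2.0 * L + E * np.log(S.n) + 4.0 * E * gamma * np.log(S.p)
        records.append((float(lam), E, float(L), float(ebic)))
        fits.append(K)
    table = pd.DataFrame(
        records, columns=["lambda", "n_edges", "log_likelihood", "ebic"]
    )
    if not np.isfinite(table["ebic"]).any():
        raise EstimationError("no penalty level produced a valid glasso fit")
    selected = int(np.argmin(table["ebic"].to_numpy()))  # first occurrence = larger lambda
    K_sel = fits[selected]
    W = precision_to_partial(K_sel)
    net = PartialCorrelationNetwork(
        W=W,
        node_ids=S.node_ids,
        community={nid: scores.community.get(nid, "unknown") for nid in S.node_ids},
        provenance={
            "n": S.n,
            "p": S.p,
            "gamma": gamma,
            "method": method,
            "lambda_selected": float(grid.values[selected]),
            "n_lambda": grid.n_lambda,
            "min_ratio": min_ratio,
        },
    )
    path = EBICPath(table=table, gamma=gamma, selected_index=selected)
    return net, path
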