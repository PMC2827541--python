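"""Maximum (penalized) pseudolikelihood estimation by logistic regression.

Maximizing the pseudolikelihood of the binary MRF reduces to a logistic
regression in which every labeled node is one statistical unit, the response
is the node's state, and the predictors are the counts of its neighbors in
state 1 and state 0.  Two case-building conventions are provided:

* :func:`build_cases_annotated_only` — the two-step baseline's convention:
  only POS/NEG nodes contribute rows, and UNKNOWN neighbors are pruned from
  the counts (so neighborhoods shrink, which is what biases that baseline's
  estimates toward larger magnitudes).
* :func:`build_cases_full` — the joint sampler's convention: all UNKNOWN
  states have been imputed, imputed nodes contribute to the neighbor counts,
  and response rows are restricted to the originally-annotated nodes
  (``scope='observed'``) or extended to every node (``scope='all'``).

Plain fitting uses iteratively reweighted least squares; the penalized
variant applies the Firth modified-score (Jeffreys-prior) correction, which
keeps estimates finite under complete separation — the common situation for
sparse functional terms with few positive examples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mrf_model import ContractViolation, Theta, sigmoid
from .network_io import NEG, POS, UNKNOWN, ProteinNetwork

logger = logging.getLogger(__name__)

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class DegenerateResponseError(ValueError):
    """All responses are identical; the logistic model is unidentified."""


class SeparationWarning(UserWarning):
    """Maximum-likelihood logistic estimates diverged (complete separation)."""


@dataclass
class TrainingCases:
    """Per-node rows (response, m1, m0) with node-identifier provenance."""

    response: np.ndarray  # (n,) 0/1
    m1: np.ndarray        # (n,) neighbors in state 1 (kernel-weighted sums may be real)
    m0: np.ndarray        # (n,) neighbors in state 0
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=np.int64)
        self.m1 = np.asarray(self.m1)
        self.m0 = np.asarray(self.m0)

    @property
    def n(self) -> int:
        return self.response.shape[0]

    def design_matrix(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(self.n), self.m1.astype(float), self.m0.astype(float)]
        )


@dataclass
class FitResult:
    theta: Theta
    covariance: np.ndarray  # 3x3; inf on the diagonal for dropped predictors
    converged: bool
    n_cases: int
    message: str = ""


def build_cases_annotated_only(
    network: ProteinNetwork, labels: np.ndarray
) -> TrainingCases:
    """One row per POS/NEG node, with UNKNOWN neighbors pruned from counts."""
    labels = np.asarray(labels)
    annotated = np.flatnonzero(labels != UNKNOWN)
    if annotated.size == 0 or len(set(labels[annotated].tolist())) < 2:
        raise DegenerateResponseError(
            "need at least one POS and one NEG node to build training cases"
        )
    a = network.adjacency
    m1 = (a @ (labels == POS).astype(np.int64))[annotated]
    m0 = (a @ (labels == NEG).astype(np.int64))[annotated]
    return TrainingCases(
        response=(labels[annotated] == POS).astype(np.int64),
        m1=m1,
        m0=m0,
        node_ids=[network.nodes[i] for i in annotated],
    )


def build_cases_full(
    network: ProteinNetwork,
    imputed_labels: np.ndarray,
    observed_mask: np.ndarray | None = None,
    scope: str = "all",
) -> TrainingCases:
    """Training cases from a fully imputed labeling.

    Imputed nodes always contribute to the neighbor counts; *scope* selects
    which nodes contribute response rows — ``'all'`` (default, matching the
    pseudolikelihood's product over all nodes) keeps every node,
    ``'observed'`` keeps only the originally-annotated nodes given by
    *observed_mask*.
    """
    imputed_labels = np.asarray(imputed_labels)
    if np.any(imputed_labels == UNKNOWN):
        raise ContractViolation("build_cases_full requires a fully imputed labeling")
    n = network.n_nodes
    if scope == "all":
        rows = np.arange(n)
    elif scope == "observed":
        if observed_mask is None:
            raise ValueError("scope='observed' requires observed_mask")
        rows = np.flatnonzero(np.asarray(observed_mask))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    a = network.adjacency
    m1 = (a @ (imputed_labels == POS).astype(np.int64))[rows]
    m0 = (a @ (imputed_labels == NEG).astype(np.int64))[rows]
    return TrainingCases(
        response=(imputed_labels[rows] == POS).astype(np.int64),
        m1=m1,
        m0=m0,
        node_ids=[network.nodes[i] for i in rows],
    )


def _active_columns(X: np.ndarray) -> np.ndarray:
    """Indices of design columns to fit: intercept plus non-constant predictors.

    Columns that would make the design rank-deficient (collinear predictors,
    or more columns than rows) are dropped as well; their coefficients are
    reported as 0 with infinite variance.
    """
    active = [0]
    for k in (1, 2):
        if np.ptp(X[:, k]) > 0:
            candidate = active + [k]
            if np.linalg.matrix_rank(X[:, candidate]) == len(candidate):
                active.append(k)
    return np.array(active)


def _expand(beta_active: np.ndarray, cov_active: np.ndarray, active: np.ndarray):
    beta = np.zeros(3)
    cov = np.zeros((3, 3))
    np.fill_diagonal(cov, np.inf)
    beta[active] = beta_active
    cov[np.ix_(active, active)] = cov_active
    return beta, cov


def fit_logistic(cases: TrainingCases) -> FitResult:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    Iterates to gradient max-norm < 1e-8 or 100 iterations; the covariance is
    the inverse observed Fisher information.  Complete separation shows up as
    non-convergence with diverging coefficients and is reported via
    ``converged=False`` and a :class:`SeparationWarning` — callers should
    fall back to :func:`fit_penalized`.
    """
    y = cases.response
    if cases.n < 2 or y.min() == y.max():
        raise DegenerateResponseError("need >=2 rows with both response values")
    X_full = cases.design_matrix()
    active = _active_columns(X_full)
    X = X_full[:, active]
    beta = np.zeros(X.shape[1])
    converged = False
    message = ""
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        p = sigmoid(eta)
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < IRLS_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
    eta = X @ beta
    p = sigmoid(eta)
    # under complete separation the gradient still vanishes numerically while
    # the coefficients diverge and the fit classifies perfectly
    separated = (
        np.max(np.abs(beta)) > 10.0
        and np.all(p[y == 1] > 1 - 1e-4)
        and np.all(p[y == 0] < 1e-4)
    )
    if separated:
        converged = False
    if not converged:
        message = (
            "logistic coefficients diverged (complete separation)"
            if separated
            else "IRLS did not converge; responses may be completely separated"
        )
        warnings.warn(message, SeparationWarning)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov_active = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_active = np.full((X.shape[1], X.shape[1]), np.inf)
    full_beta, full_cov = _expand(beta, cov_active, active)
    return FitResult(
        theta=Theta.from_array(full_beta),
        covariance=full_cov,
        converged=converged,
        n_cases=cases.n,
        message=message,
    )


def fit_penalized(cases: TrainingCases, max_iter: int = 200) -> FitResult:
    """Bias-reduced logistic fit by Firth's modified score.

    The Jeffreys-prior penalty 0.5*log|X'WX| removes the leading-order bias
    of the ML estimate and guarantees finite coefficients even under complete
    separation, which makes it the right initializer for the joint sampler.
    The covariance is the inverse penalized information.
    """
    y = cases.response.astype(float)
    if cases.n < 2:
        raise DegenerateResponseError("need >=2 rows")
    X_full = cases.design_matrix()
    active = _active_columns(X_full)
    X = X_full[:, active]
    k = X.shape[1]
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = sigmoid(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # leverages of the weighted design: h_i = w_i * x_i' (X'WX)^{-1} x_i
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < IRLS_TOL:
            converged = True
            break
        step = info_inv @ score
        # damp very large steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
    eta = X @ beta
    p = sigmoid(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov_active = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_active = np.linalg.pinv(info)
    full_beta, full_cov = _expand(beta, cov_active, active)
    if not np.all(np.isfinite(full_beta)):  # pragma: no cover - guarded by damping
        raise RuntimeError("penalized fit produced non-finite coefficients")
    return FitResult(
        theta=Theta.from_array(full_beta),
        covariance=full_cov,
        converged=converged,
        n_cases=cases.n,
    )
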