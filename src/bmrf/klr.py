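"""Diffusion-kernel logistic regression comparator.

The diffusion kernel K = expm(beta * H), with H = A - D the opposite
Laplacian of the adjacency matrix, replaces hard adjacency with a smoothed
notion of neighborhood: K_ij is the amount of "heat" that diffuses from j to
i in time beta.  KLR then fits the same two-predictor logistic model as the
MRF conditional, but with kernel-weighted sums over annotated positive and
negative proteins in place of raw neighbor counts — ignoring label
uncertainty in both fitting and prediction.  The matrix exponential is
computed densely by scaling-and-squaring (Pade), which is what makes KLR
impractical on large networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import estimators
from .estimators import FitResult, TrainingCases, fit_logistic, fit_penalized
from .mrf_model import sigmoid
from .network_io import NEG, POS, UNKNOWN, ProteinNetwork

logger = logging.getLogger(__name__)

DEFAULT_BETA = 1.0
DEFAULT_SIZE_CAP = 3000


class NetworkTooLargeError(ValueError):
    """The dense matrix exponential is impractical at this size."""


@dataclass
class DiffusionKernel:
    matrix: np.ndarray  # dense symmetric N x N
    beta: float


def diffusion_kernel(
    network: ProteinNetwork,
    beta: float = DEFAULT_BETA,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> DiffusionKernel:
    """K = expm(beta * (A - D)) by dense scaling-and-squaring.

    The opposite Laplacian has zero column sums, so K is symmetric with unit
    column sums for every beta; beta=0 gives the identity.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    n = network.n_nodes
    if n > size_cap:
        raise NetworkTooLargeError(
            f"network has {n} nodes (> cap {size_cap}); the dense matrix "
            "exponential is impractical here — consider the bmrf sampler instead"
        )
    a = network.adjacency.toarray().astype(float)
    h = a - np.diag(a.sum(axis=1))
    if beta == 0:
        return DiffusionKernel(np.eye(n), 0.0)
    return DiffusionKernel(expm(beta * h), float(beta))


def kernel_predictors(
    kernel: DiffusionKernel, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-weighted annotated-neighbor sums s1, s0 for every node.

    s1_i sums K_ij over annotated-positive j != i; s0_i over
    annotated-negative j != i.  UNKNOWN proteins contribute to neither
    predictor; the diagonal (self-similarity) is excluded to mirror the
    neighbor-count form of the MRF conditional.
    """
    labels = np.asarray(labels)
    k = kernel.matrix
    pos = (labels == POS).astype(float)
    neg = (labels == NEG).astype(float)
    d = np.diag(k)
    s1 = k @ pos - d * pos
    s0 = k @ neg - d * neg
    return s1, s0


def klr_predict(
    kernel: DiffusionKernel, labels: np.ndarray, node_ids: list[str] | None = None
) -> tuple[np.ndarray, FitResult]:
    """Fit the kernel logistic model on annotated nodes; score every node.

    Returns ``(scores, fit)`` with one fitted probability per node.  Falls
    back to the Firth-penalized fit (logged) if the ML fit separates.
    """
    labels = np.asarray(labels)
    annotated = np.flatnonzero(labels != UNKNOWN)
    if annotated.size == 0 or len(set(labels[annotated].tolist())) < 2:
        raise estimators.DegenerateResponseError(
            "klr_predict needs at least one POS and one NEG node"
        )
    s1, s0 = kernel_predictors(kernel, labels)
    ids = node_ids or [str(i) for i in range(labels.shape[0])]
    cases = TrainingCases(
        response=(labels[annotated] == POS).astype(np.int64),
        m1=s1[annotated],
        m0=s0[annotated],
        node_ids=[ids[i] for i in annotated],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", estimators.SeparationWarning)
        fit = fit_logistic(cases)
    if not fit.converged:
        logger.info("KLR ML fit separated; falling back to penalized fit")
        fit = fit_penalized(cases)
    theta = fit.theta
    scores = sigmoid(theta.alpha + theta.beta * s1 + theta.gamma * s0)
    return np.asarray(scores, dtype=float), fit
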