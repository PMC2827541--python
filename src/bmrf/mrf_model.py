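"""Markov random field model for binary function labels on a network.

The homogeneous second-order MRF over binary labels x on an interaction
network has an intractable normalizing constant, so all inference here works
with the pseudolikelihood: the product over nodes of the conditional
probability of each node's state given its neighbors.  That conditional is a
logistic regression with two neighbor-count predictors,

    logit P(x_i = 1 | x_neighbors) = alpha + beta * M1_i + gamma * M0_i,

where M1_i / M0_i count the neighbors of node i currently in state 1 / 0.
``Theta = (alpha, beta, gamma)`` is the minimal 3-parameter form; the
redundant 4-parameter pairwise-energy form is only ever materialised as
diagnostic :class:`EnergyCounts`.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .network_io import NEG, POS, UNKNOWN, ProteinNetwork


class Theta(NamedTuple):
    """MRF parameters: intercept and the two neighbor-count coefficients."""

    alpha: float
    beta: float   # coefficient of M1, neighbors in state 1
    gamma: float  # coefficient of M0, neighbors in state 0

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    @staticmethod
    def from_array(arr) -> "Theta":
        a, b, g = np.asarray(arr, dtype=float)
        return Theta(float(a), float(b), float(g))


class NeighborCounts(NamedTuple):
    m1: int
    m0: int


class EnergyCounts(NamedTuple):
    """Sufficient statistics of the pairwise energy (diagnostics only).

    n1: nodes in state 1; n11/n10/n00: edges whose endpoint states are
    (1,1) / mixed / (0,0).
    """

    n1: int
    n11: int
    n10: int
    n00: int


class ContractViolation(ValueError):
    """An operation was called outside its stated preconditions."""


def sigmoid(x):
    """Numerically stable logistic function, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def log_sigmoid(x):
    """log(sigmoid(x)) without overflow: -log1p(exp(-x)) done stably."""
    x = np.asarray(x, dtype=float)
    # -softplus(-x) = min(x, 0) - log1p(exp(-|x|))
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def neighbor_counts(
    network: ProteinNetwork,
    labels: np.ndarray,
    node: str,
    include_unknown: bool = False,
) -> NeighborCounts:
    """Counts of a node's neighbors in state 1 and state 0.

    With ``include_unknown=False`` (the pruning convention used when training
    on annotated proteins only), UNKNOWN neighbors contribute to neither
    count.  With ``include_unknown=True`` the caller asserts that every
    neighbor carries an imputed state; an UNKNOWN neighbor is then an error.
    """
    i = network.index[node]
    states = labels[network.neighbor_indices(i)]
    if include_unknown and np.any(states == UNKNOWN):
        raise ContractViolation(
            f"node {node!r} has UNKNOWN neighbors but include_unknown=True"
        )
    return NeighborCounts(int(np.sum(states == POS)), int(np.sum(states == NEG)))


def all_neighbor_counts(
    network: ProteinNetwork, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(m1, m0) arrays for every node at once; UNKNOWN neighbors count to neither."""
    a = network.adjacency
    m1 = a @ (labels == POS).astype(np.int64)
    m0 = a @ (labels == NEG).astype(np.int64)
    return m1, m0


def conditional_logit(theta: Theta, counts: NeighborCounts) -> float:
    """Log-odds that a node is in state 1 given its neighbor counts."""
    return float(theta.alpha + theta.beta * counts.m1 + theta.gamma * counts.m0)


def conditional_logits(theta: Theta, m1: np.ndarray, m0: np.ndarray) -> np.ndarray:
    return theta.alpha + theta.beta * m1 + theta.gamma * m0


def log_plf(
    theta: Theta,
    labels: np.ndarray,
    network: ProteinNetwork,
    scope: np.ndarray | None = None,
) -> float:
    """Log-pseudolikelihood of a fully imputed labeling.

    Sum over nodes of log P(x_i | x_neighbors, theta); *scope* optionally
    restricts the sum to a boolean node mask (e.g. the originally-annotated
    nodes).  Every node must carry a state; finite theta gives a finite value.
    """
    labels = np.asarray(labels)
    if np.any(labels == UNKNOWN):
        raise ContractViolation("log_plf requires a fully imputed labeling")
    m1, m0 = all_neighbor_counts(network, labels)
    return log_plf_from_counts(theta, labels, m1, m0, scope)


def log_plf_from_counts(
    theta: Theta,
    labels: np.ndarray,
    m1: np.ndarray,
    m0: np.ndarray,
    scope: np.ndarray | None = None,
) -> float:
    """Log-PLF given precomputed neighbor-count arrays (sampler fast path)."""
    z = conditional_logits(theta, m1, m0)
    y = labels == POS
    # y*z - softplus(z), summed over scope
    terms = np.where(y, z, 0.0) - (np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z))))
    if scope is not None:
        terms = terms[scope]
    return float(np.sum(terms))


def energy_counts(network: ProteinNetwork, labels: np.ndarray) -> EnergyCounts:
    """Edge-class and node counts of a fully labeled network (diagnostics)."""
    labels = np.asarray(labels)
    if np.any(labels == UNKNOWN):
        raise ContractViolation("energy_counts requires a fully labeled network")
    n1 = int(np.sum(labels == POS))
    n11 = n10 = n00 = 0
    for u, v in network.edges:
        su, sv = labels[network.index[u]], labels[network.index[v]]
        if su == POS and sv == POS:
            n11 += 1
        elif su == NEG and sv == NEG:
            n00 += 1
        else:
            n10 += 1
    return EnergyCounts(n1, n11, n10, n00)
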