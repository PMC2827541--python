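"""MCMC inference engines for function labels on an interaction network.

Three entry points:

* :func:`gibbs_sweep` — one sequential Gibbs sweep of label updates at fixed
  parameters (also the building block of the synthetic-label simulator).
* :func:`mrf_deng` — the classic two-step baseline: fit theta once on the
  annotated subnetwork (pruning unannotated neighbors), then Gibbs-sample the
  unknown labels at that fixed theta.
* :func:`bmrf` — the Bayesian joint sampler: alternate Gibbs label sweeps
  with adaptive Differential Evolution MCMC (DEMC) updates of theta on the
  pseudolikelihood, so predictions average over both label and parameter
  uncertainty.

The DEMC proposal adds a scaled difference of two distinct rows drawn from
an archive Z of past parameter states, plus a small uniform jitter; with the
optimal scaling 2.38/sqrt(2d) it self-tunes to the posterior geometry.  The
posterior probability of each originally-unknown protein is the
Rao-Blackwellized average of the conditional probabilities used in its Gibbs
updates after burn-in.

The inner sweep loop is compiled with numba; all randomness is pre-drawn
from a single seeded numpy Generator per run, so results are exactly
reproducible given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import estimators
from .estimators import FitResult, build_cases_annotated_only, fit_logistic, fit_penalized
from .mrf_model import ContractViolation, Theta, log_plf_from_counts, sigmoid
from .network_io import POS, UNKNOWN, ProteinNetwork

logger = logging.getLogger(__name__)

#: ter Braak's optimal DEMC step size at parameter dimension d=3.
DEFAULT_GAMMA_STEP = 2.38 / math.sqrt(2 * 3)


@dataclass
class McmcConfig:
    """Run-length and proposal settings shared by the samplers.

    ``gamma_step`` is the DEMC scaling factor (default 2.38/sqrt(2d), d=3);
    ``eps_scale`` the half-width of the uniform jitter on each proposal
    component; ``z_init_size`` the number of archive rows drawn around the
    penalized pseudolikelihood estimate before the chain starts;
    ``plf_scope`` selects whether the Metropolis ratio for theta sums the
    pseudolikelihood over every node (``'all'``, default — the
    pseudolikelihood is the product of the conditional probabilities across
    all nodes) or over originally-annotated nodes only (``'observed'``,
    which anchors theta exclusively to observed responses).
    """

    n_iter: int = 2000
    burn_in: int = 500
    seed: int = 0
    gamma_step: float = DEFAULT_GAMMA_STEP
    eps_scale: float = 1e-4
    z_init_size: int = 30
    plf_scope: str = "all"
    #: optional (low, high) support of the uniform parameter prior, applied
    #: componentwise; None means an unbounded flat prior.  A bounded box
    #: keeps the posterior proper on tiny or separation-prone problems.
    theta_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.z_init_size < 3:
            raise ValueError("z_init_size must be >= 3")
        if self.plf_scope not in ("observed", "all"):
            raise ValueError("plf_scope must be 'observed' or 'all'")


@dataclass
class PosteriorSummary:
    """Posterior output for the originally-unknown proteins of one run."""

    nodes: list[str]
    probabilities: np.ndarray
    theta_mean: Theta
    theta_sd: Theta
    acceptance_rate: float
    n_proposed: int = 0
    n_accepted: int = 0
    theta_samples: np.ndarray | None = field(default=None, repr=False)
    init_fit: FitResult | None = field(default=None, repr=False)
    archive: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.probabilities.tolist()))


@njit(cache=False)
def _sweep_kernel(indptr, indices, state, m1, m0, alpha, beta, gamma, order, uniforms, probs):
    """Sequential Gibbs updates over `order`, maintaining neighbor counts."""
    for k in range(order.shape[0]):
        i = order[k]
        z = alpha + beta * m1[i] + gamma * m0[i]
        if z >= 0.0:
            p = 1.0 / (1.0 + np.exp(-z))
        else:
            e = np.exp(z)
            p = e / (1.0 + e)
        probs[k] = p
        new = 1 if uniforms[k] < p else 0
        old = state[i]
        if new != old:
            state[i] = new
            d = 1 if new == 1 else -1
            for jj in range(indptr[i], indptr[i + 1]):
                j = indices[jj]
                m1[j] += d
                m0[j] -= d


class _GibbsEngine:
    """Mutable sweep state: 0/1 labels plus per-node neighbor counts."""

    def __init__(self, network: ProteinNetwork, state01: np.ndarray) -> None:
        adj = network.adjacency
        self.indptr = adj.indptr.astype(np.int64)
        self.indices = adj.indices.astype(np.int64)
        self.state = np.ascontiguousarray(state01, dtype=np.int8)
        self.m1 = adj @ self.state.astype(np.int64)
        self.m0 = adj @ (1 - self.state).astype(np.int64)

    def sweep(self, theta: Theta, targets: np.ndarray, rng: np.random.Generator):
        """One sweep over a fresh permutation of *targets*.

        Returns ``(visit_order, cond_probs)`` with the conditional
        probability of state 1 used at each visit.
        """
        order = rng.permutation(targets).astype(np.int64)
        uniforms = rng.random(order.shape[0])
        probs = np.empty(order.shape[0])
        _sweep_kernel(
            self.indptr, self.indices, self.state, self.m1, self.m0,
            float(theta.alpha), float(theta.beta), float(theta.gamma),
            order, uniforms, probs,
        )
        return order, probs


def gibbs_sweep(
    network: ProteinNetwork,
    labels: np.ndarray,
    theta: Theta,
    rng: np.random.Generator,
    targets: np.ndarray | None = None,
):
    """One sequential Gibbs sweep over *targets* (node indices).

    *labels* must be fully imputed (no UNKNOWN).  Nodes are visited in a
    fresh uniformly-random permutation; each target's state is redrawn
    Bernoulli(sigmoid(logit)) from the counts of its CURRENT neighbor states.
    Returns ``(new_labels, cond_probs)`` where ``cond_probs`` is a
    full-length array holding, for each visited node, the conditional
    probability of state 1 it was drawn with (NaN for unvisited nodes).
    The input array is not modified.
    """
    labels = np.asarray(labels)
    if np.any(labels == UNKNOWN):
        raise ContractViolation("gibbs_sweep requires a fully imputed labeling")
    if targets is None:
        targets = np.arange(network.n_nodes)
    targets = np.asarray(targets, dtype=np.int64)
    engine = _GibbsEngine(network, (labels == POS).astype(np.int8))
    order, probs = engine.sweep(theta, targets, rng)
    out = np.full(network.n_nodes, np.nan)
    out[order] = probs
    return engine.state.astype(np.int8), out


def demc_propose(
    theta: Theta,
    archive: np.ndarray,
    gamma_step: float,
    eps_scale: float,
    rng: np.random.Generator,
) -> Theta:
    """DEMC candidate: theta + gamma*(Z[R1]-Z[R2]) + e, R1 != R2 uniform.

    The jitter e has independent components uniform on
    (-eps_scale, +eps_scale); it breaks the degeneracy of pure difference
    proposals while keeping the proposal symmetric.
    """
    archive = np.asarray(archive, dtype=float)
    if archive.shape[0] < 2:
        raise ContractViolation("DEMC archive needs at least 2 rows")
    r1 = int(rng.integers(archive.shape[0]))
    r2 = int(rng.integers(archive.shape[0] - 1))
    if r2 >= r1:
        r2 += 1
    eps = rng.uniform(-eps_scale, eps_scale, size=3)
    cand = theta.as_array() + gamma_step * (archive[r1] - archive[r2]) + eps
    return Theta.from_array(cand)


def metropolis_accept(
    log_plf_candidate: float,
    log_plf_current: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis test at a symmetric proposal under a flat parameter prior."""
    if not (np.isfinite(log_plf_candidate) and np.isfinite(log_plf_current)):
        raise ContractViolation("metropolis_accept requires finite log-PLF values")
    diff = log_plf_candidate - log_plf_current
    if diff >= 0:
        return True
    return bool(rng.random() < math.exp(diff))


def _fit_initial_theta(network: ProteinNetwork, labels: np.ndarray) -> FitResult:
    """ML fit on the annotated subnetwork, penalized fallback on separation."""
    cases = build_cases_annotated_only(network, labels)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", estimators.SeparationWarning)
        fit = fit_logistic(cases)
    if not fit.converged:
        logger.info("ML fit did not converge (separation?); using penalized fit")
        fit = fit_penalized(cases)
    return fit


def mrf_deng(
    network: ProteinNetwork,
    labels: np.ndarray,
    config: McmcConfig | None = None,
    theta_override: Theta | None = None,
) -> PosteriorSummary:
    """Two-step baseline: fixed-theta Gibbs sampling of the unknown labels.

    Step 1 estimates theta by logistic regression on the annotated nodes,
    pruning unannotated neighbors from the counts (penalized fallback under
    separation).  Step 2 initializes each unknown state by an independent
    Bernoulli draw at the annotated positive prevalence, then runs
    ``config.n_iter`` Gibbs sweeps at the fixed theta.  The posterior for
    each unknown protein is the average of the conditional probabilities
    used in its updates after burn-in.

    *theta_override* bypasses step 1 (testing hook).
    """
    config = config or McmcConfig()
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    if theta_override is not None:
        theta = theta_override
        init_fit = None
    else:
        init_fit = _fit_initial_theta(network, labels)
        theta = init_fit.theta
    unknown = np.flatnonzero(labels == UNKNOWN)
    zeros = Theta(0.0, 0.0, 0.0)
    if unknown.size == 0:
        return PosteriorSummary(
            nodes=[], probabilities=np.empty(0), theta_mean=theta,
            theta_sd=zeros, acceptance_rate=float("nan"), init_fit=init_fit,
        )
    annotated = labels != UNKNOWN
    prevalence = float(np.mean(labels[annotated] == POS)) if annotated.any() else 0.5
    state = (labels == POS).astype(np.int8)
    state[unknown] = (rng.random(unknown.size) < prevalence).astype(np.int8)
    engine = _GibbsEngine(network, state)
    acc = np.zeros(network.n_nodes)
    n_kept = 0
    for t in range(config.n_iter):
        order, probs = engine.sweep(theta, unknown, rng)
        if t >= config.burn_in:
            acc[order] += probs
            n_kept += 1
        if (t + 1) % 100 == 0:
            logger.debug("mrf_deng iter %d/%d", t + 1, config.n_iter)
    posterior = acc[unknown] / n_kept
    return PosteriorSummary(
        nodes=[network.nodes[i] for i in unknown],
        probabilities=posterior,
        theta_mean=theta,
        theta_sd=zeros,
        acceptance_rate=float("nan"),
        init_fit=init_fit,
    )


def _draw_archive(fit: FitResult, size: int, rng: np.random.Generator) -> np.ndarray:
    """Initial Z: draws from N(theta_hat, cov); dropped components stay fixed."""
    mean = fit.theta.as_array()
    cov = np.array(fit.covariance, dtype=float)
    finite = np.isfinite(np.diag(cov))
    archive = np.tile(mean, (size, 1))
    if finite.any():
        sub = cov[np.ix_(finite, finite)]
        archive[:, finite] = rng.multivariate_normal(
            mean[finite], sub, size=size, method="cholesky", check_valid="ignore"
        )
    return archive


def bmrf(
    network: ProteinNetwork,
    labels: np.ndarray,
    config: McmcConfig | None = None,
) -> PosteriorSummary:
    """Joint Bayesian sampler over unknown labels and MRF parameters.

    Per iteration: one Gibbs sweep over the unknown labels at the current
    theta, then one DEMC proposal for theta accepted by a Metropolis test on
    the log-pseudolikelihood of the current imputed labeling (flat prior),
    then the current theta is appended to the archive.  Labels are
    initialized by Bernoulli draws from the MRF-Deng posterior; the archive
    is seeded with ``z_init_size`` draws from a normal centered at the
    Firth-penalized pseudolikelihood estimate with its covariance.
    """
    config = config or McmcConfig()
    labels = np.asarray(labels)
    unknown = np.flatnonzero(labels == UNKNOWN)
    if unknown.size == 0:
        raise ValueError("bmrf requires at least one UNKNOWN node")
    rng = np.random.default_rng(config.seed)

    base = mrf_deng(
        network, labels,
        McmcConfig(
            n_iter=config.n_iter, burn_in=config.burn_in,
            seed=int(rng.integers(2**31 - 1)),
        ),
    )
    pen = fit_penalized(build_cases_annotated_only(network, labels))
    archive = np.empty((config.z_init_size + config.n_iter, 3))
    init_rows = _draw_archive(pen, config.z_init_size, rng)
    theta_arr = pen.theta.as_array()
    if config.theta_bounds is not None:
        lo, hi = config.theta_bounds
        init_rows = np.clip(init_rows, lo, hi)
        theta_arr = np.clip(theta_arr, lo, hi)
    archive[: config.z_init_size] = init_rows
    n_arch = config.z_init_size
    theta = Theta.from_array(theta_arr)

    state = (labels == POS).astype(np.int8)
    state[unknown] = (rng.random(unknown.size) < base.probabilities).astype(np.int8)
    engine = _GibbsEngine(network, state)

    observed = labels != UNKNOWN
    scope = observed if config.plf_scope == "observed" else None

    acc = np.zeros(network.n_nodes)
    n_kept = 0
    n_proposed = 0
    n_accepted = 0
    theta_samples = np.empty((config.n_iter - config.burn_in, 3))
    for t in range(config.n_iter):
        order, probs = engine.sweep(theta, unknown, rng)
        cur_lp = log_plf_from_counts(theta, engine.state, engine.m1, engine.m0, scope)
        cand = demc_propose(theta, archive[:n_arch], config.gamma_step,
                            config.eps_scale, rng)
        n_proposed += 1
        in_support = config.theta_bounds is None or (
            min(cand) >= config.theta_bounds[0] and max(cand) <= config.theta_bounds[1]
        )
        cand_lp = log_plf_from_counts(cand, engine.state, engine.m1, engine.m0, scope)
        if in_support and metropolis_accept(cand_lp, cur_lp, rng):
            theta = cand
            cur_lp = cand_lp
            n_accepted += 1
        archive[n_arch] = theta.as_array()
        n_arch += 1
        if t >= config.burn_in:
            acc[order] += probs
            theta_samples[n_kept] = theta.as_array()
            n_kept += 1
        if (t + 1) % 100 == 0:
            logger.debug(
                "bmrf iter %d/%d log-PLF %.2f accept %.3f theta %s",
                t + 1, config.n_iter, cur_lp, n_accepted / n_proposed, theta,
            )
    posterior = acc[unknown] / n_kept
    return PosteriorSummary(
        nodes=[network.nodes[i] for i in unknown],
        probabilities=posterior,
        theta_mean=Theta.from_array(theta_samples.mean(axis=0)),
        theta_sd=Theta.from_array(theta_samples.std(axis=0, ddof=1)),
        acceptance_rate=n_accepted / n_proposed,
        n_proposed=n_proposed,
        n_accepted=n_accepted,
        theta_samples=theta_samples,
        init_fit=pen,
        archive=archive[:n_arch],
    )
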