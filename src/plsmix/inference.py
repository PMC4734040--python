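"""Posterior inference for the infinite mixture of piecewise linear sequences.

Model
-----
Entity profiles ``x_i`` (length M) are assigned to mixture components by a
two-parameter Chinese restaurant process (the Pitman-Yor construction) with
concentration ``alpha`` and discount ``d``.  Component k has a PLS parameter
vector ``mu_k ~ N(0, Sigma_mu)`` (diagonal prior, variances per parameter
class) and a noise precision ``lambda_k ~ Gamma(a, b)`` (shape/rate); given
these,

    x_i | z_i = k  ~  N(C mu_k, lambda_k^{-1} I)

with C the PLS design matrix.  ``mu_k`` is never sampled: every likelihood
evaluation integrates it out analytically (collapsed sampling), which is
exact because the model is linear-Gaussian in ``mu_k``.

The sampler repeats three steps per iteration: Metropolis-Hastings updates
of each ``lambda_k``; a collapsed Gibbs sweep over assignments ``z_i`` with
auxiliary-variable (Neal algorithm-8 style) proposals for new components;
and Metropolis-Hastings updates of the hyper-parameters ``a, b, alpha, d``.
The output is the posterior pairwise co-clustering probability matrix,
averaged over all retained iterations of all chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .segmentation import PLSModel

__all__ = [
    "IMPLSHyperParams",
    "ChainConfig",
    "MixtureState",
    "SimilarityMatrix",
    "TraceSummary",
    "pls_marginal_loglik",
    "posterior_predictive_loglik",
    "pyp_partition_logprob",
    "sample_lambda",
    "gibbs_assignment_sweep",
    "sample_hyperparameters",
    "run_chains",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class IMPLSHyperParams:
    """Hyper-parameters of the mixture prior.

    ``alpha`` and ``d`` govern the Pitman-Yor partition prior; ``a`` and
    ``b`` are the shape and rate of the Gamma prior on component precisions;
    the ``v_*`` entries are the prior variances of the three PLS parameter
    classes (kept large so the parameter prior is effectively flat).
    """

    alpha: float = 100.0
    d: float = 0.001
    a: float = 2.1
    b: float = 0.24
    v_init: float = 100.0
    v_jump: float = 100.0
    v_slope: float = 100.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.d < 1.0):
            raise ValueError("d must lie in [0, 1)")
        for name in ("a", "b", "v_init", "v_jump", "v_slope"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    Defaults follow the tool's standard operating point: 20 chains of
    10 000 iterations with the first 2500 discarded as burn-in.  Proposal
    scales apply to log-scale random walks (logit scale for ``d``).
    ``b_prior`` selects the hyper-prior on the Gamma rate: ``"literal"``
    uses p(b) proportional to b, ``"reciprocal"`` the conventional 1/b.
    """

    n_chains: int = 20
    n_iterations: int = 10_000
    n_skip: int = 2500
    seed: int = 0
    mh_steps_per_update: int = 3
    n_aux: int = 3
    scale_lambda: float = 0.5
    scale_a: float = 0.5
    scale_b: float = 0.5
    scale_alpha: float = 0.5
    scale_d: float = 0.3
    update_hyperparameters: bool = True
    b_prior: str = "literal"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.n_skip < self.n_iterations):
            raise ValueError("n_skip must be smaller than n_iterations")
        if self.n_aux < 1:
            raise ValueError("n_aux must be at least 1")
        if self.b_prior not in ("literal", "reciprocal"):
            raise ValueError("b_prior must be 'literal' or 'reciprocal'")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Posterior pairwise co-clustering probabilities.

    ``values[i, j]`` is the fraction of retained MCMC samples in which
    entities i and j sat in the same mixture component; the diagonal is
    exactly 1.  ``n_retained`` is the total number of retained samples
    across chains (None when the matrix was loaded from a file).
    """

    values: np.ndarray
    n_retained: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        object.__setattr__(self, "values", v)

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]


@dataclass
class TraceSummary:
    """Per-iteration diagnostics: K, alpha, d, a, b per chain, plus MH
    acceptance rates per proposal family."""

    trace: pd.DataFrame
    acceptance_rates: dict[str, float]


def _prior_variance_vector(model: PLSModel, hypers: IMPLSHyperParams) -> np.ndarray:
    return model.prior_variances(hypers.v_init, hypers.v_jump, hypers.v_slope)


def pls_marginal_loglik(
    X: np.ndarray, lam: float, model: PLSModel, hypers: IMPLSHyperParams
) -> float:
    """Log marginal likelihood of a set of profiles under one PLS component.

    Computes ``log integral N(mu; 0, Sigma_mu) prod_j N(x_j; C mu, lam^-1 I)
    d mu`` exactly, via the conjugate Gaussian algebra (an L-dimensional
    Cholesky solve, not the stacked nM-dimensional covariance).
    """
    if not (lam > 0):
        raise ValueError("precision lam must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape
    if n < 1:
        raise ValueError("X must be non-empty")
    if m != model.n_timepoints:
        raise ValueError("profile length does not match the model")
    v = _prior_variance_vector(model, hypers)
    s = X.sum(axis=0)
    ss = float(np.sum(X * X))
    return _marginal_from_stats(n, s, ss, lam, model.C, model.C.T @ model.C, v)


def _marginal_from_stats(
    n: int, s: np.ndarray, ss: float, lam: float,
    C: np.ndarray, CtC: np.ndarray, v: np.ndarray,
) -> float:
    m = C.shape[0]
    A = np.diag(1.0 / v) + (lam * n) * CtC
    La = np.linalg.cholesky(A)
    rhs = lam * (C.T @ s)
    w = np.linalg.solve(La, rhs)
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(La))))
    return (
        0.5 * n * m * (np.log(lam) - _LOG_2PI)
        - 0.5 * lam * ss
        - 0.5 * float(np.sum(np.log(v)))
        - 0.5 * logdet_A
        + 0.5 * float(w @ w)
    )


def posterior_predictive_loglik(
    x: np.ndarray,
    X_k: np.ndarray | None,
    lam_k: float,
    model: PLSModel,
    hypers: IMPLSHyperParams,
) -> float:
    """Predictive log density of profile ``x`` given a component's members.

    With posterior ``mu | X_k ~ N(m_k, S_k)`` where
    ``S_k = (Sigma_mu^-1 + lam n C'C)^-1`` and
    ``m_k = lam S_k C' sum(X_k)``, the predictive is
    ``N(x; C m_k, C S_k C' + lam^-1 I)``.  An empty ``X_k`` gives the
    prior predictive ``N(x; 0, C Sigma_mu C' + lam^-1 I)``.
    """
    if not (lam_k > 0):
        raise ValueError("precision lam_k must be positive")
    x = np.asarray(x, dtype=float)
    C = model.C
    v = _prior_variance_vector(model, hypers)
    if X_k is None or np.size(X_k) == 0:
        n, s = 0, np.zeros(C.shape[0])
    else:
        X_k = np.atleast_2d(np.asarray(X_k, dtype=float))
        n, s = X_k.shape[0], X_k.sum(axis=0)
    A = np.diag(1.0 / v) + (lam_k * n) * (C.T @ C)
    S = np.linalg.inv(A)
    mean = lam_k * (C @ (S @ (C.T @ s)))
    cov = C @ S @ C.T + np.eye(C.shape[0]) / lam_k
    L = np.linalg.cholesky(cov)
    w = np.linalg.solve(L, x - mean)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (x.size * _LOG_2PI + logdet + float(w @ w))


def pls_posterior_mean(
    X_k: np.ndarray, lam_k: float, model: PLSModel, hypers: IMPLSHyperParams
) -> np.ndarray:
    """Posterior mean profile ``C m_k`` of a component given its members."""
    X_k = np.atleast_2d(np.asarray(X_k, dtype=float))
    C = model.C
    v = _prior_variance_vector(model, hypers)
    A = np.diag(1.0 / v) + (lam_k * X_k.shape[0]) * (C.T @ C)
    return lam_k * (C @ np.linalg.solve(A, C.T @ X_k.sum(axis=0)))


def pyp_partition_logprob(partition, alpha: float, d: float) -> float:
    """Exchangeable partition log-probability under the two-parameter CRP.

    ``partition`` is a label vector with one cluster label per entity.
    For K clusters of sizes n_k over N entities:

        log p = sum_{j=1}^{K-1} log(alpha + j d)
              + sum_k [lgamma(n_k - d) - lgamma(1 - d)]
              - [lgamma(alpha + N) - lgamma(alpha + 1)]
    """
    if not (alpha > 0):
        raise ValueError("alpha must be positive")
    if not (0.0 <= d < 1.0):
        raise ValueError("d must lie in [0, 1)")
    arr = np.asarray(partition)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("partition must be a non-empty 1-D label vector")
    _, counts = np.unique(arr, return_counts=True)
    return _eppf_from_sizes(counts, alpha, d)


def _eppf_from_sizes(sizes: np.ndarray, alpha: float, d: float) -> float:
    sizes = np.asarray(sizes, dtype=float)
    n_total = float(np.sum(sizes))
    k = sizes.size
    out = float(np.sum(gammaln(sizes - d))) - k * float(gammaln(1.0 - d))
    if k > 1:
        out += float(np.sum(np.log(alpha + d * np.arange(1, k))))
    out -= float(gammaln(alpha + n_total) - gammaln(alpha + 1.0))
    return out


# ---------------------------------------------------------------------------
# Mixture state and the internal fast paths


class MixtureState:
    """Current sampler state: data, partition, precisions, hyper-parameters.

    Each non-empty component carries its member set, sufficient statistics
    (count, profile sum, squared norm) and precision ``lambda``.  Posterior
    predictive quantities per component are cached and invalidated when the
    component's membership or precision changes.
    """

    def __init__(
        self,
        X: np.ndarray,
        model: PLSModel,
        hypers: IMPLSHyperParams,
        assignments: np.ndarray | None = None,
        lam: np.ndarray | None = None,
    ) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != model.n_timepoints:
            raise ValueError("data width does not match the model")
        self.X = X
        self.model = model
        self.hypers = hypers
        self.C = model.C
        self.CtC = model.C.T @ model.C
        self._sqnorms = np.einsum("ij,ij->i", X, X)
        self._refresh_prior()
        n = X.shape[0]
        if assignments is None:
            assignments = np.zeros(n, dtype=int)
        assignments = np.asarray(assignments, dtype=int)
        labels = list(dict.fromkeys(assignments.tolist()))
        if lam is None:
            lam = np.ones(len(labels))
        lam = np.asarray(lam, dtype=float)
        if lam.size != len(labels):
            raise ValueError("need exactly one precision per non-empty cluster")
        if np.any(lam <= 0):
            raise ValueError("precisions must be positive")
        self._next_cid = 0
        self.clusters: dict[int, dict] = {}
        self._assign = np.empty(n, dtype=int)
        for label, lam_k in zip(labels, lam):
            idx = np.flatnonzero(assignments == label)
            cid = self._new_cluster(float(lam_k))
            for i in idx:
                self._add_member(cid, int(i))

    # -- prior-dependent precomputation (redone when v_* change; they do not
    #    change during sampling, but hypers objects are replaced wholesale)
    def _refresh_prior(self) -> None:
        v = _prior_variance_vector(self.model, self.hypers)
        self._v = v
        self._A0 = np.diag(1.0 / v)
        B = self.C @ (v[:, None] * self.C.T)
        e, Q = np.linalg.eigh(B)
        self._eigB = np.clip(e, 0.0, None)
        self._qX = self.X @ Q

    # -- cluster bookkeeping
    def _new_cluster(self, lam: float) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.clusters[cid] = {
            "members": set(),
            "n": 0,
            "s": np.zeros(self.X.shape[1]),
            "ss": 0.0,
            "lam": lam,
            "cache": None,
        }
        return cid

    def _add_member(self, cid: int, i: int) -> None:
        c = self.clusters[cid]
        c["members"].add(i)
        c["n"] += 1
        c["s"] = c["s"] + self.X[i]
        c["ss"] += float(self._sqnorms[i])
        c["cache"] = None
        self._assign[i] = cid

    def _remove_member(self, cid: int, i: int) -> None:
        c = self.clusters[cid]
        c["members"].discard(i)
        c["n"] -= 1
        if c["n"] == 0:
            del self.clusters[cid]
        else:
            c["s"] = c["s"] - self.X[i]
            c["ss"] -= float(self._sqnorms[i])
            c["cache"] = None

    # -- public views
    @property
    def n_entities(self) -> int:
        return self.X.shape[0]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def assignments(self) -> np.ndarray:
        """Cluster labels per entity, compacted to 0..K-1 by first appearance."""
        remap: dict[int, int] = {}
        out = np.empty(self.n_entities, dtype=int)
        for i, cid in enumerate(self._assign):
            out[i] = remap.setdefault(int(cid), len(remap))
        return out

    @property
    def lam(self) -> np.ndarray:
        """Precisions ordered to match :attr:`assignments` labels."""
        order: dict[int, float] = {}
        for cid in self._assign:
            cid = int(cid)
            if cid not in order:
                order[cid] = self.clusters[cid]["lam"]
        return np.array(list(order.values()))

    def cluster_sizes(self) -> np.ndarray:
        return np.array([c["n"] for c in self.clusters.values()], dtype=float)

    # -- fast likelihood paths
    def marginal_loglik(self, cid: int, lam: float | None = None) -> float:
        c = self.clusters[cid]
        lam_k = c["lam"] if lam is None else lam
        return _marginal_from_stats(c["n"], c["s"], c["ss"], lam_k, self.C, self.CtC, self._v)

    def _predictive_cache(self, cid: int) -> tuple[np.ndarray, np.ndarray, float]:
        c = self.clusters[cid]
        if c["cache"] is None:
            lam = c["lam"]
            A = self._A0 + (lam * c["n"]) * self.CtC
            S = np.linalg.inv(A)
            mean = lam * (self.C @ (S @ (self.C.T @ c["s"])))
            cov = self.C @ S @ self.C.T + np.eye(self.C.shape[0]) / lam
            sign, logdet = np.linalg.slogdet(cov)
            c["cache"] = (mean, np.linalg.inv(cov), float(logdet))
        return c["cache"]

    def predictive_loglik(self, cid: int, i: int) -> float:
        mean, inv_cov, logdet = self._predictive_cache(cid)
        r = self.X[i] - mean
        return -0.5 * (r.size * _LOG_2PI + logdet + float(r @ (inv_cov @ r)))

    def empty_predictive_loglik(self, i: int, lam) -> np.ndarray | float:
        """Prior predictive of entity i for a fresh component.

        ``lam`` may be a scalar precision or an array of candidate
        precisions (the auxiliary-variable weights are needed in batch).
        """
        lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
        denom = self._eigB[None, :] + 1.0 / lam_arr[:, None]
        q2 = self._qX[i] ** 2
        out = -0.5 * (
            self._qX.shape[1] * _LOG_2PI
            + np.log(denom).sum(axis=1)
            + (q2[None, :] / denom).sum(axis=1)
        )
        return out if np.ndim(lam) else float(out[0])


# ---------------------------------------------------------------------------
# MCMC steps


def _log_gamma_density_unnorm(lam: float, a: float, b: float) -> float:
    return (a - 1.0) * np.log(lam) - b * lam


def sample_lambda(
    state: MixtureState, cid: int, config: ChainConfig, rng: np.random.Generator,
    _accept: list | None = None,
) -> float:
    """Metropolis-Hastings update of one component precision.

    Runs ``mh_steps_per_update`` log-normal random-walk steps targeting
    Gamma(lambda; a, b) times the collapsed likelihood of the component's
    members; the log-scale proposal contributes a Jacobian factor
    lambda'/lambda to the acceptance ratio.  The final value is stored in
    the state and returned.
    """
    c = state.clusters[cid]
    a, b = state.hypers.a, state.hypers.b
    lam = c["lam"]
    lt = _log_gamma_density_unnorm(lam, a, b) + state.marginal_loglik(cid, lam)
    for _ in range(config.mh_steps_per_update):
        lam_new = lam * np.exp(config.scale_lambda * rng.standard_normal())
        lt_new = _log_gamma_density_unnorm(lam_new, a, b) + state.marginal_loglik(cid, lam_new)
        accepted = np.log(rng.uniform()) < lt_new - lt + np.log(lam_new / lam)
        if accepted:
            lam, lt = lam_new, lt_new
        if _accept is not None:
            _accept.append(bool(accepted))
    if lam != c["lam"]:
        c["lam"] = float(lam)
        c["cache"] = None
    return float(lam)


def gibbs_assignment_sweep(
    state: MixtureState, config: ChainConfig, rng: np.random.Generator
) -> None:
    """One collapsed Gibbs sweep over all entity assignments (in place).

    For each entity in index order the entity is removed from its component
    and reassigned among existing components (weight ``(n_k - d)`` times the
    posterior predictive) and a new component (weight ``(alpha + d K) /
    n_aux`` times the prior predictive, averaged over ``n_aux`` fresh
    auxiliary precisions drawn from the Gamma prior).  Weights are handled
    in log space.
    """
    hy = state.hypers
    alpha, d, a, b = hy.alpha, hy.d, hy.a, hy.b
    n_aux = config.n_aux
    for i in range(state.n_entities):
        state._remove_member(int(state._assign[i]), i)
        cids = list(state.clusters.keys())
        k = len(cids)
        logw = np.empty(k + 1)
        for j, cid in enumerate(cids):
            logw[j] = np.log(state.clusters[cid]["n"] - d) + state.predictive_loglik(cid, i)
        lam_aux = rng.gamma(a, 1.0 / b, size=n_aux)
        aux_ll = state.empty_predictive_loglik(i, lam_aux)
        aux_max = aux_ll.max()
        aux_w = np.exp(aux_ll - aux_max)
        logw[k] = np.log(alpha + d * k) - np.log(n_aux) + aux_max + np.log(aux_w.sum())
        w = np.exp(logw - logw.max())
        cdf = np.cumsum(w)
        choice = int(np.searchsorted(cdf, rng.uniform() * cdf[-1], side="right"))
        choice = min(choice, k)
        if choice < k:
            state._add_member(cids[choice], i)
        else:
            aux_cdf = np.cumsum(aux_w)
            u = int(np.searchsorted(aux_cdf, rng.uniform() * aux_cdf[-1], side="right"))
            u = min(u, n_aux - 1)
            cid = state._new_cluster(float(lam_aux[u]))
            state._add_member(cid, i)


def _mh_log_scale(
    value: float, log_target, scale: float, steps: int,
    rng: np.random.Generator, accept: list,
) -> float:
    lt = log_target(value)
    for _ in range(steps):
        new = value * np.exp(scale * rng.standard_normal())
        with np.errstate(invalid="ignore", over="ignore"):
            lt_new = log_target(new)
        if not np.isfinite(lt_new):
            accept.append(False)
            continue
        ok = np.log(rng.uniform()) < lt_new - lt + np.log(new / value)
        if ok:
            value, lt = new, lt_new
        accept.append(bool(ok))
    return value


def sample_hyperparameters(
    state: MixtureState, config: ChainConfig, rng: np.random.Generator,
    _accept: dict | None = None,
) -> IMPLSHyperParams:
    """Metropolis-Hastings updates of (a, b) and (alpha, d).

    The Gamma hyper-parameters target their non-informative priors
    (p(a) = 1 and, per the ``b_prior`` setting, p(b) proportional to b or
    1/b) times the Gamma likelihood of the current precisions.  The
    partition hyper-parameters target p(alpha) = 1/alpha, p(d) = 1/d times
    the Pitman-Yor partition probability; alpha moves on the log scale, d
    on the logit scale (with the matching Jacobians).  The updated
    hyper-parameters are stored in the state and returned.
    """
    acc = _accept if _accept is not None else {"a": [], "b": [], "alpha": [], "d": []}
    lams = np.array([c["lam"] for c in state.clusters.values()])
    k = lams.size
    sum_log_lam = float(np.sum(np.log(lams)))
    sum_lam = float(np.sum(lams))
    sizes = state.cluster_sizes()
    hy = state.hypers
    b = hy.b

    def lt_a(a: float) -> float:
        return k * (a * np.log(b) - gammaln(a)) + (a - 1.0) * sum_log_lam

    a = _mh_log_scale(hy.a, lt_a, config.scale_a, config.mh_steps_per_update, rng, acc["a"])

    b_prior_sign = 1.0 if config.b_prior == "literal" else -1.0

    def lt_b(bb: float) -> float:
        return b_prior_sign * np.log(bb) + k * a * np.log(bb) - bb * sum_lam

    b = _mh_log_scale(hy.b, lt_b, config.scale_b, config.mh_steps_per_update, rng, acc["b"])

    def lt_alpha(al: float) -> float:
        return -np.log(al) + _eppf_from_sizes(sizes, al, d_cur)

    d_cur = hy.d
    alpha = _mh_log_scale(
        hy.alpha, lt_alpha, config.scale_alpha, config.mh_steps_per_update, rng, acc["alpha"]
    )

    d = d_cur
    lt_d = -np.log(d) + _eppf_from_sizes(sizes, alpha, d)
    for _ in range(config.mh_steps_per_update):
        logit = np.log(d) - np.log1p(-d) + config.scale_d * rng.standard_normal()
        d_new = 1.0 / (1.0 + np.exp(-logit))
        if not (0.0 < d_new < 1.0):
            acc["d"].append(False)
            continue
        lt_new = -np.log(d_new) + _eppf_from_sizes(sizes, alpha, d_new)
        jac = np.log(d_new * (1.0 - d_new)) - np.log(d * (1.0 - d))
        ok = np.log(rng.uniform()) < lt_new - lt_d + jac
        if ok:
            d, lt_d = d_new, lt_new
        acc["d"].append(bool(ok))

    state.hypers = replace(hy, a=float(a), b=float(b), alpha=float(alpha), d=float(d))
    return state.hypers


def run_chains(
    X_or_dataset,
    model: PLSModel,
    config: ChainConfig,
    init: IMPLSHyperParams | None = None,
) -> tuple[SimilarityMatrix, TraceSummary]:
    """Run independent MCMC chains and average co-clustering indicators.

    Each chain starts from a single all-inclusive component with a
    precision drawn from its Gamma prior, and is driven by a generator
    seeded deterministically from ``config.seed`` and the chain index, so
    identical configurations reproduce identical output.  Iterations with
    index strictly greater than ``n_skip`` contribute to the similarity
    counts; all chains are weighted equally.
    """
    if init is None:
        init = IMPLSHyperParams()
    X = getattr(X_or_dataset, "values", X_or_dataset)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    rows: list[tuple] = []
    accept: dict[str, list] = {"lambda": [], "a": [], "b": [], "alpha": [], "d": []}
    n_retained = 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, chain]))
        lam0 = rng.gamma(init.a, 1.0 / init.b)
        state = MixtureState(X, model, init, np.zeros(n, dtype=int), np.array([lam0]))
        hyper_acc = {key: accept[key] for key in ("a", "b", "alpha", "d")}
        for it in range(1, config.n_iterations + 1):
            for cid in list(state.clusters.keys()):
                sample_lambda(state, cid, config, rng, _accept=accept["lambda"])
            gibbs_assignment_sweep(state, config, rng)
            if config.update_hyperparameters:
                sample_hyperparameters(state, config, rng, _accept=hyper_acc)
            hy = state.hypers
            rows.append((chain, it, state.n_clusters, hy.alpha, hy.d, hy.a, hy.b))
            if it > config.n_skip:
                n_retained += 1
                for c in state.clusters.values():
                    idx = np.fromiter(c["members"], dtype=int)
                    counts[np.ix_(idx, idx)] += 1
    values = counts / float(n_retained)
    np.fill_diagonal(values, 1.0)
    trace = pd.DataFrame(rows, columns=["chain", "iteration", "K", "alpha", "d", "a", "b"])
    rates = {
        key: (float(np.mean(v)) if v else float("nan")) for key, v in accept.items()
    }
    return SimilarityMatrix(values, n_retained=n_retained), TraceSummary(trace, rates)
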