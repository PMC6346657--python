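"""Genealogy-with-migration state and the structured-coalescent density.

The sampler's state is a rooted, time-calibrated binary genealogy whose
branches carry explicit migration events: each lineage's deme membership is a
piecewise-constant path from the child node up to its parent.  Times are in
mutational units (generations x mu), so the natural parameters are
Theta = N_e * mu per deme and M = m/mu per ordered deme pair.

Rate convention: within a deme of scaled size Theta, an unordered lineage
pair coalesces at rate ``PAIR_RATE / Theta`` (so k lineages coalesce at total
rate k(k-1)/Theta when PAIR_RATE = 2, the migrate-n bookkeeping this package
follows).  A lineage in deme a jumps (backward in time) to deme b at rate
Lambda[a, b] = M for the pair's rate group.  Because the convention is a
single constant, truth comparisons must use the same constant end to end:
``effective_migrants`` converts (Theta, M) to N_e m as Theta*M/PAIR_RATE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from numba import njit
from scipy.spatial.distance import squareform
from scipy.special import gammaln


@njit(cache=True)
def _sim_prior_tree(tip_demes, theta, lam, seed):
    """Genealogy (parent links, node times, node demes) drawn from the
    structured coalescent at fixed (theta, lam), migration paths discarded.

    Used for iid sampling of the prior-predictive expected log likelihood:
    the substitution likelihood depends only on the tree, so the migration
    histories never need to be stored.
    """
    np.random.seed(seed)
    n = tip_demes.shape[0]
    K = theta.shape[0]
    out = np.zeros(K)
    for a in range(K):
        for b in range(K):
            out[a] += lam[a, b]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    deme = np.zeros(n_nodes, dtype=np.int64)
    for i in range(n):
        deme[i] = tip_demes[i]
    active = np.empty(n_nodes, dtype=np.int64)
    lin_deme = np.empty(n_nodes, dtype=np.int64)
    k = np.zeros(K)
    for i in range(n):
        active[i] = i
        lin_deme[i] = tip_demes[i]
        k[tip_demes[i]] += 1.0
    n_active = n
    next_node = n
    t = 0.0
    while n_active > 1:
        coal_total = 0.0
        mig_total = 0.0
        for d in range(K):
            coal_total += k[d] * (k[d] - 1.0) / theta[d]
            mig_total += k[d] * out[d]
        total = coal_total + mig_total
        t += -math.log(np.random.random()) / total
        u = np.random.random() * total
        if u < coal_total:
            acc = 0.0
            dd = K - 1
            for d in range(K):
                acc += k[d] * (k[d] - 1.0) / theta[d]
                if u < acc:
                    dd = d
                    break
            kd = int(k[dd])
            r1 = int(np.random.random() * kd)
            r2 = int(np.random.random() * (kd - 1))
            if r2 >= r1:
                r2 += 1
            # map within-deme ranks to positions in the active array
            pos1 = -1
            pos2 = -1
            seen = 0
            for p in range(n_active):
                if lin_deme[p] == dd:
                    if seen == r1:
                        pos1 = p
                    if seen == r2:
                        pos2 = p
                    seen += 1
            a_node = active[pos1]
            b_node = active[pos2]
            parent[a_node] = next_node
            parent[b_node] = next_node
            times[next_node] = t
            deme[next_node] = dd
            lo = pos1 if pos1 < pos2 else pos2
            hi = pos2 if pos1 < pos2 else pos1
            active[lo] = next_node
            lin_deme[lo] = dd
            if hi != n_active - 1:
                active[hi] = active[n_active - 1]
                lin_deme[hi] = lin_deme[n_active - 1]
            n_active -= 1
            next_node += 1
            k[dd] -= 1.0
        else:
            u -= coal_total
            acc = 0.0
            dd = K - 1
            for d in range(K):
                acc += k[d] * out[d]
                if u < acc:
                    dd = d
                    break
            r = int(np.random.random() * k[dd])
            pos = -1
            seen = 0
            for p in range(n_active):
                if lin_deme[p] == dd:
                    if seen == r:
                        pos = p
                        break
                    seen += 1
            u2 = np.random.random() * out[dd]
            acc2 = 0.0
            dst = K - 1
            for b in range(K):
                acc2 += lam[dd, b]
                if u2 < acc2:
                    dst = b
                    break
            lin_deme[pos] = dst
            k[dd] -= 1.0
            k[dst] += 1.0
    return parent, times, deme


class _TreeShim:
    """Minimal tree view (time/children/root) for the pruning likelihood."""

    __slots__ = ("time", "children", "parent", "n_tips")

    def __init__(self, parent, times, n_tips):
        self.parent = parent
        self.time = times
        self.n_tips = n_tips
        n_nodes = 2 * n_tips - 1
        self.children = np.full((n_nodes, 2), -1, dtype=np.int64)
        fill = np.zeros(n_nodes, dtype=np.int64)
        for v in range(n_nodes - 1):
            p = parent[v]
            if p >= 0:
                self.children[p, fill[p]] = v
                fill[p] += 1

    @property
    def root(self):
        return int(np.flatnonzero(self.parent == -1)[0])


@njit(cache=True)
def _sim_kingman_tree(n, pair_rate, seed):
    """Unstructured coalescent: exponential epochs, uniform pair merges."""
    np.random.seed(seed)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    active = np.arange(n)
    n_active = n
    next_node = n
    t = 0.0
    while n_active > 1:
        rate = 0.5 * n_active * (n_active - 1) * pair_rate
        t += -math.log(np.random.random()) / rate
        i = int(np.random.random() * n_active)
        j = int(np.random.random() * (n_active - 1))
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = next_node
        parent[b] = next_node
        times[next_node] = t
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = next_node
        if hi != n_active - 1:
            active[hi] = active[n_active - 1]
        n_active -= 1
        next_node += 1
    return parent, times


def _migration_stationary(lam: np.ndarray) -> np.ndarray:
    q = lam - np.diag(lam.sum(axis=1))
    vals, vecs = np.linalg.eig(q.T)
    idx = int(np.argmin(np.abs(vals)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_prior_predictive_loglik(
    codes: np.ndarray,
    tip_demes: np.ndarray,
    model: ModelSpec,
    priors: Priors,
    subst,
    n_draws: int,
    rng: np.random.Generator,
):
    """iid draws of log L(data | G) with (params, G) from the joint prior.

    This is the exact target of an infinitely hot power-posterior chain
    (beta -> 0) and anchors the path-sampling integral without any MCMC:
    parameters are drawn by inverse CDF and genealogies by direct
    structured-coalescent simulation.  Returns (loglik draws, theta draws,
    M draws).
    """
    from .likelihood import TreeLikelihood

    n = codes.shape[0]
    lik = TreeLikelihood(codes, subst)
    lls = np.empty(n_draws)
    th_draws = np.empty((n_draws, model.n_theta_groups))
    m_draws = np.empty((n_draws, model.n_mig_groups))
    seeds = rng.integers(0, 2**31 - 1, size=n_draws)
    mapped = model.map_demes(tip_demes)
    for i in range(n_draws):
        th = priors.theta.sample(rng, model.n_theta_groups)
        mm = priors.M.sample(rng, model.n_mig_groups) if model.n_mig_groups \
            else np.empty(0)
        th_draws[i] = th
        m_draws[i] = mm
        theta_d = model.theta_by_deme(th)
        lam = model.migration_matrix(mm)
        # In the strong-migration regime (migration much faster than
        # coalescence) the structured coalescent collapses to a Kingman
        # coalescent with pair rate sum_i pi_i^2 * PAIR_RATE/Theta_i, pi the
        # migration chain's stationary distribution; the event-level
        # simulation would spend millions of jumps to produce the same tree
        # law, so switch to the limit when the separation exceeds 1e3.
        if model.K > 1 and lam.sum(axis=1).min() * theta_d.min() > 500 * PAIR_RATE:
            pi = _migration_stationary(lam)
            pair_rate = float((pi**2 * PAIR_RATE / theta_d).sum())
            parent, times = _sim_kingman_tree(n, pair_rate, int(seeds[i]))
        else:
            parent, times, _ = _sim_prior_tree(mapped, theta_d, lam, seeds[i])
        lls[i] = lik.full_recompute(_TreeShim(parent, times, n))
    return lls, th_draws, m_draws


@njit(cache=True)
def _bridge_states(R, pows, a, b, n, us):
    """Jump-state skeleton of a uniformized bridge from a to b in n steps."""
    K = R.shape[0]
    states = np.empty(n + 1, dtype=np.int64)
    states[0] = a
    states[n] = b
    for k in range(1, n):
        total = 0.0
        prev = states[k - 1]
        for j in range(K):
            total += R[prev, j] * pows[n - k, j, b]
        u = us[k - 1] * total
        acc = 0.0
        s = K - 1
        for j in range(K):
            acc += R[prev, j] * pows[n - k, j, b]
            if u < acc:
                s = j
                break
        states[k] = s
    return states


@njit(cache=True)
def _sweep_events(times, is_coal, d1, d2, k0, A, B):
    """Timeline sweep over sorted events; accumulates the occupancy
    integrals A_i = int k_i(k_i-1) dt and B_i = int k_i dt.  Returns 0 on an
    inconsistent history (coalescence without two lineages present)."""
    K = k0.shape[0]
    k = k0.copy()
    t_prev = 0.0
    for e in range(times.shape[0]):
        dt = times[e] - t_prev
        t_prev = times[e]
        for i in range(K):
            A[i] += k[i] * (k[i] - 1.0) * dt
            B[i] += k[i] * dt
        if is_coal[e]:
            d = d1[e]
            if k[d] < 2.0:
                return 0
            k[d] -= 1.0
        else:
            k[d1[e]] -= 1.0
            k[d2[e]] += 1.0
            if k[d1[e]] < 0.0:
                return 0
    return 1

from .model import ModelSpec, Priors

#: numerator of the per-pair coalescence rate in mutational time (k(k-1)/Theta
#: total).  Changing this single constant switches to the 1/Theta convention.
PAIR_RATE = 2.0

_EMPTY_F = np.empty(0)
_EMPTY_I = np.empty(0, dtype=np.int64)


def effective_migrants(theta: float, M: float) -> float:
    """N_e m implied by (Theta, M) under the package's rate convention."""
    return theta * M / PAIR_RATE


# ---------------------------------------------------------------------------
# endpoint-conditioned migration paths (uniformization)
# ---------------------------------------------------------------------------

class MigrationKernel:
    """Endpoint-conditioned simulation and density of the deme process.

    Built from a K x K backward migration rate matrix Lambda; uses
    uniformization: with Omega >= max total exit rate and R = I + Lambda/Omega,
    the number of (virtual) jumps on a branch of length tau is Poisson(Omega
    tau) tilted by R^n[a, b], and jump states follow a discrete bridge.
    Powers of R are cached and grown on demand.
    """

    def __init__(self, lam: np.ndarray):
        self.lam = np.asarray(lam, dtype=float)
        self.K = self.lam.shape[0]
        self.out = self.lam.sum(axis=1)
        self.omega = float(self.out.max()) * 1.05 if self.out.max() > 0 else 0.0
        if self.omega > 0:
            self.R = np.eye(self.K) + (self.lam - np.diag(self.out)) / self.omega
        else:
            self.R = np.eye(self.K)
        self._pow = np.eye(self.K)[None, :, :]  # stacked R^0..R^n

    def _powers_upto(self, n: int) -> np.ndarray:
        while self._pow.shape[0] <= n:
            grow = min(max(self._pow.shape[0], 16), 4096)
            block = np.empty((grow, self.K, self.K))
            prev = self._pow[-1]
            for i in range(grow):
                prev = prev @ self.R
                block[i] = prev
            self._pow = np.concatenate([self._pow, block], axis=0)
        return self._pow

    def _n_weights(self, a: int, b: int, tau: float):
        """Poisson-tilted weights over jump counts; their sum is P_ab(tau)."""
        lam_t = self.omega * tau
        n_max = int(lam_t + 7.0 * math.sqrt(lam_t + 10.0)) + 8
        ns = np.arange(n_max + 1)
        log_pmf = -lam_t + ns * math.log(lam_t) - gammaln(ns + 1.0) if lam_t > 0 \
            else np.where(ns == 0, 0.0, -np.inf)
        pows = self._powers_upto(n_max)
        return np.exp(log_pmf) * pows[: n_max + 1, a, b]

    def trans_logprob(self, a: int, b: int, tau: float) -> float:
        if self.omega == 0.0:
            return 0.0 if a == b else -np.inf
        total = self._n_weights(a, b, tau).sum()
        return math.log(total) if total > 0 else -np.inf

    def sample_path(self, a: int, b: int, tau: float, rng: np.random.Generator):
        """Sample (times, demes) of true jumps on (0, tau), conditioned on
        starting in a and ending in b.  Returns None if a->b is impossible."""
        res = self.sample_path_with_density(a, b, tau, rng)
        return None if res is None else res[:2]

    def sample_path_with_density(self, a: int, b: int, tau: float,
                                 rng: np.random.Generator):
        """Sample a conditioned path and return (times, demes, log q)."""
        if self.omega == 0.0:
            if a != b:
                return None
            return np.empty(0), np.empty(0, dtype=np.int64), 0.0
        w = self._n_weights(a, b, tau)
        total = w.sum()
        if total <= 0:
            return None
        cum = np.cumsum(w)
        n = int(np.searchsorted(cum, rng.random() * total))
        states = _bridge_states(
            self.R, self._pow, a, b, n, rng.random(max(n - 1, 0))
        )
        times = np.sort(rng.random(n)) * tau
        keep = np.flatnonzero(states[1:] != states[:-1])
        times = times[keep]
        demes = states[keep + 1]
        logq = self.path_log_density(a, tau, times, demes) - math.log(total)
        return times, demes, logq

    def path_log_density(self, a: int, tau: float, times, demes) -> float:
        """Unconditional CTMC density of a concrete jump path starting in a."""
        if len(times) == 0:
            return -self.out[a] * tau
        src = np.empty(len(demes), dtype=np.int64)
        src[0] = a
        src[1:] = demes[:-1]
        rates = self.lam[src, demes]
        if np.any(rates <= 0):
            return -np.inf
        dts = np.diff(np.concatenate(([0.0], np.asarray(times), [tau])))
        occ = np.concatenate((src, demes[-1:]))
        return float(np.log(rates).sum() - (self.out[occ] * dts).sum())

    def conditioned_log_density(self, a: int, b: int, tau: float, times, demes) -> float:
        """log q of a path under the endpoint-conditioned proposal."""
        return self.path_log_density(a, tau, times, demes) - self.trans_logprob(a, b, tau)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class GenealogyState:
    """Mutable sampler state: tree, migration paths, parameters.

    Node indexing: 0..n_tips-1 tips (time 0), internal nodes follow; the root
    is whichever node has parent -1 (topology moves can relocate it).  For
    every non-root node, ``path_times[node]`` / ``path_demes[node]`` hold the
    migration jumps on the branch from the node (child end, at
    ``node_deme[node]``) up to its parent; after the last jump the lineage
    must sit in ``node_deme[parent]``.
    """

    model: ModelSpec
    priors: Priors
    n_tips: int
    time: np.ndarray                    # (2n-1,) mutational units
    parent: np.ndarray                  # (2n-1,)
    children: np.ndarray                # (2n-1, 2); rows for tips unused (-1)
    node_deme: np.ndarray               # (2n-1,)
    path_times: list = field(default_factory=list)
    path_demes: list = field(default_factory=list)
    theta_groups: np.ndarray = None
    m_groups: np.ndarray = None

    def __post_init__(self):
        self._kernel = None
        self._kernel_key = None
        # derived per-branch arrays kept in sync by set_path()
        n_nodes = self.n_nodes
        self.path_abs = [None] * n_nodes
        self.path_src = [None] * n_nodes
        self.end_deme = self.node_deme.copy()
        self.mig_nodes = set()
        if len(self.path_times) == n_nodes:
            for node in range(n_nodes):
                self._derive_path(node)

    def _derive_path(self, node: int) -> None:
        pt = self.path_times[node]
        pd_ = self.path_demes[node]
        if len(pt):
            self.path_abs[node] = self.time[node] + pt
            src = np.empty(len(pd_), dtype=np.int64)
            src[0] = self.node_deme[node]
            src[1:] = pd_[:-1]
            self.path_src[node] = src
            self.end_deme[node] = pd_[-1]
            self.mig_nodes.add(node)
        else:
            self.path_abs[node] = _EMPTY_F
            self.path_src[node] = _EMPTY_I
            self.end_deme[node] = self.node_deme[node]
            self.mig_nodes.discard(node)

    def set_path(self, node: int, times: np.ndarray, demes: np.ndarray) -> None:
        """Install a migration path on ``node``'s branch and refresh the
        derived bookkeeping (absolute times, jump sources, end deme)."""
        self.path_times[node] = times
        self.path_demes[node] = demes
        self._derive_path(node)

    def scale_times(self, factor: float):
        """Multiply all node heights and migration event times by ``factor``
        (deme structure untouched).  Returns an undo blob for :meth:`unscale`."""
        n = self.n_tips
        undo = (self.time, list(self.path_times), list(self.path_abs))
        self.time = self.time.copy()
        self.time[n:] *= factor
        for v in range(self.n_nodes):
            if len(self.path_times[v]):
                self.path_times[v] = self.path_times[v] * factor
                self.path_abs[v] = self.time[v] + self.path_times[v]
        return undo

    def unscale(self, undo) -> None:
        self.time, self.path_times, self.path_abs = undo
        self.path_times = list(self.path_times)
        self.path_abs = list(self.path_abs)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def theta_by_deme(self) -> np.ndarray:
        return self.model.theta_by_deme(self.theta_groups)

    def migration_matrix(self) -> np.ndarray:
        return self.model.migration_matrix(self.m_groups)

    def kernel(self) -> MigrationKernel:
        key = tuple(self.m_groups) if self.m_groups is not None else ()
        if self._kernel is None or key != self._kernel_key:
            self._kernel = MigrationKernel(self.migration_matrix())
            self._kernel_key = key
        return self._kernel

    def branch_length(self, node: int) -> float:
        return float(self.time[self.parent[node]] - self.time[node])

    def deme_at_branch_time(self, node: int, t: float) -> int:
        """Deme of the lineage above ``node`` at absolute time t
        (time[node] <= t <= time[parent])."""
        rel = t - self.time[node]
        times = self.path_times[node]
        idx = np.searchsorted(times, rel, side="right")
        if idx == 0:
            return int(self.node_deme[node])
        return int(self.path_demes[node][idx - 1])

    def n_branch_events(self, node: int) -> int:
        return len(self.path_times[node])

    def copy(self) -> "GenealogyState":
        st = GenealogyState(
            model=self.model, priors=self.priors, n_tips=self.n_tips,
            time=self.time.copy(), parent=self.parent.copy(),
            children=self.children.copy(), node_deme=self.node_deme.copy(),
            path_times=[p.copy() for p in self.path_times],
            path_demes=[p.copy() for p in self.path_demes],
            theta_groups=self.theta_groups.copy(),
            m_groups=self.m_groups.copy() if self.m_groups is not None else None,
        )
        return st


def structured_coalescent_logdensity(state: GenealogyState) -> float:
    """log density of the genealogy + migration history given (Theta, M).

    Sweeps the event timeline from the tips to the root, accumulating
    exponential waiting-time terms ``-(sum_i k_i(k_i-1)/Theta_i +
    sum_i k_i out_i) dt`` per interval, a factor ``PAIR_RATE/Theta_i`` per
    coalescence, and ``Lambda[a, b]`` per migration jump.  A state whose deme
    labels are inconsistent (a lineage arriving at its parent in the wrong
    deme, or a zero-rate jump) has density -inf.
    """
    stats = coalescent_sufficient_stats(state)
    if stats is None:
        return -np.inf
    return density_from_stats(state.theta_by_deme(), state.migration_matrix(), stats)


@dataclass
class CoalStats:
    """Sufficient statistics of a genealogy+migration history.

    The structured-coalescent log density is linear in these: per-deme
    coalescence counts and pair-time integrals A_i = int k_i(k_i-1) dt,
    per-deme occupancy integrals B_i = int k_i dt, and per-ordered-pair
    migration event counts — so parameter updates need no timeline sweep.
    """

    n_coal: np.ndarray       # (K,)
    n_mig: np.ndarray        # (K, K)
    A: np.ndarray            # (K,)
    B: np.ndarray            # (K,)


def density_from_stats(theta: np.ndarray, lam: np.ndarray, stats: CoalStats) -> float:
    with np.errstate(divide="ignore"):
        log_lam = np.log(lam)
    if np.any(np.isneginf(log_lam[stats.n_mig > 0])):
        return -np.inf
    mig_term = float((stats.n_mig * np.where(stats.n_mig > 0, log_lam, 0.0)).sum())
    coal_term = float((stats.n_coal * np.log(PAIR_RATE / theta)).sum())
    waiting = float(stats.A @ (1.0 / theta) + stats.B @ lam.sum(axis=1))
    return coal_term + mig_term - waiting


def coalescent_sufficient_stats(state: GenealogyState) -> CoalStats | None:
    """One timeline sweep; None when the history is inconsistent
    (a lineage arriving at its parent in the wrong deme, or a coalescence
    with fewer than two lineages present)."""
    K = state.model.K
    n = state.n_tips
    root = state.root
    node_deme = state.node_deme
    nonroot = np.flatnonzero(state.parent >= 0)
    if not np.array_equal(
        state.end_deme[nonroot], node_deme[state.parent[nonroot]]
    ):
        return None

    coal_times = state.time[n:]
    coal_demes = node_deme[n:]
    n_coal_events = n - 1
    mig_nodes = [v for v in state.mig_nodes if v != root]
    if mig_nodes:
        mt = np.concatenate([state.path_abs[v] for v in mig_nodes])
        ms = np.concatenate([state.path_src[v] for v in mig_nodes])
        md = np.concatenate([state.path_demes[v] for v in mig_nodes])
        times = np.concatenate([coal_times, mt])
        d1 = np.concatenate([coal_demes, ms])
        d2 = np.concatenate([np.full(n_coal_events, -1, dtype=np.int64), md])
    else:
        ms = md = _EMPTY_I
        times = coal_times
        d1 = coal_demes
        d2 = np.full(n_coal_events, -1, dtype=np.int64)

    order = np.argsort(times, kind="stable")
    is_coal = order < n_coal_events
    k0 = np.bincount(node_deme[:n], minlength=K).astype(float)
    A = np.zeros(K)
    B = np.zeros(K)
    ok = _sweep_events(
        np.ascontiguousarray(times[order]), is_coal,
        np.ascontiguousarray(d1[order]), np.ascontiguousarray(d2[order]),
        k0, A, B,
    )
    if not ok:
        return None
    n_mig = np.zeros((K, K))
    if len(ms):
        np.add.at(n_mig, (ms, md), 1.0)
    return CoalStats(
        n_coal=np.bincount(coal_demes, minlength=K).astype(float),
        n_mig=n_mig,
        A=A,
        B=B,
    )


def log_param_prior(state: GenealogyState) -> float:
    lp = float(np.sum(state.priors.theta.logpdf(state.theta_groups)))
    if state.m_groups is not None and len(state.m_groups):
        lp += float(np.sum(state.priors.M.logpdf(state.m_groups)))
    return lp


# ---------------------------------------------------------------------------
# simulation from the structured-coalescent prior (also the state initializer)
# ---------------------------------------------------------------------------

def sample_structured_genealogy(
    tip_demes: np.ndarray,
    theta: np.ndarray,
    lam: np.ndarray,
    rng: np.random.Generator,
) -> tuple:
    """Simulate a genealogy with full migration paths under the structured
    coalescent in mutational units.

    Returns (time, parent, children, node_deme, path_times, path_demes) in the
    layout of :class:`GenealogyState`.  Used for chain initialization and as
    the forward-simulation oracle for the density.
    """
    tip_demes = np.asarray(tip_demes, dtype=np.int64)
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    n = len(tip_demes)
    K = len(theta)
    out = lam.sum(axis=1)
    n_nodes = 2 * n - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    node_deme = np.zeros(n_nodes, dtype=np.int64)
    node_deme[:n] = tip_demes
    # per-lineage migration event records (relative times filled at the end)
    ev_times = {i: [] for i in range(n_nodes)}
    ev_demes = {i: [] for i in range(n_nodes)}
    birth = np.zeros(n_nodes)

    lineages = [[] for _ in range(K)]
    for i, d in enumerate(tip_demes):
        lineages[d].append(i)
    n_active = n
    next_node = n
    t = 0.0
    rand = rng.random
    # per-deme pair-rate numerator and migration jump tables
    pair_rate = PAIR_RATE / theta
    lam_cum = np.cumsum(lam, axis=1)
    while n_active > 1:
        coal_w = [len(l) * (len(l) - 1) * 0.5 * pr for l, pr in zip(lineages, pair_rate)]
        mig_w = [len(l) * o for l, o in zip(lineages, out)]
        sum_coal = sum(coal_w)
        total = sum_coal + sum(mig_w)
        t += -math.log(rand()) / total
        u = rand() * total
        if u < sum_coal:
            acc = 0.0
            for d in range(K):
                acc += coal_w[d]
                if u < acc:
                    break
            ld = lineages[d]
            i = int(rand() * len(ld))
            j = int(rand() * (len(ld) - 1))
            if j >= i:
                j += 1
            a, b = ld[i], ld[j]
            if i < j:
                i, j = j, i
            ld[i] = ld[-1]; ld.pop()
            ld[j] = ld[-1]; ld.pop()
            node = next_node
            next_node += 1
            time[node] = t
            birth[node] = t
            node_deme[node] = d
            parent[a] = node
            parent[b] = node
            children[node] = (a, b)
            ld.append(node)
            n_active -= 1
        else:
            u -= sum_coal
            acc = 0.0
            for d in range(K):
                acc += mig_w[d]
                if u < acc:
                    break
            ld = lineages[d]
            i = int(rand() * len(ld))
            node = ld[i]
            ld[i] = ld[-1]
            ld.pop()
            dst = int(np.searchsorted(lam_cum[d], rand() * lam_cum[d, -1], side="right"))
            lineages[dst].append(node)
            ev_times[node].append(t)
            ev_demes[node].append(dst)

    path_times = []
    path_demes = []
    for node in range(n_nodes):
        rel = np.asarray(ev_times[node], dtype=float) - birth[node]
        path_times.append(rel)
        path_demes.append(np.asarray(ev_demes[node], dtype=np.int64))
    return time, parent, children, node_deme, path_times, path_demes


def initial_state(
    aln_codes: np.ndarray,
    tip_demes_original: np.ndarray,
    model: ModelSpec,
    priors: Priors,
    rng: np.random.Generator,
    theta0: float | None = None,
    m0: float | None = None,
    style: str = "upgma",
) -> GenealogyState:
    """Build a starting state.

    ``style="upgma"``: UPGMA tree on pairwise differences, demes by descent,
    endpoint-conditioned migration paths — a data-informed start that
    shortens burn-in for cold chains.  ``style="prior"``: a draw from the
    structured-coalescent prior at the initial parameters — the right
    starting neighborhood for strongly heated chains, whose typical trees
    have nothing to do with the data.  Initial parameter values default to
    the geometric midpoint of each prior window.
    """
    tip_demes = model.map_demes(tip_demes_original)
    n = aln_codes.shape[0]
    L = aln_codes.shape[1]
    th = priors.theta
    pm = priors.M

    # quick moment estimates put the cold chain in the right decade: Theta
    # from within-deme diversity (E[pairwise divergence] = Theta under the
    # pair-rate convention), M from a Wright-style F_ST inversion on the
    # connected deme pairs.  Orders of magnitude matter here — a lattice
    # model started at a migration rate far below the data's cannot climb
    # within a short run because rate and paths must co-adapt.
    diffs = (
        (aln_codes[:, None, :] != aln_codes[None, :, :]).mean(axis=2)
        if L else np.zeros((n, n))
    )
    if theta0 is None or m0 is None:
        same = tip_demes[:, None] == tip_demes[None, :]
        off = ~np.eye(n, dtype=bool)
        pi_within = float(diffs[same & off].mean()) if np.any(same & off) else 0.0
        connected = np.zeros((model.K, model.K), dtype=bool)
        for (a, b) in model.mig_ties:
            connected[a, b] = connected[b, a] = True
        link = connected[tip_demes[:, None], tip_demes[None, :]]
        pi_between = float(diffs[link].mean()) if np.any(link) else pi_within
        if theta0 is None:
            theta0 = float(np.clip(max(pi_within, 1e-12), th.lower, th.upper))
        if m0 is None:
            fst = (pi_between - pi_within) / max(pi_between, 1e-12)
            fst = min(max(fst, 0.02), 0.9)
            nem = (1.0 / fst - 1.0) / 4.0
            m0 = float(np.clip(PAIR_RATE * nem / theta0, pm.lower, pm.upper))
    theta_groups = np.full(model.n_theta_groups, theta0)
    m_groups = np.full(model.n_mig_groups, m0) if model.n_mig_groups else np.empty(0)

    if style == "prior":
        time, parent, children, node_deme, ptimes, pdemes = (
            sample_structured_genealogy(
                tip_demes,
                model.theta_by_deme(theta_groups),
                model.migration_matrix(m_groups),
                rng,
            )
        )
        return GenealogyState(
            model=model, priors=priors, n_tips=n, time=time, parent=parent,
            children=children, node_deme=node_deme,
            path_times=ptimes, path_demes=pdemes,
            theta_groups=theta_groups, m_groups=m_groups,
        )

    # UPGMA on per-site difference proportions; node height = distance / 2
    z = sch.average(squareform(diffs, checks=False))
    n_nodes = 2 * n - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    node_deme = np.zeros(n_nodes, dtype=np.int64)
    node_deme[:n] = tip_demes
    eps = max(0.05 / L, 1e-6) if L else 1e-4
    for j in range(n - 1):
        a, b, dist, _ = z[j]
        a, b = int(a), int(b)
        node = n + j
        h = dist / 2.0
        h = max(h, time[a] + eps, time[b] + eps)
        time[node] = h
        parent[a] = node
        parent[b] = node
        children[node] = (a, b)
        node_deme[node] = node_deme[a]  # deme of first descendant clade

    state = GenealogyState(
        model=model, priors=priors, n_tips=n, time=time, parent=parent,
        children=children, node_deme=node_deme,
        path_times=[np.empty(0) for _ in range(n_nodes)],
        path_demes=[np.empty(0, dtype=np.int64) for _ in range(n_nodes)],
        theta_groups=theta_groups, m_groups=m_groups,
    )
    if model.K > 1:
        kern = state.kernel()
        for node in range(n_nodes):
            p = parent[node]
            if p < 0:
                continue
            res = kern.sample_path(
                int(node_deme[node]), int(node_deme[p]),
                float(time[p] - time[node]), rng,
            )
            if res is None:
                raise RuntimeError("could not initialize a migration path")
            state.set_path(node, *res)
    return state
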