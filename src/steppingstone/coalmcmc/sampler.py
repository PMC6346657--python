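"""Metropolis-coupled MCMC over genealogies with migration histories.

Each chain targets the power posterior

    pi_beta(G, paths, Theta, M)  ∝  L(data | G)^beta
                                    * p(G, paths | Theta, M) * p(Theta) p(M)

with beta = 1/temperature, so the coldest chain (beta = 1) samples the
posterior and a very hot chain samples essentially the prior; the ladder of
per-chain mean log likelihoods feeds the path-sampling evidence estimate.

Move mixture (weights configurable):

* topology — subtree prune-regraft at a fixed attachment height, splicing
  the migration paths of the affected branches and redrawing the pruned
  lineage's path by endpoint-conditioned simulation;
* times — node-height slide (uniform within the bracketing window; an
  exponential tail proposal for the root) with the adjacent paths redrawn;
* migration — redraw one branch's path, or resample one internal node's deme
  together with its adjacent paths;
* parameters — reflected log-scale random walk over every Theta and M group
  (cheap, because the coalescent density is linear in cached sufficient
  statistics of the genealogy).

Every proposal is accepted by a standard Metropolis-Hastings ratio in which
endpoint-conditioned path proposal densities appear explicitly, so detailed
balance holds move by move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..hky import HKYModel
from .likelihood import TreeLikelihood
from .model import MCMCConfig, ModelSpec, Priors
from .state import (
    GenealogyState,
    coalescent_sufficient_stats,
    density_from_stats,
    initial_state,
    log_param_prior,
)

_TINY = 1e-9


def _reflect(y: float, lo: float, hi: float) -> float:
    """Fold y into [lo, hi] by reflection at both boundaries."""
    width = hi - lo
    y = (y - lo) % (2.0 * width)
    return lo + (width - abs(y - width) if y > width else y)


class Chain:
    """One heated chain: state, cached target components, and the move kit."""

    def __init__(self, state: GenealogyState, codes: np.ndarray,
                 subst: HKYModel, beta: float, config: MCMCConfig,
                 rng: np.random.Generator):
        self.state = state
        self.beta = beta
        self.config = config
        self.rng = rng
        self.lik = TreeLikelihood(codes, subst)
        self.loglik = self.lik.full_recompute(state)
        self.stats = coalescent_sufficient_stats(state)
        if self.stats is None:
            raise RuntimeError("initial state has zero coalescent density")
        self.logcoal = density_from_stats(
            state.theta_by_deme(), state.migration_matrix(), self.stats
        )
        self.logprior = log_param_prior(state)
        self.accepts = np.zeros(4, dtype=np.int64)
        self.proposals = np.zeros(4, dtype=np.int64)

    # -- helpers -------------------------------------------------------------
    def _redraw_path(self, node: int, tau_new: float, a: int, b: int):
        """Propose a new path for ``node``'s branch; returns
        (times, demes, logq_new, logq_old) or None on guard rejection."""
        st = self.state
        kern = st.kernel()
        if st.model.K == 1:
            return np.empty(0), np.empty(0, dtype=np.int64), 0.0, 0.0
        if kern.omega * tau_new > self.config.max_expected_jumps:
            return None
        res = kern.sample_path_with_density(a, b, tau_new, self.rng)
        if res is None:
            return None
        times, demes, logq_new = res
        if len(times) > self.config.max_branch_events:
            return None
        tau_old = st.branch_length(node)
        a_old = int(st.node_deme[node])
        b_old = int(st.node_deme[st.parent[node]])
        logq_old = kern.conditioned_log_density(
            a_old, b_old, tau_old, st.path_times[node], st.path_demes[node]
        )
        return times, demes, logq_new, logq_old

    def _try_stats(self) -> tuple[float, object] | None:
        stats = coalescent_sufficient_stats(self.state)
        if stats is None:
            return None
        dens = density_from_stats(
            self.state.theta_by_deme(), self.state.migration_matrix(), stats
        )
        return dens, stats

    def _accept(self, delta: float) -> bool:
        return delta >= 0.0 or self.rng.random() < math.exp(max(delta, -700.0))

    # -- moves ---------------------------------------------------------------
    def move_time(self) -> bool:
        st = self.state
        n = st.n_tips
        v = int(self.rng.integers(n, st.n_nodes))
        c1, c2 = (int(c) for c in st.children[v])
        lo = max(st.time[c1], st.time[c2])
        is_root = st.parent[v] == -1
        hastings = 0.0
        if is_root:
            lam_f = max(st.time[v] - lo, _TINY)
            t_new = lo + self.rng.exponential(lam_f)
            lam_r = max(t_new - lo, _TINY)
            hastings = (
                (-(st.time[v] - lo) / lam_r - math.log(lam_r))
                - (-(t_new - lo) / lam_f - math.log(lam_f))
            )
        else:
            hi = float(st.time[st.parent[v]])
            t_new = lo + self.rng.random() * (hi - lo)
        branches = [c1, c2] + ([] if is_root else [v])
        proposals = {}
        logq = 0.0
        for br in branches:
            if br == v:
                tau_new = float(st.time[st.parent[v]]) - t_new
            else:
                tau_new = t_new - float(st.time[br])
            res = self._redraw_path(
                br, tau_new, int(st.node_deme[br]), int(st.node_deme[st.parent[br]])
            )
            if res is None:
                return False
            times, demes, q_new, q_old = res
            proposals[br] = (times, demes)
            logq += q_old - q_new

        old_time = float(st.time[v])
        old_paths = {br: (st.path_times[br], st.path_demes[br]) for br in branches}
        st.time[v] = t_new
        for br, (times, demes) in proposals.items():
            st.set_path(br, times, demes)
        new = self._try_stats()
        new_ll, undo = self.lik.update(st, [c1, c2])
        if new is not None:
            new_coal, stats = new
            delta = (
                self.beta * (new_ll - self.loglik)
                + (new_coal - self.logcoal) + hastings + logq
            )
            if self._accept(delta):
                self.loglik, self.logcoal, self.stats = new_ll, new_coal, stats
                return True
        st.time[v] = old_time
        for br, (times, demes) in old_paths.items():
            st.set_path(br, times, demes)
        self.lik.restore(undo)
        return False

    def move_scale(self) -> bool:
        """Rescale every node height (and migration event time) by a common
        log-uniform factor.  A deterministic bijection, so the Hastings term
        is the Jacobian: one power of the factor per scaled coordinate.
        Essential for hot chains, whose typical tree heights differ from the
        data-informed start by orders of magnitude."""
        st = self.state
        n = st.n_tips
        c = math.exp(0.5 * (2.0 * self.rng.random() - 1.0))
        n_events = sum(len(st.path_times[v]) for v in range(st.n_nodes)
                       if st.parent[v] != -1)
        scale_undo = st.scale_times(c)
        new = self._try_stats()
        new_ll, undo = self.lik.update(st, list(range(n)))
        if new is not None:
            new_coal, stats = new
            logjac = (n - 1 + n_events) * math.log(c)
            delta = (
                self.beta * (new_ll - self.loglik)
                + (new_coal - self.logcoal) + logjac
            )
            if self._accept(delta):
                self.loglik, self.logcoal, self.stats = new_ll, new_coal, stats
                return True
        st.unscale(scale_undo)
        self.lik.restore(undo)
        return False

    def move_spr(self) -> bool:
        st = self.state
        x = int(self.rng.integers(0, st.n_nodes))
        p = int(st.parent[x])
        if p == -1 or st.parent[p] == -1:
            return False
        g = int(st.parent[p])
        kids = st.children[p]
        s = int(kids[0]) if int(kids[1]) == x else int(kids[1])
        t_p = float(st.time[p])

        # candidate edges after detaching (s inherits p's edge up to g)
        def parent_after_detach(c: int) -> int:
            return g if c == s else int(st.parent[c])

        candidates = []
        for c in range(st.n_nodes):
            if c == x or c == p:
                continue
            pp = parent_after_detach(c)
            if pp == -1 or pp == p:
                continue
            if st.time[c] < t_p < st.time[pp]:
                candidates.append(c)
        if not candidates:
            return False
        c = int(candidates[self.rng.integers(len(candidates))])
        q = parent_after_detach(c)

        # migration path of the detached edge c -> q, and the deme at t_p
        if c == s:
            shift = t_p - float(st.time[s])
            c_times = np.concatenate([st.path_times[s], st.path_times[p] + shift])
            c_demes = np.concatenate([st.path_demes[s], st.path_demes[p]])
        else:
            c_times, c_demes = st.path_times[c], st.path_demes[c]
        rel = t_p - float(st.time[c])
        idx = int(np.searchsorted(c_times, rel, side="right"))
        d_new = int(st.node_deme[c]) if idx == 0 else int(c_demes[idx - 1])

        res = self._redraw_path(x, t_p - float(st.time[x]), int(st.node_deme[x]), d_new)
        if res is None:
            return False
        x_times, x_demes, q_new, q_old = res

        snap = {
            "parent": {y: int(st.parent[y]) for y in (x, s, c, p)},
            "children": {y: st.children[y].copy() for y in (g, p, q)},
            "deme_p": int(st.node_deme[p]),
            "paths": {y: (st.path_times[y], st.path_demes[y]) for y in (s, c, x, p)},
        }

        # detach: s takes over p's slot under g
        st.children[g][st.children[g].tolist().index(p)] = s
        st.parent[s] = g
        # attach p into edge (c, q)
        st.parent[c] = p
        st.children[p][:] = (c, x)
        st.parent[p] = q
        if c == s:
            st.children[g][st.children[g].tolist().index(s)] = p
        else:
            st.children[q][st.children[q].tolist().index(c)] = p
        st.node_deme[p] = d_new
        if c != s:
            shift = t_p - float(st.time[s])
            st.set_path(
                s,
                np.concatenate([snap["paths"][s][0], snap["paths"][p][0] + shift]),
                np.concatenate([snap["paths"][s][1], snap["paths"][p][1]]),
            )
        st.set_path(c, c_times[:idx], c_demes[:idx])
        st.set_path(p, c_times[idx:] - rel, c_demes[idx:])
        st.set_path(x, x_times, x_demes)

        new = self._try_stats()
        new_ll, undo = self.lik.update(st, [s, c, x])
        if new is not None:
            new_coal, stats = new
            delta = (
                self.beta * (new_ll - self.loglik)
                + (new_coal - self.logcoal) + (q_old - q_new)
            )
            if self._accept(delta):
                self.loglik, self.logcoal, self.stats = new_ll, new_coal, stats
                return True
        for y, val in snap["parent"].items():
            st.parent[y] = val
        for y, val in snap["children"].items():
            st.children[y][:] = val
        st.node_deme[p] = snap["deme_p"]
        for y, (times, demes) in snap["paths"].items():
            st.set_path(y, times, demes)
        self.lik.restore(undo)
        return False

    def move_migration(self) -> bool:
        st = self.state
        if st.model.K == 1:
            return False
        if self.rng.random() < 0.5:
            return self._move_branch_path()
        return self._move_node_deme()

    def _move_branch_path(self) -> bool:
        st = self.state
        node = int(self.rng.integers(0, st.n_nodes))
        if st.parent[node] == -1:
            return False
        res = self._redraw_path(
            node, st.branch_length(node),
            int(st.node_deme[node]), int(st.node_deme[st.parent[node]]),
        )
        if res is None:
            return False
        times, demes, q_new, q_old = res
        old = (st.path_times[node], st.path_demes[node])
        st.set_path(node, times, demes)
        new = self._try_stats()
        if new is not None:
            new_coal, stats = new
            if self._accept((new_coal - self.logcoal) + q_old - q_new):
                self.logcoal, self.stats = new_coal, stats
                return True
        st.set_path(node, *old)
        return False

    def _move_node_deme(self) -> bool:
        st = self.state
        n = st.n_tips
        v = int(self.rng.integers(n, st.n_nodes))
        d_new = int(self.rng.integers(st.model.K))
        c1, c2 = (int(c) for c in st.children[v])
        branches = [c1, c2] + ([] if st.parent[v] == -1 else [v])
        proposals = {}
        logq = 0.0
        for br in branches:
            if br == v:
                a, b = d_new, int(st.node_deme[st.parent[v]])
            else:
                a, b = int(st.node_deme[br]), d_new
            res = self._redraw_path(br, st.branch_length(br), a, b)
            if res is None:
                return False
            times, demes, q_new, q_old = res
            proposals[br] = (times, demes)
            logq += q_old - q_new
        old_deme = int(st.node_deme[v])
        old_paths = {br: (st.path_times[br], st.path_demes[br]) for br in branches}
        st.node_deme[v] = d_new
        for br, (times, demes) in proposals.items():
            st.set_path(br, times, demes)
        new = self._try_stats()
        if new is not None:
            new_coal, stats = new
            if self._accept((new_coal - self.logcoal) + logq):
                self.logcoal, self.stats = new_coal, stats
                return True
        st.node_deme[v] = old_deme
        for br, (times, demes) in old_paths.items():
            st.set_path(br, times, demes)
        return False

    def move_params(self) -> bool:
        """Sweep every Theta and M group with a reflected log random walk.

        The genealogy is untouched and the coalescent density is linear in
        per-group aggregates of the cached sufficient statistics, so each
        group update is O(1): for a Theta group, only its demes' coalescence
        counts and pair-time integrals enter the density change; for a rate
        group, only its pairs' jump counts and source-deme occupancies.
        """
        st = self.state
        stats = self.stats
        any_accept = False
        updates = []
        for g, members in enumerate(st.model.theta_group_members):
            nc = float(stats.n_coal[members].sum())
            a_sum = float(stats.A[members].sum())
            updates.append((st.theta_groups, st.priors.theta, g, nc, a_sum, True))
        for g, pairs in enumerate(st.model.mig_group_members):
            nm = float(sum(stats.n_mig[a, b] for a, b in pairs))
            b_sum = float(sum(stats.B[a] for a, b in pairs))
            updates.append((st.m_groups, st.priors.M, g, nm, b_sum, False))
        dcoal_total = 0.0
        dprior_total = 0.0
        for vec, prior, idx, n_events, integral, is_theta in updates:
            x = float(vec[idx])
            y = math.log(x) + self.config.param_step * self.rng.standard_normal()
            y = _reflect(y, math.log(prior.lower), math.log(prior.upper))
            x_new = math.exp(y)
            if is_theta:
                # events carry 1/theta factors; waiting time integral A/theta
                dcoal = (
                    n_events * (math.log(x) - math.log(x_new))
                    - integral * (1.0 / x_new - 1.0 / x)
                )
            else:
                dcoal = (
                    n_events * (math.log(x_new) - math.log(x))
                    - integral * (x_new - x)
                )
            dprior = prior.logpdf(x_new) - prior.logpdf(x)
            delta = dcoal + dprior + math.log(x_new / x)
            if self._accept(delta):
                vec[idx] = x_new
                dcoal_total += dcoal
                dprior_total += dprior
                any_accept = True
        if any_accept:
            self.logcoal += dcoal_total
            self.logprior += dprior_total
        return any_accept

    # -- one proposal --------------------------------------------------------
    def step(self) -> None:
        u = self.rng.random()
        w = self.config.move_weights
        total = sum(w)
        acc = 0.0
        kind = 3
        for i in range(4):
            acc += w[i] / total
            if u < acc:
                kind = i
                break
        self.proposals[kind] += 1
        # hot chains rely on the scale move to traverse tree-height scales
        scale_frac = 0.3 if self.beta < 0.2 else 0.1
        if kind == 1 and self.rng.random() < scale_frac:
            ok = self.move_scale()
        else:
            ok = (self.move_spr, self.move_time, self.move_migration,
                  self.move_params)[kind]()
        if ok:
            self.accepts[kind] += 1

    def log_target(self) -> float:
        return self.beta * self.loglik + self.logcoal + self.logprior


def mcmc_step(state: GenealogyState, codes: np.ndarray, subst: HKYModel,
              beta: float, rng: np.random.Generator,
              config: MCMCConfig | None = None) -> GenealogyState:
    """One sweep (one proposal of each move family) on a free-standing state."""
    config = config or MCMCConfig.suite_scale()
    chain = Chain(state, codes, subst, beta, config, rng)
    chain.move_time()
    chain.move_spr()
    chain.move_migration()
    chain.move_params()
    return chain.state


@dataclass
class Mc3Result:
    """Post-burn-in traces per temperature plus swap statistics."""

    betas: tuple
    loglik: dict                      # beta -> (n_samples,) array
    theta: dict                       # beta -> (n_samples, G) array
    M: dict                           # beta -> (n_samples, Gm) array
    swap_attempts: np.ndarray
    swap_accepts: np.ndarray
    move_accepts: np.ndarray = None
    move_proposals: np.ndarray = None

    def mean_loglik_by_beta(self) -> dict:
        return {b: float(np.mean(v)) for b, v in self.loglik.items()}


def run_mc3(
    codes: np.ndarray,
    tip_demes_original: np.ndarray,
    model: ModelSpec,
    priors: Priors,
    config: MCMCConfig,
    rng: np.random.Generator,
    subst: HKYModel | None = None,
) -> Mc3Result:
    """Run the Metropolis-coupled sampler; one chain per temperature.

    Rungs at or above ``config.prior_beta_cutoff`` run as coupled Markov
    chains from the same data-informed start, exchanging states between
    adjacent pairs every ``swap_every`` proposals with the standard MC3
    acceptance probability.  Rungs below the cutoff target a distribution
    indistinguishable from the prior (with the default ladder, beta = 1e-5
    tilts the prior by a factor L^{1e-5}); their expectations are estimated
    by iid prior-predictive sampling — exact parameter draws and direct
    structured-coalescent genealogy simulation — which is unbiased and free
    of the mixing pathologies a near-prior chain suffers on a data-sized
    state.  Samples are recorded after ``burn_in`` at every ``sample_every``
    proposals, at every temperature.
    """
    from .state import sample_prior_predictive_loglik

    subst = subst or HKYModel()
    betas = config.betas
    chain_betas = [b for b in betas if b >= config.prior_beta_cutoff]
    prior_betas = [b for b in betas if b < config.prior_beta_cutoff]
    n_chains = len(chain_betas)
    streams = rng.spawn(n_chains + 2)
    init = initial_state(codes, tip_demes_original, model, priors, streams[-1])
    chains = [
        Chain(init.copy() if i else init, codes, subst, beta, config, streams[i])
        for i, beta in enumerate(chain_betas)
    ]
    swap_rng = streams[-1]
    swap_attempts = np.zeros(max(n_chains - 1, 1), dtype=np.int64)
    swap_accepts = np.zeros(max(n_chains - 1, 1), dtype=np.int64)
    samples = {b: {"ll": [], "theta": [], "M": []} for b in chain_betas}
    pair = 0
    for step in range(1, config.total_steps + 1):
        for ch in chains:
            ch.step()
        if n_chains > 1 and config.swap_every and step % config.swap_every == 0:
            i = pair % (n_chains - 1)
            pair += 1
            a, b = chains[i], chains[i + 1]
            swap_attempts[i] += 1
            delta = (a.beta - b.beta) * (b.loglik - a.loglik)
            if delta >= 0 or swap_rng.random() < math.exp(max(delta, -700.0)):
                swap_accepts[i] += 1
                for attr in ("state", "lik", "loglik", "logcoal", "logprior", "stats"):
                    tmp = getattr(a, attr)
                    setattr(a, attr, getattr(b, attr))
                    setattr(b, attr, tmp)
        if step > config.burn_in and step % config.sample_every == 0:
            for ch in chains:
                rec = samples[ch.beta]
                rec["ll"].append(ch.loglik)
                rec["theta"].append(ch.state.theta_groups.copy())
                rec["M"].append(ch.state.m_groups.copy())

    loglik = {b: np.asarray(s["ll"]) for b, s in samples.items()}
    theta = {b: np.asarray(s["theta"]) for b, s in samples.items()}
    M = {b: np.asarray(s["M"]) for b, s in samples.items()}
    for b in prior_betas:
        lls, th_draws, m_draws = sample_prior_predictive_loglik(
            codes, tip_demes_original, model, priors, subst,
            config.prior_draws, streams[-2],
        )
        loglik[b] = lls
        theta[b] = th_draws
        M[b] = m_draws
    return Mc3Result(
        betas=tuple(betas),
        loglik=loglik,
        theta=theta,
        M=M,
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        move_accepts=np.vstack([ch.accepts for ch in chains]),
        move_proposals=np.vstack([ch.proposals for ch in chains]),
    )


def run_model_evidence(
    aln,
    model: ModelSpec,
    priors: Priors,
    config: MCMCConfig,
    rng: np.random.Generator,
    subst: HKYModel | None = None,
) -> dict:
    """Fit one metapopulation model to an alignment and estimate its evidence.

    Returns a summary dict: Bezier and trapezoid log marginal likelihoods,
    the per-temperature mean log likelihood path, posterior parameter samples
    from the cold chain, and swap diagnostics.
    """
    from .evidence import bezier_marginal_likelihood

    res = run_mc3(
        aln.codes.astype(np.int64), aln.deme_of_sample, model, priors, config,
        rng, subst,
    )
    ml = bezier_marginal_likelihood(res.mean_loglik_by_beta())
    cold = 1.0
    return {
        "model": model.name,
        "log_ml": ml.log_ml,
        "log_ml_trapezoid": ml.log_ml_trapezoid,
        "mean_loglik_by_beta": res.mean_loglik_by_beta(),
        "theta_samples": res.theta[cold],
        "M_samples": res.M[cold],
        "loglik_samples": res.loglik[cold],
        "swap_rate": (res.swap_accepts / np.maximum(res.swap_attempts, 1)).tolist(),
        "n_parameters": model.n_theta_groups + model.n_mig_groups,
    }
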