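"""Felsenstein pruning likelihood with cached, invalidatable partials.

Migration events never touch the substitution process, so the data likelihood
depends only on the tree topology and node times.  Partial likelihoods are
4 x L arrays per node, rescaled per site (the per-site log scale factors
accumulate toward the root); after a local tree move only the ancestors of
the touched nodes are recomputed, which is what keeps a long chain affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ..hky import HKYModel


@njit(cache=True, fastmath=True)
def _node_update(right, eigvals, left, t1, t2, part1, part2, ls1, ls2,
                 out_part, out_ls):
    """Fused pruning step for one internal node: assemble both branch
    transition matrices from the cached spectral decomposition, then
    out = scale((P(t1) @ part1) * (P(t2) @ part2))."""
    p1 = np.empty((4, 4))
    p2 = np.empty((4, 4))
    e1 = np.exp(eigvals * t1)
    e2 = np.exp(eigvals * t2)
    for i in range(4):
        for j in range(4):
            v1 = 0.0
            v2 = 0.0
            for k in range(4):
                v1 += right[i, k] * e1[k] * left[k, j]
                v2 += right[i, k] * e2[k] * left[k, j]
            p1[i, j] = v1 if v1 > 0.0 else 0.0
            p2[i, j] = v2 if v2 > 0.0 else 0.0
    _combine_into(p1, part1, p2, part2, ls1, ls2, out_part, out_ls)


@njit(cache=True, fastmath=True)
def _combine_into(p1, part1, p2, part2, ls1, ls2, out_part, out_ls):
    """Fused pruning step: out = scale((p1 @ part1) * (p2 @ part2))."""
    a = np.dot(p1, part1)
    b = np.dot(p2, part2)
    L = a.shape[1]
    for j in range(L):
        m = 0.0
        for i in range(4):
            v = a[i, j] * b[i, j]
            out_part[i, j] = v
            if v > m:
                m = v
        if m == 0.0:
            m = 1.0
        inv = 1.0 / m
        for i in range(4):
            out_part[i, j] *= inv
        out_ls[j] = np.log(m) + ls1[j] + ls2[j]


class TreeLikelihood:
    """Pruning likelihood bound to a fixed alignment and substitution model.

    The tree (parent/children/time arrays) is read from the state object at
    every (re)computation; the cache maps node -> (partial, logscale).
    """

    def __init__(self, codes: np.ndarray, subst: HKYModel):
        self.codes = np.asarray(codes)
        self.n_tips, self.L = self.codes.shape
        self.subst = subst
        n_nodes = 2 * self.n_tips - 1
        self.partial = np.zeros((n_nodes, 4, self.L))
        self.logscale = np.zeros((n_nodes, self.L))
        # one-hot tip partials, never invalidated
        for i in range(self.n_tips):
            self.partial[i, self.codes[i], np.arange(self.L)] = 1.0
        self._loglik = None

    # -- full recomputation --------------------------------------------------
    def full_recompute(self, state) -> float:
        order = np.argsort(state.time[self.n_tips:], kind="stable") + self.n_tips
        for node in order:
            self._compute_node(state, int(node))
        self._loglik = self._root_loglik(state)
        return self._loglik

    def _compute_node(self, state, node: int):
        c1 = int(state.children[node][0])
        c2 = int(state.children[node][1])
        t0 = state.time[node]
        s = self.subst
        _node_update(
            s._right, s._eigvals, s._left,
            max(t0 - state.time[c1], 0.0), max(t0 - state.time[c2], 0.0),
            self.partial[c1], self.partial[c2],
            self.logscale[c1], self.logscale[c2],
            self.partial[node], self.logscale[node],
        )

    def _root_loglik(self, state) -> float:
        root = state.root
        site = self.subst.pi @ self.partial[root]
        return float(np.sum(np.log(site) + self.logscale[root]))

    # -- partial updates -----------------------------------------------------
    def update(self, state, dirty_nodes) -> tuple[float, list]:
        """Recompute the ancestors (inclusive) of ``dirty_nodes``.

        Returns the new log likelihood and an undo record to pass to
        :meth:`restore` if the enclosing proposal is rejected.
        """
        affected = set()
        for node in dirty_nodes:
            node = int(node)
            while node != -1:
                if node >= self.n_tips:
                    affected.add(node)
                node = int(state.parent[node])
        order = sorted(affected, key=lambda v: state.time[v])
        undo = [
            (v, self.partial[v].copy(), self.logscale[v].copy(), self._loglik)
            for v in order
        ]
        for v in order:
            self._compute_node(state, v)
        self._loglik = self._root_loglik(state)
        return self._loglik, undo

    def restore(self, undo) -> None:
        for v, part, scale, ll in undo:
            self.partial[v] = part
            self.logscale[v] = scale
            self._loglik = ll

    @property
    def loglik(self) -> float:
        return self._loglik


def felsenstein_loglik(state, codes: np.ndarray, subst: HKYModel) -> float:
    """One-shot pruning log likelihood of an alignment on a genealogy."""
    if codes.shape[0] != state.n_tips:
        raise ValueError("tip count must match the alignment")
    return TreeLikelihood(codes, subst).full_recompute(state)
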